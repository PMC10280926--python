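# Methods

## Scope and model

A holobiont metagenome is modelled as a set of scaffolds, each carrying a
length, a mean read coverage, and zero or more predicted genes whose best
protein hits provide taxonomy labels. Three genome classes are assumed:
one eukaryote-like host (large, intron-bearing genes, moderate gene
density, low coverage), one dominant prokaryote-like symbiont (compact,
high coverage), and minor contaminants. The pipeline's stages are
independent library functions; the orchestrator only fixes their order
and wiring.

## Scaffold classification by gene vote

Votes are gene best-hit taxonomies collapsed to superkingdom (the first
field of a semicolon-delimited lineage). A scaffold is assigned the
taxon that (a) is one of {Eukaryota, Bacteria, Archaea}, (b) is the
unique plurality winner among those three, and (c) reaches vote fraction
`min_fraction` (default 0.5) of *all* annotated genes on the scaffold.
Labels outside the three superkingdoms (viruses, unclassified lineages)
count in the denominator but can never win, which routes viral scaffolds
to NotAnnotated.

Two alternative readings of "assigned if at least half of the genes
agree" exist when `min_fraction < 0.5` would let two taxa qualify
simultaneously. We require the *unique plurality* winner rather than
"any taxon above threshold": the two rules coincide for thresholds
≥ 0.5, and the plurality rule makes assignment monotone in the threshold
(raising `min_fraction` can only demote scaffolds toward NotAnnotated),
which is the behaviour a sensitivity analysis expects. Exact ties are
NotAnnotated — deterministic and conservative.

Scaffold retention is strictly "longer than 1 kb" (`length > min_len`).
Gene calls above the e-value cutoff (default 10⁻⁵) are dropped at parse
time; genes without a retained hit are excluded from the vote
denominator.

## Coverage partitioning

Scaffold coverages are clustered in log₂(coverage + 1) space. The 1-D
minimum within-group-sum-of-squares partition is always contiguous in
sorted order, so an O(n²k) dynamic program over sorted values is exact
and deterministic; ties in the DP are broken toward the earliest split
point. The +1 offset only matters at depths ≪ 1×; at assembly-scale
depths the grouping is scale-free. Group count k is user-chosen
(default 3: symbiont / host / low-coverage residue) or picked by an
explained-variance elbow: add groups while each addition removes ≥ 5% of
the total log-coverage variance.

Per-genome coverage is the **length-weighted mean** Σ(lᵢcᵢ)/Σlᵢ. The
aggregation behind published per-genome point coverages is rarely
stated; length weighting is the natural estimator of per-base depth and
is configurable by passing any other aggregate to the ratio directly.

The cell ratio is `symbiont_cov / host_cov × host_ploidy`, ploidy
defaulting to 2 (animal hosts are presumed diploid). The reported
integer rounds half away from zero.

## Compactness panel

* **N50/L50**: sort descending, accumulate until ≥ half the total; N50
  is the length reached, L50 the number of sequences used.
* **G+C**: mean ± sd of the G+C fraction over non-overlapping windows
  (default 10 kb). Ambiguity codes are excluded from numerator and
  denominator. A trailing fragment counts when it covers ≥ half a
  window; a sequence shorter than that still contributes its single
  window, so short scaffolds are not silently dropped. The quoted
  "± sd" dispersion of a genome's G+C is window-size dependent; 10 kb is
  the package default and configurable.
* **Coding density**: merged CDS intervals (so alternative transcripts
  are not double-counted) divided by total assembly length.
* **Introns**: per gene, the gaps between consecutive exons of the
  representative transcript (longest total CDS; ties to the smallest
  transcript id — deterministic and conventional). Introns/gene averages
  over genes; intron length averages over introns.
* **Intergenic distance**: between consecutive gene (outermost-exon)
  spans per scaffold, overlapping genes clamped to 0 rather than
  excluded, so the mean is over all consecutive pairs. Clamping vs
  exclusion is unstated in most published figures; clamping keeps the
  denominator well-defined and is configurable in spirit by filtering
  overlapping genes beforehand.
* Coordinates: GFF3 is 1-based inclusive on disk, half-open 0-based
  internally; strand is ignored for density and distance metrics.

## Core/pan orthogroup partition

Core = ≥ 1 member in every genus (default) or every species (strict
mode); both are exposed because published "conserved across the N
genera" counts are usually genus-level. `single_genus` counts groups
confined to one genus and therefore *includes* single-species groups;
`single_species` is reported separately so the multi-species
genus-restricted class is recoverable exactly. Lineage specificity of
core families requires an explicit external-match flag column — whether
a family has any match outside the lineage is a database annotation that
cannot be recomputed offline, so it is an input, not a computation.

Headline percentages are rounded half away from zero, integers for
whole-matrix fractions and one decimal for the lineage-specific core
fraction, matching how such tables are conventionally printed.

`cluster_rbh` builds orthogroups as connected components of the
reciprocal-best-hit graph between proteomes. This is a transparent
surrogate for Markov-clustering tools (OrthoMCL/OrthoFinder), adequate
for well-separated families; it can chain paralogs MCL would split and
is documented as such, not presented as equivalent.

## Reciprocal-best-hit survey

The aligner is exact Smith–Waterman with affine gaps: BLOSUM62 (loaded
from Biopython's published tables), gap open 11, gap extend 1, a gap of
length L costing 11 + L — the blastp default model without heuristic
seeding. X scores 0 against everything, including itself. Traceback is
fully deterministic: start at the highest-scoring cell (ties toward the
smallest target index, then query index), prefer diagonal, then
target-consuming, then query-consuming moves. Identity is matches over
all alignment columns, gaps included.

Calls use a raw-score threshold (default 60) rather than e-values:
Karlin–Altschul e-values depend on database size and are not comparable
across proteomes; an e-value estimate with published gapped-BLOSUM62
constants (K = 0.041, λ = 0.267) is available as a report column only.
Best-hit ties break to the lexicographically smallest target id. The
reciprocal check runs within the two supplied proteomes — a deliberate,
documented difference from surveys whose reciprocal step searches a
comprehensive database. A per-family regular-expression motif hook can
demote presence calls that lack a required sequence feature; it ships
empty.

The kernel is numba-jitted; a score-only O(m)-memory pass ranks hits and
the full matrix is materialised only for the winning pair.

## Synthetic data

The generator emulates the study conditions at reduced genome extent.
Defaults: host 40 scaffolds of ~50 kb (normal, sd 12 kb, floor 1.5 kb),
G+C 0.36, 0.269 genes/kb, 1.59 introns/gene of mean length 341 bp
(normal, sd 30%, floor 30 bp), exon lengths ~N(450, 150) floored at
60 bp; symbiont 1.63 Mb split over up to 11 scaffolds, G+C 0.373,
single-exon genes ~N(950, 250) placed to hit coding density 0.839
exactly; 10 contaminant contigs of 3–8 kb at coding density 0.80 and
12–25× coverage. Host coverage 186×, symbiont multiplier 6.48, ploidy 2.
Scaffold coverage is log-normal around the class mean with the median at
the mean parameter, so zero noise reproduces the configured values
exactly and coverage stays positive. Label noise flips each gene's
superkingdom to a uniformly chosen wrong label with the configured
probability; an optional unannotated rate drops calls entirely.

Gene placement distributes the non-genic residue of each scaffold over
the gaps via a Dirichlet draw, which at the default density yields mean
intergenic distances near 2 kb. Sequences are i.i.d. nucleotides at the
target G+C: no repeats, no codon structure, no regional GC variation —
so passing tests demonstrate correctness of the *computations*, not
robustness to repeat-rich or compositionally heterogeneous genomes.
Orthogroup matrices are constructed category-by-category (core /
genus-restricted / species-specific) with independent per-cell loss;
under loss rate ℓ a core family survives as core with probability
∏_g (1 − ℓ^{m_g}) over genus sizes m_g, the closed form the recovery
tests check. Protein panels mutate a random root sequence by point
substitution only (no indels), keeping observed identity an unbiased
estimate of the configured identity; decoy paralogs are attached to
present families at a lower identity.

Randomness: one seed per artifact; structure, sequence, coverage and
label streams are independent children of it (`SeedSequence.spawn`), so
outputs are byte-reproducible and perturbing one noise source leaves the
others untouched.

## Problem sizes in the test suite

Multi-seed suites run on scaled inputs chosen once as representative:
binning accuracy uses 100 holobionts of ~0.75 Mb (15 host scaffolds of
~40 kb, 90 kb symbiont, 6 contaminants) at 20% label noise, scored over
scaffolds with ≥ 5 genes; core recovery uses 200 matrices of 1000
families over 10 species in 5 genera at 10% loss; the survey benchmark
uses 100 families with 80% ortholog presence and 30% decoy incidence.
The exhaustive oracle checks cover all vote combinations up to 6 genes,
all length lists up to size 8 on a value grid (plus randomized lists),
and random alignment pairs of combined length ≤ 20 against an
independent full-DP aligner.

## Known limitations

* The vote is superkingdom-level; no true lowest-common-ancestor walk
  over a taxonomy tree, and no composition-based (k-mer) binning.
* Coverage is taken from the input table as-is; no BAM-level depth
  recomputation, deduplication or GC–coverage joint modelling.
* `cluster_rbh` is not Markov clustering (see above).
* The survey has no heuristic seeding, profile (HMM) search or
  phylogenetic confirmation; domain-architecture checks are reduced to
  the optional motif hook.
* The generator's realism gaps (repeats, composition structure, read
  -level artefacts) bound what green tests imply about real assemblies.
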