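"""Ground-truthed synthetic holobiont data.

Real holobiont assemblies mix one large, intron-bearing, moderately
gene-dense host genome at low read coverage with one compact, gene-dense
symbiont genome at much higher coverage, plus minor contaminant contigs.
This module generates such mixtures — assembly FASTA, GFF3 gene models,
per-scaffold coverage, per-gene best-hit taxonomy calls — together with
the truth tables needed to score every downstream stage, plus orthogroup
membership matrices and protein family panels for the orthology and
reciprocal-best-hit stages.

Default parameters follow the study system this package was built around:
a glass-sponge-like host (G+C 0.36, coverage 186x, diploid, 1.59 introns
per gene of mean length 341 bp, 0.269 genes/kb) hosting a dominant
Thaumarchaeota-like symbiont (1.63 Mb, coding density 0.839, coverage
6.48x the host's).  The host is scaled to ~2 Mb (40 scaffolds) so suites
run at desk scale; every per-base and per-gene parameter is kept at its
study value, only the genome extent shrinks.

Randomness: one seed per artifact; sub-generators (structure, sequence,
coverage, labels) derive independent child streams from it via
``numpy.random.SeedSequence.spawn``, so e.g. label noise can vary without
disturbing the sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .orthstats import OrthoMatrix
from .rbh import PROTEIN_ALPHABET, ProteinSeq
from .taxbin import GeneTaxCall, ScaffoldRecord

__all__ = [
    "SpecValidationError",
    "HolobiontSpec",
    "GroundTruth",
    "SynGene",
    "Holobiont",
    "ProteinPanel",
    "generate_holobiont",
    "generate_ortho_families",
    "generate_protein_panel",
]

#: True scaffold bin -> superkingdom of its genes.
BIN_TAXON = {
    "host_nuclear": "Eukaryota",
    "symbiont": "Archaea",
    "contaminant": "Bacteria",
}

_TAX_LABELS = ("Eukaryota", "Bacteria", "Archaea")

# internal composition constants (study-like, not user-tunable)
_SYMBIONT_GC = 0.373
_CONTAM_GC = 0.45
_EXON_LEN_MEAN, _EXON_LEN_SD = 450.0, 150.0
_PROK_GENE_LEN_MEAN, _PROK_GENE_LEN_SD = 950.0, 250.0
_CONTAM_CODING = 0.80
_CONTAM_COV_RANGE = (12.0, 25.0)


class SpecValidationError(ValueError):
    """A generator parameter violates its contract; names the field."""


@dataclass
class HolobiontSpec:
    """Parameters of one synthetic holobiont metagenome."""

    host_n_scaffolds: int = 40
    host_scaffold_len_mean: float = 50_000.0
    host_scaffold_len_sd: float = 12_000.0
    host_gc: float = 0.36
    host_gene_density: float = 0.269  # genes per kb
    host_intron_rate: float = 1.59  # mean introns per gene
    host_intron_len_mean: float = 341.0
    symbiont_len: int = 1_630_000
    symbiont_coding_density: float = 0.839
    symbiont_coverage_multiplier: float = 6.48
    host_coverage_mean: float = 186.0
    coverage_noise_sd: float = 0.2  # sd of log-coverage
    contaminant_n: int = 10
    tax_label_error_rate: float = 0.1
    unannotated_rate: float = 0.0
    host_ploidy: int = 2
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "host_n_scaffolds", "host_scaffold_len_mean", "host_gc",
            "host_gene_density", "host_intron_len_mean", "symbiont_len",
            "symbiont_coding_density", "symbiont_coverage_multiplier",
            "host_coverage_mean",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be > 0, got {getattr(self, name)}")
        nonneg = [
            "host_scaffold_len_sd", "host_intron_rate", "coverage_noise_sd",
            "contaminant_n",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise SpecValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "host_gc", "symbiont_coding_density", "tax_label_error_rate",
            "unannotated_rate",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise SpecValidationError(
                    f"{name} must be a fraction in [0, 1], got {getattr(self, name)}"
                )
        if self.host_ploidy < 1:
            raise SpecValidationError(f"host_ploidy must be >= 1, got {self.host_ploidy}")


@dataclass
class GroundTruth:
    """What the generator actually built, keyed the way pipelines report."""

    scaffold_bins: dict[str, str] = field(default_factory=dict)
    scaffold_taxa: dict[str, str] = field(default_factory=dict)
    scaffold_coverage_mean: dict[str, float] = field(default_factory=dict)
    gene_taxa: dict[str, str] = field(default_factory=dict)
    family_categories: dict[str, str] = field(default_factory=dict)
    family_present: dict[str, bool] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass
class SynGene:
    gene_id: str
    scaffold_id: str
    exons: list[tuple[int, int]]  # half-open, sorted
    strand: str = "+"

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class Holobiont:
    """In-memory synthetic holobiont plus its ground truth."""

    spec: HolobiontSpec
    scaffolds: list[ScaffoldRecord]
    sequences: dict[str, str]
    genes: list[SynGene]
    calls: list[GeneTaxCall]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write assembly, gene models, coverage, hits and truth tables."""
        from . import io as hio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": outdir / "assembly.fasta",
            "gff": outdir / "genes.gff3",
            "coverage": outdir / "coverage.tsv",
            "hits": outdir / "hits.tsv",
            "calls": outdir / "calls.tsv",
            "gene_map": outdir / "gene_map.tsv",
            "truth_scaffolds": outdir / "truth_scaffolds.tsv",
            "truth_genes": outdir / "truth_genes.tsv",
            "spec": outdir / "spec.json",
        }
        hio.write_fasta(self.sequences, paths["assembly"])
        _write_gff3(self.genes, paths["gff"])
        hio.write_coverage_tsv(self.scaffolds, paths["coverage"])
        _write_hits_tabular(self.calls, paths["hits"])
        hio.write_calls_tsv(self.calls, paths["calls"])
        pd.DataFrame(
            {"gene_id": [g.gene_id for g in self.genes],
             "scaffold_id": [g.scaffold_id for g in self.genes]}
        ).to_csv(paths["gene_map"], sep="\t", index=False)
        pd.DataFrame(
            {
                "scaffold_id": list(self.truth.scaffold_bins),
                "true_bin": list(self.truth.scaffold_bins.values()),
                "true_taxon": [self.truth.scaffold_taxa[s] for s in self.truth.scaffold_bins],
                "coverage_mean": [
                    self.truth.scaffold_coverage_mean[s] for s in self.truth.scaffold_bins
                ],
            }
        ).to_csv(paths["truth_scaffolds"], sep="\t", index=False)
        pd.DataFrame(
            {"gene_id": list(self.truth.gene_taxa),
             "true_taxon": list(self.truth.gene_taxa.values())}
        ).to_csv(paths["truth_genes"], sep="\t", index=False)
        hio.write_json(asdict(self.spec), paths["spec"])
        return paths


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    r = rng.random(length)
    at = (1 - gc) / 2
    codes = np.digitize(r, [at, 2 * at, 2 * at + gc / 2])
    return "".join(np.array(list("ATGC"))[codes].tolist())


def _allocate_gaps(rng: np.random.Generator, total: int, n_gaps: int) -> np.ndarray:
    if n_gaps == 0:
        return np.array([], dtype=int)
    if total <= 0:
        return np.zeros(n_gaps, dtype=int)
    props = rng.dirichlet(np.ones(n_gaps))
    gaps = np.floor(props * total).astype(int)
    gaps[-1] += total - gaps.sum()
    return gaps


def _host_gene_structures(rng, n_genes, intron_rate, intron_len_mean):
    structures = []
    for _ in range(n_genes):
        n_introns = int(rng.poisson(intron_rate))
        exon_lens = np.maximum(
            60, np.round(rng.normal(_EXON_LEN_MEAN, _EXON_LEN_SD, n_introns + 1))
        ).astype(int)
        intron_lens = np.maximum(
            30, np.round(rng.normal(intron_len_mean, 0.3 * intron_len_mean, n_introns))
        ).astype(int)
        structures.append((exon_lens, intron_lens))
    return structures


def _place_host_genes(rng, scaffold_id, length, spec) -> list[SynGene]:
    n_genes = int(round(length / 1000 * spec.host_gene_density))
    structures = _host_gene_structures(
        rng, n_genes, spec.host_intron_rate, spec.host_intron_len_mean
    )
    # drop genes from the end if the scaffold cannot hold them
    spans = [int(e.sum() + i.sum()) for e, i in structures]
    while structures and sum(spans) > 0.9 * length:
        structures.pop()
        spans.pop()
    gaps = _allocate_gaps(rng, length - sum(spans), len(structures) + 1)
    genes = []
    pos = 0
    for gi, (exon_lens, intron_lens) in enumerate(structures):
        pos += int(gaps[gi])
        exons = []
        cursor = pos
        for k, el in enumerate(exon_lens):
            exons.append((cursor, cursor + int(el)))
            cursor += int(el)
            if k < len(intron_lens):
                cursor += int(intron_lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(SynGene(f"{scaffold_id}.g{gi:03d}", scaffold_id, exons, strand))
        pos = cursor
    return genes


def _place_compact_genes(rng, scaffold_id, length, coding_density) -> list[SynGene]:
    """Single-exon genes filling the scaffold to the target coding density."""
    target = int(round(length * coding_density))
    gene_lens: list[int] = []
    acc = 0
    while acc < target:
        l = max(150, int(round(rng.normal(_PROK_GENE_LEN_MEAN, _PROK_GENE_LEN_SD))))
        if acc + l > target:
            l = target - acc
            if l < 60:  # too small to be a gene: absorb into the previous one
                if gene_lens:
                    gene_lens[-1] += l
                acc = target
                break
        gene_lens.append(l)
        acc += l
    gaps = _allocate_gaps(rng, length - sum(gene_lens), len(gene_lens) + 1)
    genes = []
    pos = 0
    for gi, l in enumerate(gene_lens):
        pos += int(gaps[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            SynGene(f"{scaffold_id}.g{gi:03d}", scaffold_id, [(pos, pos + l)], strand)
        )
        pos += l
    return genes


def generate_holobiont(spec: HolobiontSpec) -> Holobiont:
    """Generate one synthetic holobiont metagenome with ground truth.

    Deterministic for a fixed spec (the seed is part of the spec):
    scaffold coverages are drawn log-normally around each genome's mean
    (median = the configured mean, so zero noise reproduces it exactly),
    per-gene taxonomy labels are flipped to a random wrong superkingdom
    with probability ``tax_label_error_rate`` and dropped (gene
    unannotated) with probability ``unannotated_rate``.
    """
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(4)
    rng_struct = np.random.default_rng(children[0])
    rng_seq = np.random.default_rng(children[1])
    rng_cov = np.random.default_rng(children[2])
    rng_label = np.random.default_rng(children[3])

    truth = GroundTruth(params=asdict(spec))
    plan: list[tuple[str, int, float, float, str]] = []  # id, len, gc, cov_mean, bin

    for i in range(spec.host_n_scaffolds):
        length = max(
            1500,
            int(round(rng_struct.normal(spec.host_scaffold_len_mean, spec.host_scaffold_len_sd))),
        )
        plan.append((f"host_s{i:04d}", length, spec.host_gc, spec.host_coverage_mean, "host_nuclear"))

    n_symb = int(max(1, min(11, spec.symbiont_len // 10_000)))
    base = spec.symbiont_len // n_symb
    symb_cov = spec.host_coverage_mean * spec.symbiont_coverage_multiplier
    for i in range(n_symb):
        length = base + (spec.symbiont_len - base * n_symb if i == 0 else 0)
        plan.append((f"symb_s{i:02d}", length, _SYMBIONT_GC, symb_cov, "symbiont"))

    for i in range(spec.contaminant_n):
        length = int(rng_struct.integers(3000, 8001))
        cov = float(rng_struct.uniform(*_CONTAM_COV_RANGE))
        plan.append((f"contam_s{i:02d}", length, _CONTAM_GC, cov, "contaminant"))

    scaffolds: list[ScaffoldRecord] = []
    sequences: dict[str, str] = {}
    genes: list[SynGene] = []
    calls: list[GeneTaxCall] = []

    for sid, length, gc, cov_mean, bin_name in plan:
        if bin_name == "host_nuclear":
            sgenes = _place_host_genes(rng_struct, sid, length, spec)
        elif bin_name == "symbiont":
            sgenes = _place_compact_genes(rng_struct, sid, length, spec.symbiont_coding_density)
        else:
            sgenes = _place_compact_genes(rng_struct, sid, length, _CONTAM_CODING)
        sequences[sid] = _random_seq(rng_seq, length, gc)
        coverage = float(cov_mean * np.exp(spec.coverage_noise_sd * rng_cov.standard_normal()))

        true_taxon = BIN_TAXON[bin_name]
        for g in sgenes:
            truth.gene_taxa[g.gene_id] = true_taxon
            if rng_label.random() < spec.unannotated_rate:
                continue
            label = true_taxon
            if rng_label.random() < spec.tax_label_error_rate:
                wrong = [t for t in _TAX_LABELS if t != true_taxon]
                label = wrong[int(rng_label.integers(len(wrong)))]
            calls.append(
                GeneTaxCall(
                    gene_id=g.gene_id,
                    scaffold_id=sid,
                    taxon=label,
                    evalue=float(10.0 ** -rng_label.uniform(6, 60)),
                    bitscore=float(np.round(rng_label.uniform(80, 500), 1)),
                )
            )
        genes.extend(sgenes)
        scaffolds.append(
            ScaffoldRecord(sid, length, coverage, [g.gene_id for g in sgenes])
        )
        truth.scaffold_bins[sid] = bin_name
        truth.scaffold_taxa[sid] = true_taxon
        truth.scaffold_coverage_mean[sid] = float(cov_mean)

    return Holobiont(spec, scaffolds, sequences, genes, calls, truth)


def generate_ortho_families(
    n_species: int,
    genus_map: dict[str, str],
    n_families: int,
    core_fraction: float,
    genus_restricted_fraction: float,
    loss_rate: float = 0.0,
    seed: int = 0,
) -> tuple[OrthoMatrix, GroundTruth]:
    """Construct an orthogroup matrix with known category composition.

    ``round(n_families * core_fraction)`` families span every species,
    ``round(n_families * genus_restricted_fraction)`` span all species of
    one genus (preferring multi-species genera so the category is
    distinguishable from species-specific), and the remainder are private
    to a single species.  Each occupied cell is then independently deleted
    with probability ``loss_rate``; families losing every member drop out
    of the matrix but stay in the truth table.
    """
    if n_species != len(genus_map):
        raise SpecValidationError(
            f"n_species ({n_species}) != number of species in genus_map ({len(genus_map)})"
        )
    for name, val in (
        ("core_fraction", core_fraction),
        ("genus_restricted_fraction", genus_restricted_fraction),
        ("loss_rate", loss_rate),
    ):
        if not 0 <= val <= 1:
            raise SpecValidationError(f"{name} must be in [0, 1], got {val}")
    if core_fraction + genus_restricted_fraction > 1:
        raise SpecValidationError(
            "core_fraction + genus_restricted_fraction must be <= 1, got "
            f"{core_fraction + genus_restricted_fraction}"
        )
    if n_families < 0:
        raise SpecValidationError(f"n_families must be >= 0, got {n_families}")

    rng = np.random.default_rng(seed)
    species = sorted(genus_map)
    genera = sorted({genus_map[s] for s in species})
    members: dict[str, list[str]] = {g: [] for g in genera}
    for s in species:
        members[genus_map[s]].append(s)
    multi = [g for g in genera if len(members[g]) >= 2] or genera

    n_core = int(round(n_families * core_fraction))
    n_gr = min(int(round(n_families * genus_restricted_fraction)), n_families - n_core)
    n_ls = n_families - n_core - n_gr

    counts = np.zeros((n_families, len(species)), dtype=int)
    col = {s: i for i, s in enumerate(species)}
    truth = GroundTruth(
        params={
            "n_species": n_species, "n_families": n_families,
            "core_fraction": core_fraction,
            "genus_restricted_fraction": genus_restricted_fraction,
            "loss_rate": loss_rate, "seed": seed,
        }
    )
    fam_ids = [f"fam{i:05d}" for i in range(n_families)]
    for i in range(n_families):
        if i < n_core:
            counts[i, :] = 1
            category = "core"
        elif i < n_core + n_gr:
            genus = multi[int(rng.integers(len(multi)))]
            for s in members[genus]:
                counts[i, col[s]] = 1
            category = "genus_restricted"
        else:
            s = species[int(rng.integers(len(species)))]
            counts[i, col[s]] = 1
            category = "lineage_specific"
        truth.family_categories[fam_ids[i]] = category

    if loss_rate > 0:
        lost = (rng.random(counts.shape) < loss_rate) & (counts > 0)
        counts[lost] = 0

    df = pd.DataFrame(counts, index=fam_ids, columns=species)
    df = df[df.sum(axis=1) > 0]
    assigned = df.sum(axis=0)
    totals = {
        s: int(assigned[s] + rng.poisson(0.15 * max(assigned[s], 1))) for s in species
    }
    matrix = OrthoMatrix(counts=df, genus_map=dict(genus_map), species_totals=totals)
    return matrix, truth


@dataclass
class ProteinPanel:
    """A query panel with its matching (and decoy-spiked) target proteome."""

    panel: dict[str, ProteinSeq]
    queryome: list[ProteinSeq]
    targetome: list[ProteinSeq]
    truth: GroundTruth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 20, length)
    return "".join(PROTEIN_ALPHABET[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Point-substitute each site with probability ``rate`` (no indels)."""
    idx = np.array([PROTEIN_ALPHABET.index(c) for c in seq])
    hit = rng.random(len(seq)) < rate
    offsets = rng.integers(1, 20, len(seq))
    idx[hit] = (idx[hit] + offsets[hit]) % 20
    return "".join(PROTEIN_ALPHABET[i] for i in idx)


def generate_protein_panel(
    n_families: int,
    ortholog_identity: float = 0.8,
    decoy_identity: float = 0.3,
    seed: int = 0,
    present_fraction: float = 1.0,
    decoy_fraction: float = 0.3,
    length_range: tuple[int, int] = (90, 150),
) -> ProteinPanel:
    """Protein families with known orthologs and paralog decoys.

    Each family has one query protein; with probability
    ``present_fraction`` the target proteome carries its true ortholog
    (mutated to ``ortholog_identity``), and present families additionally
    gain a decoy paralog (mutated to the lower ``decoy_identity``) with
    probability ``decoy_fraction``.  Absent families have no counterpart
    of any kind in the target set.
    """
    if not 0 <= decoy_identity < ortholog_identity <= 1:
        raise SpecValidationError(
            "identities must satisfy 0 <= decoy_identity < ortholog_identity <= 1, "
            f"got decoy={decoy_identity}, ortholog={ortholog_identity}"
        )
    if n_families < 0:
        raise SpecValidationError(f"n_families must be >= 0, got {n_families}")
    rng = np.random.default_rng(seed)
    panel: dict[str, ProteinSeq] = {}
    queryome: list[ProteinSeq] = []
    targetome: list[ProteinSeq] = []
    truth = GroundTruth(
        params={
            "n_families": n_families, "ortholog_identity": ortholog_identity,
            "decoy_identity": decoy_identity, "present_fraction": present_fraction,
            "decoy_fraction": decoy_fraction, "seed": seed,
        }
    )
    for i in range(n_families):
        family = f"fam{i:03d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        root = _random_protein(rng, length)
        query = ProteinSeq(f"{family}_q", root)
        panel[family] = query
        queryome.append(query)
        present = bool(rng.random() < present_fraction)
        truth.family_present[family] = present
        if present:
            targetome.append(
                ProteinSeq(f"{family}_t", _mutate(rng, root, 1 - ortholog_identity))
            )
            if rng.random() < decoy_fraction:
                targetome.append(
                    ProteinSeq(f"{family}_decoy", _mutate(rng, root, 1 - decoy_identity))
                )
    return ProteinPanel(panel, queryome, targetome, truth)


def _write_gff3(genes: list[SynGene], path: Path) -> None:
    lines = ["##gff-version 3"]
    for g in sorted(genes, key=lambda g: (g.scaffold_id, g.start)):
        attrs = f"ID={g.gene_id}"
        lines.append(
            "\t".join(
                [g.scaffold_id, "holobin_sim", "gene", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", attrs]
            )
        )
        mrna = f"{g.gene_id}.t1"
        lines.append(
            "\t".join(
                [g.scaffold_id, "holobin_sim", "mRNA", str(g.start + 1), str(g.end),
                 ".", g.strand, ".", f"ID={mrna};Parent={g.gene_id}"]
            )
        )
        cum = 0
        for k, (s, e) in enumerate(g.exons):
            for ftype in ("exon", "CDS"):
                phase = str((3 - cum % 3) % 3) if ftype == "CDS" else "."
                fid = f"ID={mrna}.{ftype}{k};Parent={mrna}"
                lines.append(
                    "\t".join(
                        [g.scaffold_id, "holobin_sim", ftype, str(s + 1), str(e),
                         ".", g.strand, phase, fid]
                    )
                )
            cum += e - s
    path.write_text("\n".join(lines) + "\n")


def _write_hits_tabular(calls: list[GeneTaxCall], path: Path) -> None:
    """12-column tabular best-hit file; subject ids encode the taxon label."""
    rows = []
    for k, c in enumerate(calls):
        alen = 200
        pident = round(min(99.9, 30 + c.bitscore / 6), 1)
        rows.append(
            [c.gene_id, f"hit|{c.taxon}|{k:06d}", pident, alen,
             int(alen * (1 - pident / 100)), 0, 1, alen, 1, alen,
             f"{c.evalue:.3e}", c.bitscore]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
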