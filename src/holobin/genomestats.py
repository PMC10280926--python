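"""Assembly and annotation compactness metrics.

The panel computed here is the one used to compare genome architectures
across species: contiguity (N50/L50), base composition (windowed G+C mean
and dispersion), gene-count and gene-density figures, coding density over
merged CDS intervals, intron burden (introns per gene, mean intron length)
and mean intergenic distance.  Together these decompose genome size into
its drivers — gene number, intron content and intergenic spacing.

Coordinates are GFF3 1-based inclusive on disk and half-open 0-based
internally; strand is ignored for density and distance metrics.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field

import gffutils

__all__ = [
    "Transcript",
    "Gene",
    "read_gff3",
    "compute_n50",
    "gc_content",
    "coding_density",
    "representative_transcript",
    "intron_stats",
    "intergenic_stats",
    "annotation_summary",
]


@dataclass
class Transcript:
    """One mRNA: exon and CDS intervals, half-open 0-based, sorted."""

    transcript_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def cds_length(self) -> int:
        ivals = self.cds if self.cds else self.exons
        return sum(e - s for s, e in ivals)


@dataclass
class Gene:
    """A gene locus with its transcripts; span is the outermost exon extent."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    transcripts: list[Transcript] = field(default_factory=list)


def read_gff3(source: str, from_string: bool = False) -> list[Gene]:
    """Load gene models from a GFF3 file (or text) into :class:`Gene` records.

    Expects the conventional gene/mRNA/exon/CDS hierarchy with ID/Parent
    attributes.  Parsing is delegated to gffutils with an in-memory
    database.
    """
    db = gffutils.create_db(
        source,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(
            gene_id=g.id,
            scaffold_id=g.seqid,
            start=g.start - 1,
            end=g.end,
            strand=g.strand or "+",
        )
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            tr = Transcript(transcript_id=t.id)
            for e in db.children(t, featuretype="exon", order_by="start"):
                tr.exons.append((e.start - 1, e.end))
            for c in db.children(t, featuretype="CDS", order_by="start"):
                tr.cds.append((c.start - 1, c.end))
            gene.transcripts.append(tr)
        genes.append(gene)
    return genes


def compute_n50(lengths: list[int]) -> tuple[int, int]:
    """Return (N50, L50) of a set of sequence lengths.

    Sort descending and accumulate: N50 is the first length at which the
    running sum reaches half the total; L50 is how many sequences that
    took.
    """
    if not lengths:
        raise ValueError("compute_n50: empty length list")
    if any(l <= 0 for l in lengths):
        raise ValueError("compute_n50: all lengths must be > 0")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for i, l in enumerate(ordered, start=1):
        acc += l
        if acc >= half:
            return l, i
    raise AssertionError("unreachable")


def _iter_windows(seq: str, window: int):
    n = len(seq)
    pos = 0
    while pos < n:
        chunk = seq[pos : pos + window]
        # a trailing fragment counts only if it covers at least half a
        # window; a sequence shorter than that still yields its one window
        if pos > 0 and len(chunk) < window and len(chunk) * 2 < window:
            break
        pos += window
        yield chunk


def gc_content(
    sequences: dict[str, str] | list[tuple[str, str]],
    window: int = 10000,
) -> tuple[float, float]:
    """Windowed G+C content: (mean %, sd %) over non-overlapping windows.

    Ambiguity codes are excluded from both numerator and denominator; a
    trailing window is kept when it spans at least half the window size.
    The sd across windows is the dispersion usually quoted alongside a
    genome's G+C figure.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    items = sequences.items() if isinstance(sequences, dict) else sequences
    fractions = []
    seen = False
    for _sid, seq in items:
        seen = True
        for chunk in _iter_windows(seq.upper(), window):
            gc = chunk.count("G") + chunk.count("C")
            at = chunk.count("A") + chunk.count("T")
            if gc + at == 0:
                continue
            fractions.append(gc / (gc + at))
    if not seen:
        raise ValueError("gc_content: empty sequence set")
    if not fractions:
        raise ValueError("gc_content: no window with unambiguous bases")
    mean = statistics.fmean(fractions) * 100
    sd = statistics.stdev(fractions) * 100 if len(fractions) > 1 else 0.0
    return mean, sd


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coding_density(
    cds_intervals: dict[str, list[tuple[int, int]]],
    assembly_length: int,
    scaffold_lengths: dict[str, int] | None = None,
) -> float:
    """Percent of the assembly covered by protein-coding sequence.

    Intervals (half-open, per scaffold) are merged before summing so that
    overlapping CDS from alternative transcripts are not double-counted.
    When ``scaffold_lengths`` is supplied, out-of-bounds intervals raise.
    """
    if assembly_length <= 0:
        raise ValueError(f"assembly_length must be > 0, got {assembly_length}")
    coding = 0
    for sid, ivals in cds_intervals.items():
        for s, e in ivals:
            if s < 0 or e < s:
                raise ValueError(f"bad interval ({s}, {e}) on {sid}")
            if scaffold_lengths is not None and e > scaffold_lengths.get(sid, math.inf):
                raise ValueError(
                    f"interval ({s}, {e}) exceeds scaffold {sid} "
                    f"length {scaffold_lengths[sid]}"
                )
        coding += sum(e - s for s, e in merge_intervals(ivals))
    return coding / assembly_length * 100


def representative_transcript(gene: Gene) -> Transcript | None:
    """Longest-total-CDS transcript; ties broken by smallest transcript id."""
    if not gene.transcripts:
        return None
    return min(gene.transcripts, key=lambda t: (-t.cds_length(), t.transcript_id))


def intron_stats(genes: list[Gene]) -> tuple[float, float]:
    """(mean introns per gene, mean intron length in bp).

    Introns are the gaps between consecutive exons of each gene's
    representative transcript.  The first mean averages intron counts over
    all genes (single-exon genes contribute zero); the second averages
    lengths over all introns and is NaN when no gene has an intron.
    """
    if not genes:
        raise ValueError("intron_stats: empty gene list")
    counts = []
    lengths = []
    for gene in genes:
        tr = representative_transcript(gene)
        if tr is None or not tr.exons:
            counts.append(0)
            continue
        exons = sorted(tr.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"overlapping exons in transcript {tr.transcript_id} "
                    f"of gene {gene.gene_id}"
                )
            lengths.append(s2 - e1)
        counts.append(len(exons) - 1)
    mean_len = statistics.fmean(lengths) if lengths else math.nan
    return statistics.fmean(counts), mean_len


def intergenic_stats(genes: list[Gene]) -> float:
    """Mean distance between consecutive gene spans on the same scaffold.

    Genes are sorted by start within each scaffold; the gap to the next
    gene is clamped to zero when genes overlap, so every consecutive pair
    contributes.  Scaffold ends contribute nothing.  NaN when no scaffold
    carries two genes.
    """
    by_scaffold: dict[str, list[Gene]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    gaps = []
    for members in by_scaffold.values():
        members.sort(key=lambda g: (g.start, g.end))
        for a, b in zip(members, members[1:]):
            gaps.append(max(0, b.start - a.end))
    return statistics.fmean(gaps) if gaps else math.nan


def annotation_summary(
    sequences: dict[str, str],
    genes: list[Gene],
    window: int = 10000,
) -> dict:
    """Combined assembly + annotation panel as a flat dict.

    Raises when gene models reference scaffolds absent from the assembly.
    Intron and intergenic fields are reported as None when undefined
    (no genes, or no multi-gene scaffold).
    """
    dangling = sorted({g.scaffold_id for g in genes} - set(sequences))
    if dangling:
        raise ValueError(
            "gene models reference scaffolds missing from the assembly: "
            + ", ".join(dangling)
        )
    lengths = [len(s) for s in sequences.values()]
    total = sum(lengths)
    n50, l50 = compute_n50(lengths)
    gc_mean, gc_sd = gc_content(sequences, window=window)

    panel = {
        "n_scaffolds": len(lengths),
        "total_length": total,
        "gc_mean": gc_mean,
        "gc_sd": gc_sd,
        "n50": n50,
        "l50": l50,
        "n_genes": len(genes),
        "proteins_per_mb": len(genes) / (total / 1e6),
    }
    if genes:
        cds: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            tr = representative_transcript(g)
            ivals = (tr.cds or tr.exons) if tr else [(g.start, g.end)]
            cds.setdefault(g.scaffold_id, []).extend(ivals)
        ipg, mil = intron_stats(genes)
        mid = intergenic_stats(genes)
        panel.update(
            coding_density=coding_density(
                cds, total, {sid: len(s) for sid, s in sequences.items()}
            ),
            introns_per_gene=ipg,
            mean_intron_len=None if math.isnan(mil) else mil,
            mean_intergenic_dist=None if math.isnan(mid) else mid,
        )
    else:
        panel.update(
            coding_density=0.0,
            introns_per_gene=None,
            mean_intron_len=None,
            mean_intergenic_dist=None,
        )
    return panel
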