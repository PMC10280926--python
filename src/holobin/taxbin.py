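"""Taxonomic binning of metagenome scaffolds by gene-vote majority.

Each predicted gene on a scaffold carries the taxonomy of its best protein
hit.  A scaffold is assigned to a superkingdom (Eukaryota, Bacteria or
Archaea) when the plurality taxon among its annotated genes reaches a vote
fraction threshold (default: at least half).  Scaffolds with no annotated
genes, with a tied plurality, or whose genes are dominated by labels outside
the three cellular superkingdoms (e.g. viruses) fall into the NotAnnotated
group.  This approximates a lowest-common-ancestor call collapsed to a
single rank and is the standard first pass when deconvolving a holobiont
assembly into host and symbiont genomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "ASSIGNABLE_TAXA",
    "NOT_ANNOTATED",
    "GeneTaxCall",
    "ScaffoldRecord",
    "BinAssignment",
    "filter_scaffolds",
    "collapse_to_superkingdom",
    "vote_scaffold_taxon",
    "bin_metagenome",
]

#: Superkingdoms a scaffold may be assigned to.  Votes for any other label
#: (viruses, unclassified lineages) count toward the denominator but can
#: never win, which routes purely viral scaffolds to NotAnnotated.
ASSIGNABLE_TAXA = ("Eukaryota", "Bacteria", "Archaea")

NOT_ANNOTATED = "NotAnnotated"


@dataclass(frozen=True)
class GeneTaxCall:
    """Best-hit taxonomy for one gene: the vote it casts for its scaffold."""

    gene_id: str
    scaffold_id: str
    taxon: str
    evalue: float = 0.0
    bitscore: float = 0.0


@dataclass
class ScaffoldRecord:
    """One assembly sequence with its length, read coverage and gene calls."""

    scaffold_id: str
    length: int
    coverage: float = 0.0
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(
                f"scaffold {self.scaffold_id!r}: length must be > 0, got {self.length}"
            )
        if self.coverage < 0:
            raise ValueError(
                f"scaffold {self.scaffold_id!r}: coverage must be >= 0, got {self.coverage}"
            )


@dataclass(frozen=True)
class BinAssignment:
    """Result of the vote for one scaffold.

    ``vote_fraction`` is the winning fraction, or the best losing fraction
    when the scaffold ends up NotAnnotated; ``n_votes`` is the number of
    annotated genes that took part.
    """

    scaffold_id: str
    bin: str
    vote_fraction: float
    n_votes: int


def filter_scaffolds(
    scaffolds: list[ScaffoldRecord], min_len: int = 1000
) -> list[ScaffoldRecord]:
    """Retain scaffolds strictly longer than ``min_len`` bp, order preserved.

    The default drops everything at or below 1 kb, the usual cutoff below
    which gene-vote classification is unreliable.
    """
    if min_len < 0:
        raise ValueError(f"min_len must be >= 0, got {min_len}")
    return [s for s in scaffolds if s.length > min_len]


def collapse_to_superkingdom(taxon: str) -> str:
    """Collapse a lineage string to its top rank.

    Lineages may be semicolon-delimited (``"Eukaryota; Metazoa; Porifera"``);
    the first field is the superkingdom.  Bare labels pass through.
    """
    return taxon.split(";")[0].strip()


def vote_scaffold_taxon(
    calls: list[GeneTaxCall],
    min_fraction: float = 0.5,
    rank: str = "superkingdom",
) -> BinAssignment:
    """Assign one scaffold by plurality vote over its gene calls.

    The scaffold takes the taxon with the most votes among annotated genes,
    provided that taxon is one of :data:`ASSIGNABLE_TAXA`, is the *unique*
    plurality winner, and its vote fraction reaches ``min_fraction``.
    A tied plurality, a sub-threshold winner, or zero annotated genes all
    yield NotAnnotated.  Requiring a unique plurality (rather than any taxon
    above threshold) makes the outcome monotone in ``min_fraction``: raising
    the threshold can only demote scaffolds toward NotAnnotated.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if rank != "superkingdom":
        raise ValueError(f"unsupported voting rank: {rank!r}")
    if not calls:
        return BinAssignment("", NOT_ANNOTATED, 0.0, 0)
    scaffold_ids = {c.scaffold_id for c in calls}
    if len(scaffold_ids) > 1:
        raise ValueError(
            "vote_scaffold_taxon got calls from multiple scaffolds: "
            + ", ".join(sorted(scaffold_ids))
        )
    (scaffold_id,) = scaffold_ids

    votes = Counter(collapse_to_superkingdom(c.taxon) for c in calls)
    total = sum(votes.values())
    assignable = {t: n for t, n in votes.items() if t in ASSIGNABLE_TAXA}
    if not assignable:
        return BinAssignment(scaffold_id, NOT_ANNOTATED, 0.0, total)

    top_count = max(assignable.values())
    winners = sorted(t for t, n in assignable.items() if n == top_count)
    fraction = top_count / total
    if len(winners) == 1 and fraction >= min_fraction:
        return BinAssignment(scaffold_id, winners[0], fraction, total)
    return BinAssignment(scaffold_id, NOT_ANNOTATED, fraction, total)


def bin_metagenome(
    scaffolds: list[ScaffoldRecord],
    calls: list[GeneTaxCall],
    min_fraction: float = 0.5,
    min_len: int = 1000,
) -> tuple[list[BinAssignment], dict]:
    """Classify every retained scaffold and summarise the four groups.

    Returns the per-scaffold assignments plus a summary mapping each bin to
    its scaffold count, total bp and member list.  Calls referring to
    scaffolds absent from ``scaffolds`` are a contract violation.
    """
    known = {s.scaffold_id for s in scaffolds}
    orphans = sorted({c.scaffold_id for c in calls} - known)
    if orphans:
        raise ValueError(
            "gene calls reference unknown scaffolds: " + ", ".join(orphans)
        )

    retained = filter_scaffolds(scaffolds, min_len=min_len)
    by_scaffold: dict[str, list[GeneTaxCall]] = {}
    for c in calls:
        by_scaffold.setdefault(c.scaffold_id, []).append(c)

    assignments = []
    for s in retained:
        scalls = by_scaffold.get(s.scaffold_id, [])
        if scalls:
            a = vote_scaffold_taxon(scalls, min_fraction=min_fraction)
        else:
            a = BinAssignment(s.scaffold_id, NOT_ANNOTATED, 0.0, 0)
        assignments.append(a)

    lengths = {s.scaffold_id: s.length for s in retained}
    summary: dict[str, dict] = {
        b: {"n_scaffolds": 0, "total_bp": 0, "scaffold_ids": []}
        for b in (*ASSIGNABLE_TAXA, NOT_ANNOTATED)
    }
    for a in assignments:
        entry = summary[a.bin]
        entry["n_scaffolds"] += 1
        entry["total_bp"] += lengths[a.scaffold_id]
        entry["scaffold_ids"].append(a.scaffold_id)
    return assignments, summary
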