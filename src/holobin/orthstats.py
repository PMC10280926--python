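"""Core/pan-genome partitioning of orthogroup membership matrices.

An orthogroup matrix records, for each gene family, how many members each
species contributes.  With a species -> genus map the families partition
into the core genome (present in every genus, or every species in the
stricter mode), genus-restricted families, and species-specific families;
with an external-match flag column the lineage-specific fraction of the
core can be counted.  A focal-species contrast reports the families a
genome of interest lacks relative to all other species, the families
private to it, and its pairwise sharing percentages.

Percentages are computed over the denominators conventional for each
statistic (total families for core/single-genus fractions, core families
for lineage specificity, the focal species' families for sharing) and
rounded half-away-from-zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rbh import ProteinSeq, best_hit

__all__ = [
    "OrthoMatrix",
    "PartitionReport",
    "FocalReport",
    "round_percent",
    "core_pan_partition",
    "lineage_specific_core",
    "focal_contrast",
    "assignment_rate",
    "category_rollup",
    "cluster_rbh",
]


def round_percent(x: float, ndigits: int = 0) -> float:
    """Round a percentage half away from zero (14.55 -> 14.6, 28.5 -> 29)."""
    scale = 10**ndigits
    y = np.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return float(y) if ndigits else int(y) * 1.0


@dataclass
class OrthoMatrix:
    """Orthogroup x species membership counts with lineage metadata.

    ``counts`` is a DataFrame indexed by group id with one integer column
    per species.  ``genus_map`` must cover every species.  Optional:
    ``lineage_map`` (species -> higher lineage), ``external_match``
    (group -> True when the family has a match outside the lineage under
    study), ``species_totals`` (species -> total predicted genes, for
    assignment rates).
    """

    counts: pd.DataFrame
    genus_map: dict[str, str]
    lineage_map: dict[str, str] = field(default_factory=dict)
    external_match: dict[str, bool] = field(default_factory=dict)
    species_totals: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = sorted(set(self.counts.columns) - set(self.genus_map))
        if missing:
            raise ValueError(
                "species missing from the genus map: " + ", ".join(missing)
            )
        if (self.counts.values < 0).any():
            raise ValueError("orthogroup member counts must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_groups(self) -> int:
        return len(self.counts)

    def genera(self) -> list[str]:
        return sorted({self.genus_map[s] for s in self.species})


@dataclass
class PartitionReport:
    """Counts of the core/pan partition with percent accessors."""

    n_groups: int
    level: str
    core: int
    single_genus: int
    single_species: int
    per_genus_restricted: dict[str, int]
    core_group_ids: list[str]

    @property
    def core_percent(self) -> float:
        return self.core / self.n_groups * 100 if self.n_groups else 0.0

    @property
    def single_genus_percent(self) -> float:
        return self.single_genus / self.n_groups * 100 if self.n_groups else 0.0

    def genus_restricted_percent(self, genus: str) -> float:
        if not self.n_groups:
            return 0.0
        return self.per_genus_restricted.get(genus, 0) / self.n_groups * 100

    def headline(self) -> dict:
        """Integer-rounded headline percentages plus raw counts."""
        top_genus = max(
            self.per_genus_restricted,
            key=lambda g: (self.per_genus_restricted[g], g),
            default=None,
        )
        out = {
            "n_groups": self.n_groups,
            "core": self.core,
            "core_percent": round_percent(self.core_percent),
            "single_genus": self.single_genus,
            "single_genus_percent": round_percent(self.single_genus_percent),
            "single_species": self.single_species,
        }
        if top_genus is not None:
            out["top_restricted_genus"] = top_genus
            out["top_restricted_count"] = self.per_genus_restricted[top_genus]
            out["top_restricted_percent"] = round_percent(
                self.genus_restricted_percent(top_genus)
            )
        return out


@dataclass
class FocalReport:
    absent_in_focal_present_in_all_others: int
    focal_specific: int
    shared_percent: dict[str, float]


def core_pan_partition(matrix: OrthoMatrix, level: str = "genus") -> PartitionReport:
    """Partition orthogroups into core and restricted categories.

    ``level="genus"``: a core family has at least one member in every
    genus; ``level="species"``: in every species.  ``single_genus`` counts
    families confined to one genus (which includes every single-species
    family); ``per_genus_restricted`` breaks those down by genus.
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    if matrix.n_groups == 0:
        return PartitionReport(0, level, 0, 0, 0, {}, [])
    present = matrix.counts.values > 0
    species = matrix.species
    genera = np.array([matrix.genus_map[s] for s in species])
    genus_names = sorted(set(genera))
    # group x genus presence
    genus_present = np.column_stack(
        [present[:, genera == g].any(axis=1) for g in genus_names]
    )
    if level == "genus":
        core_mask = genus_present.all(axis=1)
    else:
        core_mask = present.all(axis=1)
    n_genera_hit = genus_present.sum(axis=1)
    nonempty = present.any(axis=1)
    single_genus_mask = nonempty & (n_genera_hit == 1)
    single_species_mask = nonempty & (present.sum(axis=1) == 1)

    per_genus: dict[str, int] = {}
    for gi, g in enumerate(genus_names):
        per_genus[g] = int((single_genus_mask & genus_present[:, gi]).sum())
    return PartitionReport(
        n_groups=matrix.n_groups,
        level=level,
        core=int(core_mask.sum()),
        single_genus=int(single_genus_mask.sum()),
        single_species=int(single_species_mask.sum()),
        per_genus_restricted=per_genus,
        core_group_ids=[str(g) for g in matrix.counts.index[core_mask]],
    )


def lineage_specific_core(
    matrix: OrthoMatrix, level: str = "genus"
) -> tuple[int, float]:
    """Core families with no match outside the lineage: (count, % of core).

    Requires the matrix's external-match flags to cover every core group;
    the flag records whether the family was found in any species outside
    the lineage under study (a database annotation, supplied not
    recomputed).  Percent is over the core count, one decimal.
    """
    report = core_pan_partition(matrix, level=level)
    missing = [g for g in report.core_group_ids if g not in matrix.external_match]
    if missing:
        raise ValueError(
            "external-match flags missing for core groups: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )
    count = sum(1 for g in report.core_group_ids if not matrix.external_match[g])
    percent = round_percent(count / report.core * 100, 1) if report.core else 0.0
    return count, percent


def focal_contrast(matrix: OrthoMatrix, focal: str) -> FocalReport:
    """Contrast one species of interest against all others.

    Reports families absent from the focal species but present in *every*
    other species (candidate losses), families private to the focal
    species, and the percent of the focal species' families shared with
    each other species.
    """
    if focal not in matrix.counts.columns:
        raise ValueError(f"unknown focal species: {focal!r}")
    present = matrix.counts > 0
    focal_present = present[focal]
    others = [s for s in matrix.species if s != focal]
    all_others = present[others].all(axis=1) if others else pd.Series(False, index=present.index)
    absent_in_focal = int((~focal_present & all_others).sum())
    any_other = present[others].any(axis=1) if others else pd.Series(False, index=present.index)
    focal_specific = int((focal_present & ~any_other).sum())
    n_focal = int(focal_present.sum())
    shared = {}
    for s in others:
        inter = int((focal_present & present[s]).sum())
        shared[s] = inter / n_focal * 100 if n_focal else 0.0
    return FocalReport(absent_in_focal, focal_specific, shared)


def assignment_rate(matrix: OrthoMatrix) -> tuple[dict[str, float | None], float]:
    """Percent of each species' genes assigned to orthogroups, plus global.

    Uses the matrix's per-species gene totals.  A species with zero
    recorded genes gets None (the rate is undefined, not zero); assigned
    counts exceeding the recorded total are a contract violation.
    """
    if not matrix.species_totals:
        raise ValueError("assignment_rate requires per-species gene totals")
    assigned = matrix.counts.sum(axis=0)
    per_species: dict[str, float | None] = {}
    tot_assigned = 0
    tot_genes = 0
    for s in matrix.species:
        total = matrix.species_totals.get(s, 0)
        a = int(assigned.get(s, 0))
        if a > total:
            raise ValueError(
                f"species {s}: assigned genes ({a}) exceed recorded total ({total})"
            )
        if total == 0:
            per_species[s] = None
            continue
        per_species[s] = a / total * 100
        tot_assigned += a
        tot_genes += total
    global_rate = tot_assigned / tot_genes * 100 if tot_genes else 0.0
    return per_species, global_rate


def category_rollup(
    group_ids: list[str], category_map: dict[str, str]
) -> dict[str, tuple[int, float]]:
    """Tally functional categories over a set of groups: name -> (n, %)."""
    n = len(group_ids)
    tallies: dict[str, int] = {}
    for g in group_ids:
        cat = category_map.get(g, "unknown")
        tallies[cat] = tallies.get(cat, 0) + 1
    return {
        cat: (cnt, cnt / n * 100 if n else 0.0) for cat, cnt in sorted(tallies.items())
    }


def cluster_rbh(
    proteomes: dict[str, list[ProteinSeq]],
    min_score: int = 60,
    genus_map: dict[str, str] | None = None,
    **align_kw,
) -> OrthoMatrix:
    """Build an orthogroup matrix from reciprocal best hits between proteomes.

    For every species pair, proteins that are each other's best hit are
    linked; connected components of the resulting graph become orthogroups.
    This is a transparent surrogate for Markov-clustering orthology tools,
    not a reimplementation of them: components can chain paralogs that MCL
    would split.  Singleton proteins (no reciprocal partner) are left
    unassigned, as orthology tools leave them out of groups.
    """
    import networkx as nx

    if len(proteomes) < 2:
        raise ValueError("cluster_rbh needs at least two proteomes")
    for sp, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome: {sp}")
    species = sorted(proteomes)
    graph = nx.Graph()
    forward: dict[tuple[str, str, str], str | None] = {}
    for a in species:
        for b in species:
            if a == b:
                continue
            for p in proteomes[a]:
                hit = best_hit(p, proteomes[b], min_score, **align_kw)
                forward[(a, b, p.id)] = hit.target_id if hit else None
    for ia, a in enumerate(species):
        for b in species[ia + 1 :]:
            for p in proteomes[a]:
                t = forward[(a, b, p.id)]
                if t is not None and forward[(b, a, t)] == p.id:
                    graph.add_edge((a, p.id), (b, t))
    rows = []
    for gi, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: min(c))
    ):
        row = {s: 0 for s in species}
        for sp, _pid in comp:
            row[sp] += 1
        rows.append(pd.Series(row, name=f"OG{gi:05d}"))
    counts = (
        pd.DataFrame(rows).fillna(0).astype(int)
        if rows
        else pd.DataFrame(columns=species, dtype=int)
    )
    genus_map = genus_map or {s: s for s in species}
    totals = {s: len(proteomes[s]) for s in species}
    return OrthoMatrix(counts=counts, genus_map=genus_map, species_totals=totals)
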