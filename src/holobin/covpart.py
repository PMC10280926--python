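"""Coverage-based genome separation within a holobiont assembly.

In a metagenome sequenced from one host individual, read depth is
proportional to genome copy number: the host nuclear genome sits at one
coverage, an abundant intracellular symbiont at a much higher one, and
organelles higher still.  Clustering scaffolds on log-coverage therefore
splits a taxon bin into its constituent genomes, and the ratio of symbiont
to host coverage — multiplied by host ploidy — estimates symbiont cells per
host cell.

The 1-D clustering is exact: dynamic-programming segmentation of the sorted
log2 coverages minimising total within-group sum of squares (the optimal
partition in one dimension is always contiguous in sorted order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .taxbin import ScaffoldRecord

__all__ = [
    "GenomeBin",
    "CellRatioEstimate",
    "weighted_mean_coverage",
    "split_by_coverage",
    "choose_k",
    "symbiont_cell_ratio",
    "round_half_away",
]


@dataclass
class GenomeBin:
    """A named set of scaffolds treated as one genome."""

    name: str
    scaffold_ids: list[str]
    total_length: int
    mean_coverage: float
    n_scaffolds: int


@dataclass
class CellRatioEstimate:
    """Symbiont abundance per host cell inferred from coverage.

    ``ratio`` is symbiont coverage over host coverage times host ploidy
    (coverage counts genome copies; a diploid host carries two nuclear
    copies per cell); ``rounded`` is the nearest integer, half away from
    zero.
    """

    symbiont_bin: str
    host_bin: str
    host_ploidy: int
    ratio: float
    rounded: int


def weighted_mean_coverage(scaffolds: list[ScaffoldRecord]) -> float:
    """Length-weighted mean coverage, sum(len*cov)/sum(len)."""
    if not scaffolds:
        raise ValueError("weighted_mean_coverage: empty scaffold list")
    num = sum(s.length * s.coverage for s in scaffolds)
    den = sum(s.length for s in scaffolds)
    return num / den


def _segment_cost(values: np.ndarray) -> np.ndarray:
    """cost[i, j] = within-group SS of sorted values[i:j+1] (inclusive)."""
    n = len(values)
    ps = np.concatenate([[0.0], np.cumsum(values)])
    ps2 = np.concatenate([[0.0], np.cumsum(values**2)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    s = ps[j + 1] - ps[i]
    s2 = ps2[j + 1] - ps2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = s2 - s**2 / cnt
    cost[cnt < 1] = np.inf
    # guard tiny negative residue from cancellation
    return np.maximum(cost, 0.0)


def _optimal_segmentation(values: np.ndarray, k: int) -> list[np.ndarray]:
    """Split sorted ``values`` into k contiguous runs minimising total SS."""
    n = len(values)
    cost = _segment_cost(values)
    # D[m, j] = best cost of splitting values[0:j+1] into m+1 runs
    D = np.full((k, n), np.inf)
    back = np.zeros((k, n), dtype=int)
    D[0] = cost[0]
    for m in range(1, k):
        for j in range(m, n):
            cand = D[m - 1, m - 1 : j] + cost[m : j + 1, j]
            i = int(np.argmin(cand))
            D[m, j] = cand[i]
            back[m, j] = i + m  # start index of the final run
    bounds = []
    j = n - 1
    for m in range(k - 1, -1, -1):
        start = back[m, j] if m > 0 else 0
        bounds.append((start, j))
        j = start - 1
    bounds.reverse()
    return [np.arange(a, b + 1) for a, b in bounds]


def split_by_coverage(scaffolds: list[ScaffoldRecord], k: int) -> list[GenomeBin]:
    """Partition scaffolds into ``k`` coverage groups.

    Clusters log2(coverage + 1) by exact DP segmentation; the returned bins
    are labelled ``covbin1`` (highest mean coverage) downward.  Scale-free:
    multiplying all coverages by a constant leaves the grouping unchanged
    up to the +1 offset, which is negligible at assembly-scale depths.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not scaffolds:
        raise ValueError("split_by_coverage: empty scaffold list")
    if k > len(scaffolds):
        raise ValueError(
            f"k={k} exceeds number of scaffolds ({len(scaffolds)})"
        )
    cov = np.array([s.coverage for s in scaffolds], dtype=float)
    order = np.argsort(cov, kind="stable")
    logv = np.log2(cov[order] + 1.0)
    runs = _optimal_segmentation(logv, k)

    groups = []
    for run in runs:
        members = [scaffolds[order[i]] for i in run]
        groups.append(members)
    groups.sort(key=lambda ms: -weighted_mean_coverage(ms))
    bins = []
    for rank, members in enumerate(groups, start=1):
        bins.append(
            GenomeBin(
                name=f"covbin{rank}",
                scaffold_ids=[m.scaffold_id for m in members],
                total_length=sum(m.length for m in members),
                mean_coverage=weighted_mean_coverage(members),
                n_scaffolds=len(members),
            )
        )
    return bins


def choose_k(
    scaffolds: list[ScaffoldRecord], k_max: int = 6, gain_threshold: float = 0.05
) -> int:
    """Pick the number of coverage groups by an explained-variance elbow.

    Splits are added while each extra group removes at least
    ``gain_threshold`` of the total log-coverage variance; deterministic
    and adequate for the well-separated coverage strata this package
    targets.
    """
    n = len(scaffolds)
    if n == 0:
        raise ValueError("choose_k: empty scaffold list")
    k_max = min(k_max, n)
    cov = np.sort(np.log2(np.array([s.coverage for s in scaffolds]) + 1.0))
    total_ss = float(np.sum((cov - cov.mean()) ** 2))
    if total_ss == 0.0:
        return 1
    prev_ss = total_ss
    k = 1
    while k < k_max:
        runs = _optimal_segmentation(cov, k + 1)
        ss = sum(float(np.sum((cov[r] - cov[r].mean()) ** 2)) for r in runs)
        if (prev_ss - ss) / total_ss < gain_threshold:
            break
        prev_ss = ss
        k += 1
    return k


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (12.5 -> 13)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def symbiont_cell_ratio(
    symbiont_cov: float,
    host_cov: float,
    host_ploidy: int = 2,
    symbiont_bin: str = "symbiont",
    host_bin: str = "host-nuclear",
) -> CellRatioEstimate:
    """Estimate symbiont cells per host cell from genome coverages.

    ``ratio = symbiont_cov / host_cov * host_ploidy``: coverage measures
    genome copies per unit of sampled tissue, so dividing by host coverage
    gives symbiont genomes per host genome copy, and the ploidy factor
    converts host genome copies to host cells (default 2, a diploid host).
    """
    if host_cov <= 0:
        raise ValueError(f"host coverage must be > 0, got {host_cov}")
    if host_ploidy < 1:
        raise ValueError(f"host ploidy must be >= 1, got {host_ploidy}")
    if symbiont_cov < 0:
        raise ValueError(f"symbiont coverage must be >= 0, got {symbiont_cov}")
    ratio = symbiont_cov / host_cov * host_ploidy
    return CellRatioEstimate(
        symbiont_bin=symbiont_bin,
        host_bin=host_bin,
        host_ploidy=host_ploidy,
        ratio=ratio,
        rounded=round_half_away(ratio),
    )
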