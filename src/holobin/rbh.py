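"""Reciprocal-best-hit presence/absence survey of candidate gene families.

A candidate family is searched against a predicted proteome with exact
Smith-Waterman local alignment (affine gaps, BLOSUM62 by default).  The
best hit is then aligned back against the query proteome: the family is
called *present* when the reciprocal search returns the original query,
*ambiguous* when a forward hit exists but reciprocity fails (the classic
signature of hitting a paralog), and *absent* when nothing reaches the
score threshold.

Significance is a raw-score threshold rather than an e-value: e-values
depend on the size of the searched database and are not comparable across
proteomes.  A Karlin-Altschul e-value estimate is available as an optional
report column (:func:`karlin_altschul_evalue`) but never drives calls.

The alignment kernel is exact full-matrix dynamic programming (no heuristic
seeding), jit-compiled with numba.  Tie-breaking is fully deterministic:
the traceback starts at the highest-scoring cell, ties resolved toward the
smallest target index then the smallest query index, and prefers diagonal
over target-gap over query-gap moves.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

__all__ = [
    "PROTEIN_ALPHABET",
    "ProteinSeq",
    "AlignmentHit",
    "PresenceCall",
    "load_score_matrix",
    "local_align",
    "align_score",
    "best_hit",
    "reciprocal_best_hit",
    "survey",
    "karlin_altschul_evalue",
]

#: The 20 standard residues plus X (unknown).  X scores 0 against
#: everything, including itself, so runs of unknown sequence neither help
#: nor hurt an alignment.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVX"

_INDEX = {c: i for i, c in enumerate(PROTEIN_ALPHABET)}


@dataclass(frozen=True)
class ProteinSeq:
    """An identified amino-acid sequence (uppercase, 20 residues + X)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.residues) - set(PROTEIN_ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: residues outside alphabet: "
                + ", ".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a target.

    Spans are half-open on the original sequences; ``identity`` is the
    fraction of identical residues over all alignment columns, gap columns
    included (the BLAST convention).
    """

    query_id: str
    target_id: str
    score: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity: float


@dataclass(frozen=True)
class PresenceCall:
    """Survey verdict for one candidate family."""

    family: str
    status: str  # present | absent | ambiguous
    best_hit: AlignmentHit | None
    reciprocal_ok: bool


@lru_cache(maxsize=4)
def load_score_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Substitution matrix over :data:`PROTEIN_ALPHABET` as int64.

    Loaded from Biopython's published tables, then the X row/column is
    zeroed per this package's convention.
    """
    src = substitution_matrices.load(name)
    n = len(PROTEIN_ALPHABET)
    sub = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            sub[i, j] = int(src[a, b])
    x = _INDEX["X"]
    sub[x, :] = 0
    sub[:, x] = 0
    return sub


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        bytes(_INDEX[c] for c in seq), dtype=np.uint8
    ).astype(np.int64)


_NEG = -(10**9)


@njit(cache=True)
def _sw_fill(q, t, sub, gap_open, gap_ext):
    """Affine-gap Smith-Waterman matrices.

    H = best local score ending at (i, j); E = ending with a gap in the
    query (target residue unmatched); F = gap in the target.  A gap of
    length L costs gap_open + gap_ext * L.
    """
    n = q.shape[0]
    m = t.shape[0]
    H = np.zeros((n + 1, m + 1), np.int64)
    E = np.full((n + 1, m + 1), _NEG, np.int64)
    F = np.full((n + 1, m + 1), _NEG, np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - gap_open - gap_ext, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - gap_open - gap_ext, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    return H, E, F


@njit(cache=True)
def _sw_score(q, t, sub, gap_open, gap_ext):
    """Score-only Smith-Waterman with O(m) memory; used for hit ranking."""
    n = q.shape[0]
    m = t.shape[0]
    Hprev = np.zeros(m + 1, np.int64)
    Hcur = np.zeros(m + 1, np.int64)
    Eprev = np.full(m + 1, _NEG, np.int64)
    Fprev = np.full(m + 1, _NEG, np.int64)
    best = 0
    for i in range(1, n + 1):
        Hcur[0] = 0
        ecur = _NEG
        for j in range(1, m + 1):
            ecur = max(Hcur[j - 1] - gap_open - gap_ext, ecur - gap_ext)
            f = max(Hprev[j] - gap_open - gap_ext, Fprev[j] - gap_ext)
            h = Hprev[j - 1] + sub[q[i - 1], t[j - 1]]
            if ecur > h:
                h = ecur
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hcur[j] = h
            Eprev[j] = ecur
            Fprev[j] = f
            if h > best:
                best = h
        Hprev, Hcur = Hcur, Hprev
    return best


def align_score(
    a: ProteinSeq,
    b: ProteinSeq,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal local alignment score only (fast path, no traceback)."""
    sub = load_score_matrix(matrix)
    return int(_sw_score(_encode(a.residues), _encode(b.residues), sub, gap_open, gap_extend))


def local_align(
    a: ProteinSeq,
    b: ProteinSeq,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of query ``a`` vs target ``b``.

    Returns the alignment hit with score, half-open spans and identity.
    When no cell scores above zero (sequences share nothing alignable),
    the hit has score 0 and empty spans.
    """
    sub = load_score_matrix(matrix)
    q = _encode(a.residues)
    t = _encode(b.residues)
    H, E, F = _sw_fill(q, t, sub, gap_open, gap_extend)

    score = int(H.max())
    if score == 0:
        return AlignmentHit(a.id, b.id, 0, (0, 0), (0, 0), 0.0)
    # highest-scoring cell; ties -> smallest target index, then query index
    cells = np.argwhere(H == score)
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i, j = (int(v) for v in cells[order[0]])

    matches = 0
    columns = 0
    end_i, end_j = i, j
    state = "H"
    while H[i, j] > 0 or state != "H":
        if state == "H":
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if H[i, j] == diag:
                matches += int(q[i - 1] == t[j - 1])
                columns += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_extend:
                state = "H"
            j -= 1
        else:  # F
            columns += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_extend:
                state = "H"
            i -= 1
    return AlignmentHit(
        query_id=a.id,
        target_id=b.id,
        score=score,
        query_span=(i, end_i),
        target_span=(j, end_j),
        identity=matches / columns if columns else 0.0,
    )


def best_hit(
    query: ProteinSeq,
    proteome: list[ProteinSeq],
    min_score: int = 60,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentHit | None:
    """Highest-scoring qualifying hit of ``query`` in ``proteome``.

    Equal scores are broken by lexicographically smallest target id.
    Returns None when nothing reaches ``min_score``.
    """
    if not proteome:
        return None
    sub = load_score_matrix(matrix)
    q = _encode(query.residues)
    best: tuple[int, str] | None = None
    best_target = None
    for target in proteome:
        s = int(_sw_score(q, _encode(target.residues), sub, gap_open, gap_extend))
        if s < min_score:
            continue
        key = (-s, target.id)
        if best is None or key < best:
            best = key
            best_target = target
    if best_target is None:
        return None
    return local_align(query, best_target, matrix, gap_open, gap_extend)


def reciprocal_best_hit(
    query: ProteinSeq,
    queryome: list[ProteinSeq],
    targetome: list[ProteinSeq],
    min_score: int = 60,
    **align_kw,
) -> tuple[bool, AlignmentHit | None, AlignmentHit | None]:
    """Forward/backward best-hit check for one query.

    ``reciprocal_ok`` is True iff the forward best hit exists and its own
    best hit back in ``queryome`` is the original query.
    """
    if not any(p.id == query.id for p in queryome):
        raise ValueError(f"query {query.id!r} is not a member of the queryome")
    forward = best_hit(query, targetome, min_score, **align_kw)
    if forward is None:
        return False, None, None
    target = next(p for p in targetome if p.id == forward.target_id)
    backward = best_hit(target, queryome, min_score, **align_kw)
    ok = backward is not None and backward.target_id == query.id
    return ok, forward, backward


def survey(
    panel: dict[str, ProteinSeq | list[ProteinSeq]],
    queryome: list[ProteinSeq],
    targetome: list[ProteinSeq],
    min_score: int = 60,
    motif_filters: dict[str, str] | None = None,
    **align_kw,
) -> list[PresenceCall]:
    """Presence/absence calls for a panel of candidate families.

    Each family maps to one or more query proteins drawn from the
    queryome.  A family is *present* when any of its queries passes the
    reciprocal-best-hit check (and, if a motif filter is configured for
    that family, the hit target matches the motif); *absent* when no query
    has a forward hit at ``min_score``; *ambiguous* otherwise.

    ``motif_filters`` is an optional family -> regular-expression hook for
    secondary sequence-feature checks; it ships empty.
    """
    if not panel:
        raise ValueError("survey: empty panel")
    motif_filters = motif_filters or {}
    target_by_id = {p.id: p for p in targetome}
    calls = []
    for family in panel:
        queries = panel[family]
        if isinstance(queries, ProteinSeq):
            queries = [queries]
        status = "absent"
        chosen: AlignmentHit | None = None
        reciprocal_ok = False
        for query in queries:
            ok, forward, _backward = reciprocal_best_hit(
                query, queryome, targetome, min_score, **align_kw
            )
            if forward is None:
                continue
            if ok and family in motif_filters:
                ok = bool(
                    re.search(motif_filters[family], target_by_id[forward.target_id].residues)
                )
            if ok:
                status, chosen, reciprocal_ok = "present", forward, True
                break
            if status == "absent":
                status, chosen = "ambiguous", forward
        calls.append(PresenceCall(family, status, chosen, reciprocal_ok))
    return calls


def presence_matrix(calls: list[PresenceCall]) -> dict[str, str]:
    """Family -> one-letter presence code (P/A/?) for tabular output."""
    code = {"present": "P", "absent": "A", "ambiguous": "?"}
    return {c.family: code[c.status] for c in calls}


def karlin_altschul_evalue(
    score: int, query_len: int, db_len: int, K: float = 0.041, lam: float = 0.267
) -> float:
    """Karlin-Altschul e-value estimate, E = K*m*n*exp(-lambda*S).

    Default constants are the published gapped BLOSUM62 (open 11 / extend 1)
    values.  Reported for orientation only; calls use raw scores.
    """
    return K * query_len * db_len * math.exp(-lam * score)
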