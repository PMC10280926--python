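"""Local alignment kernel and reciprocal-best-hit survey.

The Smith-Waterman scores are cross-checked against Biopython's
PairwiseAligner configured with the same matrix and affine gap model — an
independent full-DP implementation of the same optimisation problem.
"""

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from hypothesis import given, settings
from hypothesis import strategies as st

from holobin.rbh import (
    PROTEIN_ALPHABET,
    ProteinSeq,
    best_hit,
    karlin_altschul_evalue,
    load_score_matrix,
    local_align,
    reciprocal_best_hit,
    survey,
)
from holobin.synthetic import generate_protein_panel


def oracle_aligner(gap_open=11, gap_extend=1):
    base = substitution_matrices.load("BLOSUM62")
    letters = PROTEIN_ALPHABET
    arr = substitution_matrices.Array(alphabet=letters, dims=2)
    for a in letters:
        for b in letters:
            arr[a, b] = 0.0 if "X" in (a, b) else float(base[a, b])
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = arr
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def oracle_score(a: str, b: str, **kw) -> int:
    return int(oracle_aligner(**kw).score(a, b))


class TestProteinSeq:
    def test_rejects_empty_and_bad_residues(self):
        with pytest.raises(ValueError):
            ProteinSeq("p", "")
        with pytest.raises(ValueError, match="[JO]"):
            ProteinSeq("p", "ACJO")


class TestLocalAlign:
    def test_blosum62_diagonal_sum(self):
        hit = local_align(ProteinSeq("a", "ACDE"), ProteinSeq("b", "ACDE"))
        assert hit.score == 24  # 4 + 9 + 6 + 5
        assert hit.identity == 1.0
        assert hit.query_span == (0, 4) and hit.target_span == (0, 4)

    def test_single_residue(self):
        assert local_align(ProteinSeq("a", "A"), ProteinSeq("b", "A")).score == 4

    def test_x_scores_zero(self):
        assert local_align(ProteinSeq("a", "XXXX"), ProteinSeq("b", "XXXX")).score == 0
        # X inside an alignment neither helps nor hurts the flanks
        hit = local_align(ProteinSeq("a", "WWXWW"), ProteinSeq("b", "WWXWW"))
        assert hit.score == 4 * 11  # four W/W pairs

    def test_self_alignment_dominates(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, 30))
            b = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, 30))
            pa, pb = ProteinSeq("a", a), ProteinSeq("b", b)
            assert local_align(pa, pa).score >= local_align(pa, pb).score

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 21, 25))
            b = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 21, 25))
            s1 = local_align(ProteinSeq("a", a), ProteinSeq("b", b)).score
            s2 = local_align(ProteinSeq("b", b), ProteinSeq("a", a)).score
            assert s1 == s2

    def test_gapped_alignment_against_oracle(self):
        a = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        b = "MKTAYIAKQISFVKSHFSRQLEERLGLIEVQ"  # two-residue deletion
        hit = local_align(ProteinSeq("a", a), ProteinSeq("b", b))
        assert hit.score == oracle_score(a, b)

    @given(
        a=st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=10),
        b=st.text(alphabet=PROTEIN_ALPHABET, min_size=1, max_size=10),
    )
    @settings(derandomize=True, max_examples=400)
    def test_matches_full_dp_oracle_combined_length_le_20(self, a, b):
        got = local_align(ProteinSeq("a", a), ProteinSeq("b", b)).score
        assert got == oracle_score(a, b)

    def test_identity_and_spans_consistent(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, 40))
            b = "".join(PROTEIN_ALPHABET[i] for i in rng.integers(0, 20, 40))
            hit = local_align(ProteinSeq("a", a), ProteinSeq("b", b))
            (qs, qe), (ts, te) = hit.query_span, hit.target_span
            assert 0 <= qs <= qe <= len(a) and 0 <= ts <= te <= len(b)
            assert 0.0 <= hit.identity <= 1.0


class TestBestHit:
    def make_proteome(self):
        return [
            ProteinSeq("t1", "MKTAYIAKQRQISFVKSHFSRQ"),
            ProteinSeq("t2", "GGGGGGGGGGGGGGGGGG"),
            ProteinSeq("t3", "PPPPPPPPPPPPPPPPPP"),
        ]

    def test_identical_target_wins(self):
        q = ProteinSeq("q", "MKTAYIAKQRQISFVKSHFSRQ")
        hit = best_hit(q, self.make_proteome(), min_score=40)
        assert hit.target_id == "t1"

    def test_below_threshold_returns_none(self):
        q = ProteinSeq("q", "WWWWW")
        assert best_hit(q, self.make_proteome(), min_score=60) is None

    def test_tie_broken_by_target_id(self):
        q = ProteinSeq("q", "MKTAYIAKQRQ")
        proteome = [
            ProteinSeq("t2", "MKTAYIAKQRQ"),
            ProteinSeq("t1", "MKTAYIAKQRQ"),
        ]
        assert best_hit(q, proteome, min_score=10).target_id == "t1"

    def test_raising_min_score_never_adds_hits(self):
        q = ProteinSeq("q", "MKTAYIAKQRQISFVKSHFSRQ")
        proteome = self.make_proteome()
        lo = best_hit(q, proteome, min_score=20)
        hi = best_hit(q, proteome, min_score=lo.score + 1)
        assert hi is None or hi.score > lo.score


class TestReciprocal:
    def test_true_ortholog_pair(self):
        q = ProteinSeq("q1", "MKTAYIAKQRQISFVKSHFSRQ")
        queryome = [q, ProteinSeq("q2", "GGGGGGGGGGGGGGGG")]
        targetome = [ProteinSeq("t1", "MKTAYIAKQRQISFVKSHFSRQ"),
                     ProteinSeq("t2", "PPPPPPPPPPPPPPPP")]
        ok, fwd, bwd = reciprocal_best_hit(q, queryome, targetome, min_score=40)
        assert ok and fwd.target_id == "t1" and bwd.target_id == "q1"

    def test_paralog_breaks_reciprocity(self):
        # the target's own best hit is a closer paralog of the query
        q = ProteinSeq("q1", "MKTAYIAKQRQISFVKSHFSRQAAAA")
        paralog = ProteinSeq("q0", "MKTAYIAKQRQISFVKSHFSRQWWCC")
        target = ProteinSeq("t1", "MKTAYIAKQRQISFVKSHFSRQWWCC")
        ok, fwd, bwd = reciprocal_best_hit(q, [q, paralog], [target], min_score=40)
        assert fwd.target_id == "t1"
        assert bwd.target_id == "q0"
        assert not ok

    def test_empty_targetome(self):
        q = ProteinSeq("q1", "MKTAYIAKQRQ")
        ok, fwd, _ = reciprocal_best_hit(q, [q], [], min_score=40)
        assert not ok and fwd is None

    def test_query_must_be_in_queryome(self):
        q = ProteinSeq("q1", "MKTAYIAKQRQ")
        with pytest.raises(ValueError, match="queryome"):
            reciprocal_best_hit(q, [ProteinSeq("other", "AAAA")], [], min_score=40)


class TestSurvey:
    def test_perfect_orthologs_all_present(self):
        p = generate_protein_panel(10, ortholog_identity=1.0, decoy_identity=0.0,
                                   decoy_fraction=0.0, seed=0)
        calls = survey(p.panel, p.queryome, p.targetome)
        assert all(c.status == "present" for c in calls)

    def test_constructed_absence(self, small_panel):
        calls = {c.family: c for c in survey(
            small_panel.panel, small_panel.queryome, small_panel.targetome)}
        absent_families = [f for f, present in small_panel.truth.family_present.items()
                           if not present]
        assert absent_families, "fixture should contain absent families"
        for f in absent_families:
            assert calls[f].status == "absent"

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            survey({}, [], [])

    def test_monotone_in_min_score(self, small_panel):
        lo = {c.family: c.status for c in survey(
            small_panel.panel, small_panel.queryome, small_panel.targetome, min_score=40)}
        hi = {c.family: c.status for c in survey(
            small_panel.panel, small_panel.queryome, small_panel.targetome, min_score=200)}
        for f in lo:
            if hi[f] == "present":
                assert lo[f] == "present"
            if lo[f] == "absent":
                assert hi[f] == "absent"

    def test_proteome_order_invariance(self, small_panel):
        fwd = survey(small_panel.panel, small_panel.queryome, small_panel.targetome)
        rev = survey(small_panel.panel, small_panel.queryome,
                     list(reversed(small_panel.targetome)))
        assert [(c.family, c.status) for c in fwd] == [(c.family, c.status) for c in rev]

    def test_motif_filter_demotes_presence(self, small_panel):
        present = [c.family for c in survey(
            small_panel.panel, small_panel.queryome, small_panel.targetome)
            if c.status == "present"]
        fam = present[0]
        calls = {c.family: c for c in survey(
            small_panel.panel, small_panel.queryome, small_panel.targetome,
            motif_filters={fam: "THISMOTIFNEVEROCCURS"})}
        assert calls[fam].status == "ambiguous"


def test_karlin_altschul_monotone_decreasing():
    e1 = karlin_altschul_evalue(50, 100, 10000)
    e2 = karlin_altschul_evalue(100, 100, 10000)
    assert e2 < e1 < 1e3
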