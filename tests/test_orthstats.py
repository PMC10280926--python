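"""Core/pan partitioning, focal contrasts and RBH clustering."""

import numpy as np
import pandas as pd
import pytest

from holobin.orthstats import (
    OrthoMatrix,
    assignment_rate,
    category_rollup,
    cluster_rbh,
    core_pan_partition,
    focal_contrast,
    lineage_specific_core,
    round_percent,
)
from holobin.rbh import ProteinSeq
from holobin.synthetic import generate_ortho_families, generate_protein_panel


def matrix_from_rows(rows, genus_map, **kw):
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else pd.DataFrame(rows)
    return OrthoMatrix(counts=df, genus_map=genus_map, **kw)


THREE_GENERA = {"s1": "G1", "s2": "G1", "s3": "G2", "s4": "G3"}


class TestPartition:
    def test_all_core_saturation(self):
        counts = pd.DataFrame(1, index=["g1", "g2"], columns=list(THREE_GENERA))
        rep = core_pan_partition(OrthoMatrix(counts, THREE_GENERA))
        assert rep.core == rep.n_groups == 2
        assert rep.single_genus == 0

    def test_three_genus_enumeration(self):
        counts = pd.DataFrame(
            [
                {"s1": 1, "s2": 0, "s3": 1, "s4": 1},  # spans all genera: core
                {"s1": 1, "s2": 1, "s3": 0, "s4": 0},  # G1 only
                {"s1": 0, "s2": 0, "s3": 1, "s4": 0},  # G2 only (single species)
            ],
            index=["g1", "g2", "g3"],
        )
        rep = core_pan_partition(OrthoMatrix(counts, THREE_GENERA))
        assert (rep.core, rep.single_genus) == (1, 2)
        assert round_percent(rep.core_percent) == 33
        assert round_percent(rep.single_genus_percent) == 67
        assert rep.per_genus_restricted == {"G1": 1, "G2": 1, "G3": 0}
        assert rep.single_species == 1

    def test_single_genus_counts_sum_with_multi_genus(self):
        m, _ = generate_ortho_families(
            10, {f"G{g}_s{i}": f"G{g}" for g in range(5) for i in (1, 2)},
            400, 0.25, 0.4, loss_rate=0.2, seed=9,
        )
        rep = core_pan_partition(m)
        present = m.counts.values > 0
        genera = np.array([m.genus_map[s] for s in m.species])
        hits = np.column_stack(
            [present[:, genera == g].any(axis=1) for g in sorted(set(genera))]
        ).sum(axis=1)
        multi = int((hits > 1).sum())
        assert sum(rep.per_genus_restricted.values()) == rep.single_genus
        assert rep.single_genus + multi == rep.n_groups

    def test_species_level_stricter_than_genus_level(self):
        counts = pd.DataFrame(
            [{"s1": 1, "s2": 0, "s3": 1, "s4": 1}], index=["g1"]
        )
        m = OrthoMatrix(counts, THREE_GENERA)
        assert core_pan_partition(m, level="genus").core == 1
        assert core_pan_partition(m, level="species").core == 0

    def test_row_and_column_permutation_invariance(self):
        m, _ = generate_ortho_families(
            6, {f"s{i}": f"G{i % 3}" for i in range(6)}, 200, 0.3, 0.3,
            loss_rate=0.1, seed=2,
        )
        rep = core_pan_partition(m)
        rng = np.random.default_rng(0)
        perm = m.counts.iloc[rng.permutation(len(m.counts))]
        perm = perm[list(np.array(m.species)[rng.permutation(len(m.species))])]
        rep2 = core_pan_partition(OrthoMatrix(perm, m.genus_map))
        assert (rep.core, rep.single_genus, rep.single_species) == (
            rep2.core, rep2.single_genus, rep2.single_species
        )

    def test_missing_genus_map_entry_rejected(self):
        counts = pd.DataFrame([{"s1": 1, "mystery": 1}])
        with pytest.raises(ValueError, match="mystery"):
            OrthoMatrix(counts, {"s1": "G1"})


class TestLineageSpecificCore:
    def test_all_matched_outside(self):
        counts = pd.DataFrame(1, index=["g1", "g2"], columns=list(THREE_GENERA))
        m = OrthoMatrix(counts, THREE_GENERA,
                        external_match={"g1": True, "g2": True})
        assert lineage_specific_core(m) == (0, 0.0)

    def test_one_of_eight(self):
        counts = pd.DataFrame(1, index=[f"g{i}" for i in range(8)],
                              columns=list(THREE_GENERA))
        flags = {f"g{i}": i != 0 for i in range(8)}
        m = OrthoMatrix(counts, THREE_GENERA, external_match=flags)
        assert lineage_specific_core(m) == (1, 12.5)

    def test_missing_flags_named(self):
        counts = pd.DataFrame(1, index=["g1"], columns=list(THREE_GENERA))
        m = OrthoMatrix(counts, THREE_GENERA)
        with pytest.raises(ValueError, match="g1"):
            lineage_specific_core(m)


class TestFocalContrast:
    def test_saturation(self):
        counts = pd.DataFrame(1, index=["g1", "g2"], columns=list(THREE_GENERA))
        fr = focal_contrast(OrthoMatrix(counts, THREE_GENERA), "s1")
        assert fr.absent_in_focal_present_in_all_others == 0

    def test_enumeration(self):
        # focal in {g1, g2}; all others in {g1, g3, g4, g5}; g2 focal-only
        species = {"f": "Gf", "a": "Ga", "b": "Gb", "c": "Gc"}
        counts = pd.DataFrame(
            {
                "f": [1, 1, 0, 0, 0],
                "a": [1, 0, 1, 1, 1],
                "b": [1, 0, 1, 1, 1],
                "c": [1, 0, 1, 1, 1],
            },
            index=[f"g{i}" for i in range(1, 6)],
        )
        fr = focal_contrast(OrthoMatrix(counts, species), "f")
        assert fr.absent_in_focal_present_in_all_others == 3
        assert fr.focal_specific == 1
        assert fr.shared_percent == {
            "a": pytest.approx(50.0), "b": pytest.approx(50.0), "c": pytest.approx(50.0)
        }

    def test_species_order_invariance(self):
        species = {"f": "Gf", "a": "Ga", "b": "Gb"}
        counts = pd.DataFrame(
            {"f": [1, 0, 1], "a": [1, 1, 0], "b": [0, 1, 1]},
            index=["g1", "g2", "g3"],
        )
        m1 = OrthoMatrix(counts, species)
        m2 = OrthoMatrix(counts[["b", "f", "a"]], species)
        f1, f2 = focal_contrast(m1, "f"), focal_contrast(m2, "f")
        assert (f1.absent_in_focal_present_in_all_others, f1.focal_specific) == (
            f2.absent_in_focal_present_in_all_others, f2.focal_specific
        )
        assert f1.shared_percent == f2.shared_percent

    def test_unknown_focal_rejected(self):
        counts = pd.DataFrame(1, index=["g1"], columns=list(THREE_GENERA))
        with pytest.raises(ValueError, match="nope"):
            focal_contrast(OrthoMatrix(counts, THREE_GENERA), "nope")


class TestAssignmentRate:
    def test_all_assigned(self):
        counts = pd.DataFrame({"s1": [2, 3], "s2": [1, 1]}, index=["g1", "g2"])
        m = OrthoMatrix(counts, {"s1": "G1", "s2": "G2"},
                        species_totals={"s1": 5, "s2": 2})
        per, glob = assignment_rate(m)
        assert per == {"s1": pytest.approx(100.0), "s2": pytest.approx(100.0)}
        assert glob == pytest.approx(100.0)

    def test_thirteen_of_twenty(self):
        counts = pd.DataFrame({"s1": [13]}, index=["g1"])
        m = OrthoMatrix(counts, {"s1": "G1"}, species_totals={"s1": 20})
        per, glob = assignment_rate(m)
        assert per["s1"] == pytest.approx(65.0)

    def test_zero_total_is_missing_not_zero(self):
        counts = pd.DataFrame({"s1": [1], "s2": [0]}, index=["g1"])
        m = OrthoMatrix(counts, {"s1": "G1", "s2": "G2"},
                        species_totals={"s1": 2, "s2": 0})
        per, _ = assignment_rate(m)
        assert per["s2"] is None

    def test_overassignment_rejected(self):
        counts = pd.DataFrame({"s1": [5]}, index=["g1"])
        m = OrthoMatrix(counts, {"s1": "G1"}, species_totals={"s1": 3})
        with pytest.raises(ValueError, match="exceed"):
            assignment_rate(m)


def test_category_rollup_percents():
    rollup = category_rollup(["g1", "g2", "g3", "g4"], {"g1": "transport", "g2": "transport"})
    assert rollup["transport"] == (2, pytest.approx(50.0))
    assert rollup["unknown"] == (2, pytest.approx(50.0))


class TestClusterRBH:
    def test_disjoint_identical_families(self):
        p = generate_protein_panel(6, ortholog_identity=1.0, decoy_identity=0.0,
                                   decoy_fraction=0.0, seed=1)
        proteomes = {"A": p.queryome, "B": p.targetome}
        m = cluster_rbh(proteomes, min_score=60)
        assert m.n_groups == 6
        assert (m.counts.values == 1).all()

    def test_shared_family_across_three_species(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        proteomes = {
            "A": [ProteinSeq("a1", seq)],
            "B": [ProteinSeq("b1", seq)],
            "C": [ProteinSeq("c1", seq)],
        }
        m = cluster_rbh(proteomes, min_score=60)
        assert m.n_groups == 1
        assert m.counts.iloc[0].tolist() == [1, 1, 1]

    def test_groups_match_generator_truth(self):
        p = generate_protein_panel(25, ortholog_identity=0.8, decoy_identity=0.3,
                                   decoy_fraction=0.3, seed=6)
        # keep only true orthologs + decoys as species B
        proteomes = {"A": p.queryome, "B": p.targetome}
        m = cluster_rbh(proteomes, min_score=60)
        pairs = m.counts[(m.counts["A"] == 1) & (m.counts["B"] == 1)]
        assert len(pairs) >= 0.95 * 25

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_rbh({"A": [ProteinSeq("a", "MKT")], "B": []})

    def test_single_proteome_rejected(self):
        with pytest.raises(ValueError):
            cluster_rbh({"A": [ProteinSeq("a", "MKT")]})
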