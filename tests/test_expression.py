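"""Deconvolution scores, interaction weights, proliferation, archetypes."""

import numpy as np
import pandas as pd
import pytest

from fibrocircuit import (
    ArchetypeSet,
    GeneSignature,
    archetype_occupancy_fold_change,
    cluster_fold_change,
    convex_decomposition,
    decompose_cells,
    fraction_normalize,
    interaction_graph,
    proliferation_score,
    score_correlation,
    signature_score,
    weighted_interaction,
    zone_fold_change,
)


class TestFractionNormalize:
    def test_columns_sum_to_one_and_scale_invariance(self):
        counts = pd.DataFrame({"s1": [10, 30, 60], "s2": [1, 1, 2]},
                              index=["g1", "g2", "g3"])
        frac = fraction_normalize(counts)
        np.testing.assert_allclose(frac.sum(axis=0), 1.0, atol=1e-12)
        assert frac["s1"].tolist() == [0.1, 0.3, 0.6]
        scaled = fraction_normalize(counts * 7)
        pd.testing.assert_frame_equal(frac, scaled)

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"ok": [1], "empty": [0]}, index=["g"])
        with pytest.raises(ValueError, match="empty"):
            fraction_normalize(counts)

    def test_duplicate_gene_rejected(self):
        counts = pd.DataFrame([[1], [2]], index=["g", "g"], columns=["s"])
        with pytest.raises(ValueError, match="g"):
            fraction_normalize(counts)


class TestSignatureScore:
    @pytest.fixture()
    def fractions(self):
        return pd.DataFrame({"s": [0.1, 0.3, 0.6]}, index=["g1", "g2", "g3"])

    def test_mean_and_sum_modes(self, fractions):
        sig = GeneSignature("mf", ["g1", "g2"])
        assert signature_score(fractions, sig, "mean")["s"] == pytest.approx(0.2)
        assert signature_score(fractions, sig, "sum")["s"] == pytest.approx(0.4)

    def test_order_and_duplicates_irrelevant(self, fractions):
        a = signature_score(fractions, GeneSignature("x", ["g2", "g1"]), "mean")
        b = signature_score(fractions, GeneSignature("x", ["g1", "g2", "g1"]), "mean")
        assert a["s"] == b["s"]

    def test_missing_genes_warn_and_no_overlap_errors(self, fractions):
        with pytest.warns(UserWarning):
            signature_score(fractions, GeneSignature("x", ["g1", "nope"]), "mean")
        with pytest.raises(ValueError):
            signature_score(fractions, GeneSignature("x", ["nope"]), "mean")

    def test_score_monotone_in_mixture_fraction(self):
        # two cell types with disjoint markers mixed at increasing fractions
        profile_a = np.array([0.5, 0.5, 0.0, 0.0])
        profile_b = np.array([0.0, 0.0, 0.5, 0.5])
        genes = ["a1", "a2", "b1", "b2"]
        scores = []
        for f in (0.1, 0.3, 0.5):
            mix = f * profile_a + (1 - f) * profile_b
            fr = pd.DataFrame({"s": mix}, index=genes)
            scores.append(signature_score(fr, GeneSignature("a", ["a1", "a2"]), "mean")["s"])
        assert scores[0] < scores[1] < scores[2]


class TestZoneFoldChange:
    def make_design(self, infarct_scores, remote_scores):
        rows, scores = [], {}
        for i, (inf, rem) in enumerate(zip(infarct_scores, remote_scores)):
            for zone, val in (("infarct", inf), ("remote", rem)):
                name = f"r{i}_{zone}"
                rows.append({"sample": name, "condition": "c", "timepoint": "t",
                             "zone": zone})
                scores[name] = val
        meta = pd.DataFrame(rows).set_index("sample")
        return pd.Series(scores), meta

    def test_identical_zones_fc_one(self):
        scores, meta = self.make_design([0.2, 0.2], [0.2, 0.2])
        out = zone_fold_change(scores, meta)
        assert out.loc[0, "fold_change"] == pytest.approx(1.0)

    def test_fold_change_of_group_means(self):
        scores, meta = self.make_design([0.3, 0.5], [0.1, 0.1])
        out = zone_fold_change(scores, meta)
        assert out.loc[0, "fold_change"] == pytest.approx(4.0)

    def test_zero_remote_flagged(self):
        scores, meta = self.make_design([0.3], [0.0])
        out = zone_fold_change(scores, meta)
        assert out.loc[0, "flagged"]
        assert np.isnan(out.loc[0, "fold_change"])


class TestInteraction:
    def test_cluster_fold_change_arithmetic(self):
        assert cluster_fold_change(5.0, 5.0) == 1.0
        assert cluster_fold_change(30.0, 10.0) == 3.0
        with pytest.raises(ValueError):
            cluster_fold_change(10.0, 0.0)

    @pytest.mark.parametrize("cs,cr,acts,expected", [
        (1.0, 1.0, [0.5], 0.5),
        (2.0, 3.0, [0.1, 0.2], 1.8),
        (0.0, 7.0, [0.9], 0.0),
    ])
    def test_weighted_interaction_formula(self, cs, cr, acts, expected):
        assert weighted_interaction(cs, cr, acts) == pytest.approx(expected)

    def test_self_loop_graph(self):
        ab = pd.DataFrame({"cell_type": ["mF", "mF"], "timepoint": ["d0", "d3"],
                           "percent_of_cells": [5.0, 15.0]})
        act = pd.DataFrame({"sender": ["mF"], "receiver": ["mF"], "ligand": ["l1"],
                            "activity": [0.4], "timepoint": ["d3"]})
        G = interaction_graph(ab, act, "d3", "d0")
        assert G.nodes["mF"]["fold_change"] == pytest.approx(3.0)
        assert G["mF"]["mF"]["weight"] == pytest.approx(3.0 * 3.0 * 0.4)

    def test_empty_activities_nodes_only(self):
        ab = pd.DataFrame({"cell_type": ["mF", "mF"], "timepoint": ["d0", "d3"],
                           "percent_of_cells": [5.0, 10.0]})
        act = pd.DataFrame(columns=["sender", "receiver", "ligand", "activity",
                                    "timepoint"])
        G = interaction_graph(ab, act, "d3", "d0")
        assert G.number_of_nodes() == 1 and G.number_of_edges() == 0

    def test_missing_abundance_names_cell_type(self):
        ab = pd.DataFrame({"cell_type": ["mF"], "timepoint": ["d3"],
                           "percent_of_cells": [5.0]})
        act = pd.DataFrame({"sender": ["mF"], "receiver": ["mF"], "ligand": ["l"],
                            "activity": [0.1], "timepoint": ["d3"]})
        with pytest.raises(KeyError, match="mF"):
            interaction_graph(ab, act, "d3", "d0")

    def test_bilinear_and_additive_over_ligand_partitions(self):
        acts = [0.1, 0.2, 0.3]
        w = weighted_interaction(2.0, 3.0, acts)
        assert w == pytest.approx(2.0 * weighted_interaction(1.0, 3.0, acts))
        assert w == pytest.approx(
            weighted_interaction(2.0, 3.0, acts[:1]) + weighted_interaction(2.0, 3.0, acts[1:])
        )


class TestProliferationScore:
    def test_retention_window_and_score(self):
        counts = pd.DataFrame(
            {"kept": [100, 900], "low": [50, 450], "high": [5000, 9000]},
            index=["cc1", "other"],
        )
        sig = GeneSignature("cell_cycle", ["cc1"])
        scores, retained = proliferation_score(counts, sig)
        assert retained.tolist() == [True, False, False]
        assert scores["kept"] == pytest.approx(0.1)

    def test_boundaries_inclusive_and_zero_cc(self):
        counts = pd.DataFrame({"lo": [0, 1000], "hi": [0, 10000], "mid": [0, 5000]},
                              index=["cc1", "other"])
        scores, retained = proliferation_score(counts, GeneSignature("cc", ["cc1"]))
        assert retained.all()
        assert (scores == 0.0).all()


class TestScoreCorrelation:
    def test_perfect_correlations(self):
        x = np.arange(5.0)
        r, p = score_correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        r2, _ = score_correlation(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            score_correlation([1, 2, 3], [5, 5, 5])

    def test_noisy_generated_correlation_in_band(self, rng):
        # 6 timepoints, true slope structure with mild noise: r stays high
        x = np.linspace(0, 1, 6)
        rs = []
        for _ in range(50):
            y = x + rng.normal(0, 0.16, 6)
            rs.append(score_correlation(x, y)[0])
        assert 0.7 < np.mean(rs) < 1.0


def simplex_archetypes(n_genes=12, n_arch=4, seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    A = rng.normal(0, scale, size=(n_genes, n_arch))
    return ArchetypeSet(positions=A, labels=tuple(f"a{i}" for i in range(n_arch)))


class TestConvexDecomposition:
    def test_vertex_recovers_indicator(self):
        arch = simplex_archetypes()
        theta = convex_decomposition(arch.positions[:, 1], arch)
        np.testing.assert_allclose(theta, [0, 1, 0, 0], atol=1e-8)

    def test_centroid_recovers_uniform(self):
        arch = simplex_archetypes()
        centroid = arch.positions.mean(axis=1)
        theta = convex_decomposition(centroid, arch)
        np.testing.assert_allclose(theta, 0.25, atol=1e-8)

    def test_simplex_constraint_always_holds(self, rng):
        arch = simplex_archetypes()
        for _ in range(20):
            g = rng.normal(0, 30, size=12)  # points far outside the simplex too
            theta = convex_decomposition(g, arch)
            assert theta.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(theta >= 0)

    def test_noiseless_dirichlet_recovery(self, rng):
        arch = simplex_archetypes()
        theta_true = rng.dirichlet(np.ones(4), size=30)
        cells = theta_true @ arch.positions.T
        for g, t in zip(cells, theta_true):
            np.testing.assert_allclose(convex_decomposition(g, arch), t, atol=1e-6)

    def test_interior_residual_zero(self, rng):
        arch = simplex_archetypes()
        t = rng.dirichlet(np.ones(4))
        g = arch.positions @ t
        theta = convex_decomposition(g, arch)
        resid = np.linalg.norm(g - arch.positions @ theta)
        assert resid <= 1e-8 * max(1.0, np.linalg.norm(g))

    def test_noisy_assignment_accuracy(self, rng):
        arch = simplex_archetypes(scale=10.0)
        theta_true = rng.dirichlet(np.full(4, 0.3), size=200)  # near-vertex cells
        cells = theta_true @ arch.positions.T + rng.normal(0, 0.05, (200, 12))
        out = decompose_cells(cells, arch)
        pred = out["closest"].str.removeprefix("a").astype(int)
        acc = np.mean(pred.to_numpy() == theta_true.argmax(axis=1))
        assert acc > 0.95

    def test_dimension_mismatch(self):
        arch = simplex_archetypes()
        with pytest.raises(ValueError):
            convex_decomposition(np.zeros(5), arch)

    def test_affinely_dependent_archetypes_rejected(self):
        A = np.ones((6, 3))
        with pytest.raises(ValueError):
            ArchetypeSet(positions=A, labels=("a", "b", "c"))


class TestOccupancyFoldChange:
    def test_identical_distributions_fc_one(self):
        assign = pd.Series(["a1", "a2"] * 10)
        days = pd.Series(["d0"] * 10 + ["d3"] * 10)
        out = archetype_occupancy_fold_change(assign, days, "d3", "d0", ["a1", "a2"])
        np.testing.assert_allclose(out["fold_change"], 1.0)

    def test_new_archetype_infinite_with_flag(self):
        assign = pd.Series(["a1", "a2", "a1", "a2"] + ["a1", "a2", "a3", "a4"])
        days = pd.Series(["d0"] * 4 + ["d3"] * 4)
        out = archetype_occupancy_fold_change(assign, days, "d3", "d0",
                                              ["a1", "a2", "a3", "a4"]).set_index("archetype")
        assert out.loc["a1", "fold_change"] == pytest.approx(0.5)
        assert np.isinf(out.loc["a3", "fold_change"]) and out.loc["a3", "flagged"]
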