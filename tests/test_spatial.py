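"""Neighborhood composition, aggregation, group tests, region calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fibrocircuit import (
    CellMap,
    aggregate,
    classify_fibrosis_region,
    compare_groups,
    neighborhood_composition,
    proliferative_fraction,
)
from fibrocircuit.synth import SpatialConfig, gen_cell_map


def make_map(rows, **kw):
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "cell_type"])
    return CellMap(cells=df, **kw)


class TestComposition:
    def test_single_cell_sees_itself(self):
        prof = neighborhood_composition(make_map([(0, 0, "myofibroblast")]))
        assert prof.counts.loc[0, "myofibroblast"] == 1
        assert prof.percentages.loc[0, "myofibroblast"] == 100.0

    def test_cells_beyond_radius_are_isolated(self):
        prof = neighborhood_composition(
            make_map([(0, 0, "macrophage"), (60, 0, "myofibroblast")]), radius=50
        )
        assert prof.counts.sum(axis=1).tolist() == [1, 1]

    def test_coincident_cells_share_profile(self):
        m = make_map([(5, 5, "macrophage"), (5, 5, "myofibroblast"), (5, 5, "myofibroblast")])
        prof = neighborhood_composition(m, radius=50)
        for i in range(3):
            assert prof.counts.loc[i, "myofibroblast"] == 2
            assert prof.counts.loc[i, "macrophage"] == 1
            assert prof.percentages.loc[i, "myofibroblast"] == pytest.approx(200 / 3)

    def test_percentages_sum_to_100(self, rng):
        n = 300
        df = pd.DataFrame({
            "x_um": rng.uniform(0, 500, n),
            "y_um": rng.uniform(0, 500, n),
            "cell_type": rng.choice(["macrophage", "myofibroblast", "other"], n),
        })
        prof = neighborhood_composition(CellMap(cells=df))
        np.testing.assert_allclose(prof.percentages.sum(axis=1), 100.0)

    def test_pair_symmetry_of_neighbor_counts(self, rng):
        # total cross-type neighbor pairs i->j equal j->i
        n = 200
        df = pd.DataFrame({
            "x_um": rng.uniform(0, 300, n),
            "y_um": rng.uniform(0, 300, n),
            "cell_type": rng.choice(["macrophage", "myofibroblast"], n),
        })
        m = CellMap(cells=df)
        prof = neighborhood_composition(m, radius=50)
        mf_focal = df["cell_type"] == "myofibroblast"
        # macrophages seen by myofibroblast focals vs the transpose
        a = prof.counts.loc[mf_focal, "macrophage"].sum()
        b = prof.counts.loc[~mf_focal, "myofibroblast"].sum()
        assert a == b

    def test_translation_rotation_invariance(self, rng):
        n = 100
        xy = rng.uniform(0, 200, size=(n, 2))
        types = rng.choice(["macrophage", "myofibroblast"], n)
        base = neighborhood_composition(
            CellMap(cells=pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1],
                                        "cell_type": types}))
        )
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = xy @ R.T + [1000.0, -500.0]
        moved = neighborhood_composition(
            CellMap(cells=pd.DataFrame({"x_um": xy2[:, 0], "y_um": xy2[:, 1],
                                        "cell_type": types}))
        )
        pd.testing.assert_frame_equal(base.counts, moved.counts)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_composition(make_map([]))

    def test_poisson_expectation_with_border_exclusion(self):
        # homogeneous Poisson: interior focal cell of type t sees
        # 1 + Poisson(lambda_t * pi r^2) cells of its own type
        cfg = SpatialConfig(scenario="cold", fov_size_um=800.0)
        lam = cfg.type_intensities()
        r = 50.0
        area = np.pi * r**2
        means = {"myofibroblast": [], "macrophage": []}
        for seed in range(20):
            m = gen_cell_map(cfg, seed=seed)
            prof = neighborhood_composition(m, radius=r, exclude_margin=r,
                                            bounds=(0, 800, 0, 800))
            focal_types = m.cells.loc[prof.counts.index, "cell_type"]
            mf = focal_types == "myofibroblast"
            means["myofibroblast"].append(prof.counts.loc[mf, "myofibroblast"].mean())
            means["macrophage"].append(prof.counts.loc[mf, "macrophage"].mean())
        for t, expected in [("myofibroblast", lam["myofibroblast"] * area + 1.0),
                            ("macrophage", lam["macrophage"] * area)]:
            obs = np.array(means[t])
            se = obs.std(ddof=1) / np.sqrt(len(obs))
            assert abs(obs.mean() - expected) <= 2 * se + 1e-9, (t, obs.mean(), expected, se)


class TestAggregate:
    def test_single_fov_identity(self):
        m = make_map([(0, 0, "myofibroblast"), (0, 0, "myofibroblast")])
        prof = neighborhood_composition(m)
        out = aggregate([prof])
        assert out.loc[0, "count_myofibroblast"] == 2.0
        assert out.loc[0, "pct_myofibroblast"] == 100.0
        assert out.loc[0, "n_fovs"] == 1

    def test_fovs_weighted_equally(self):
        # FOV means 1 and 3 myofibroblast neighbors -> animal mean 2,
        # regardless of how many cells each FOV contains (five separated
        # triplets in FOV b: every cell still sees exactly 3)
        m1 = make_map([(0, 0, "myofibroblast")], fov_id="a", animal_id="x")
        m2 = make_map([(200 * k, 0, "myofibroblast") for k in range(5) for _ in range(3)],
                      fov_id="b", animal_id="x")
        out = aggregate([neighborhood_composition(m) for m in (m1, m2)])
        assert out.loc[0, "count_myofibroblast"] == pytest.approx((1 + 3) / 2)


class TestCompareGroups:
    @staticmethod
    def exact_mw_p(xs, ys):
        """Exhaustive enumeration oracle for the two-sided Mann-Whitney p."""
        pooled = list(xs) + list(ys)
        n = len(xs)

        def ustat(idx):
            xsel = [pooled[i] for i in idx]
            ysel = [pooled[i] for i in range(len(pooled)) if i not in idx]
            return sum(1 for a in xsel for b in ysel if a > b)

        u_obs = ustat(tuple(range(n)))
        us = [ustat(idx) for idx in itertools.combinations(range(len(pooled)), n)]
        mean_u = len(xs) * len(ys) / 2
        extreme = sum(1 for u in us if abs(u - mean_u) >= abs(u_obs - mean_u))
        return extreme / len(us)

    def test_separated_groups_match_enumeration_oracle(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                           "value": [1, 2, 3, 10, 20, 30]})
        out = compare_groups(df, "group", "value", [("a", "b")])
        assert out.loc[0, "U"] == 0.0
        oracle = self.exact_mw_p([1, 2, 3], [10, 20, 30])
        assert oracle == pytest.approx(0.1)
        assert out.loc[0, "p_raw"] == pytest.approx(oracle)

    def test_identical_groups_adjusted_p_is_one(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "value": [5, 6, 7] * 2})
        out = compare_groups(df, "group", "value", [("a", "b")])
        assert out.loc[0, "p_bonferroni"] == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3 + ["d"] * 3,
                           "value": [1, 2, 3, 10, 20, 30, 1, 2, 3, 1, 2, 3]})
        comparisons = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c")]
        out = compare_groups(df, "group", "value", comparisons)
        assert np.allclose(out["p_bonferroni"],
                           np.minimum(1.0, out["p_raw"] * 4))

    def test_small_group_skipped_with_warning(self):
        df = pd.DataFrame({"group": ["a", "b", "b"], "value": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out = compare_groups(df, "group", "value", [("a", "b")])
        assert len(out) == 0


class TestRegionCall:
    def test_six_to_one_is_cold(self):
        assert classify_fibrosis_region(
            {"myofibroblast": 6.0, "macrophage": 1.0}) == "cold"

    def test_one_to_one_elevated_is_hot(self):
        assert classify_fibrosis_region(
            {"myofibroblast": 5.0, "macrophage": 5.0}) == "hot"

    def test_between_thresholds_indeterminate(self):
        assert classify_fibrosis_region(
            {"myofibroblast": 2.5, "macrophage": 1.0}) == "indeterminate"

    def test_zero_macrophages_flagged_cold(self):
        with pytest.warns(UserWarning):
            assert classify_fibrosis_region(
                {"myofibroblast": 3.0, "macrophage": 0.0}) == "cold"


class TestProliferativeFraction:
    def test_no_positive_cells_zero_everywhere(self):
        df = pd.DataFrame({"x_um": [0.0, 1.0], "y_um": [0.0, 1.0],
                           "cell_type": ["myofibroblast"] * 2, "EdU_positive": [0, 0]})
        out = proliferative_fraction(CellMap(cells=df))
        assert (out == 0.0).all()

    def test_all_positive_myofibroblasts_hundred(self):
        df = pd.DataFrame({"x_um": [0.0, 1.0], "y_um": [0.0, 1.0],
                           "cell_type": ["myofibroblast"] * 2, "EdU_positive": [1, 1]})
        out = proliferative_fraction(CellMap(cells=df))
        assert (out == 100.0).all()

    def test_missing_marker_errors(self):
        df = pd.DataFrame({"x_um": [0.0], "y_um": [0.0], "cell_type": ["myofibroblast"]})
        with pytest.raises(ValueError):
            proliferative_fraction(CellMap(cells=df))

    def test_binomial_expectation_on_generator(self):
        # EdU assigned to myofibroblasts with p=0.2: mean neighborhood
        # percentage ~ 20 x interior myofibroblast share
        cfg = SpatialConfig(scenario="cold", fov_size_um=800.0, edu_probability=0.2)
        vals, shares = [], []
        for seed in range(20):
            m = gen_cell_map(cfg, seed=seed)
            vals.append(proliferative_fraction(m).mean())
            prof = neighborhood_composition(m)
            shares.append(prof.percentages["myofibroblast"].mean())
        vals = np.array(vals)
        expected = 0.2 * np.mean(shares)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - expected) <= 2 * se + 0.2
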