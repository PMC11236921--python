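"""Entropy segregation scores, local G* clustering, and VIF screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fooddesert.segregation import (
    citywide_entropy_index,
    classify_clusters,
    compute_vif,
    entropy_deviation_score,
    local_gstar,
    segregation_features,
    tract_entropy,
)

from conftest import random_graph


class TestTractEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((1.0, 0.0, 0.0, 0.0), 0.0),
            ((0.25, 0.25, 0.25, 0.25), np.log(4)),
            ((0.5, 0.5, 0.0, 0.0), np.log(2)),
        ],
    )
    def test_known_values(self, p, expected):
        assert tract_entropy(p) == pytest.approx(expected, abs=1e-9)

    def test_rejects_negative_and_non_unit_sums(self):
        with pytest.raises(ValueError):
            tract_entropy((-0.1, 1.1, 0.0, 0.0))
        with pytest.raises(ValueError):
            tract_entropy((0.5, 0.4, 0.0, 0.0))

    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_permutation_invariant_and_below_uniform_max(self, weights):
        p = np.array(weights) / np.sum(weights)
        e = tract_entropy(p)
        assert e == pytest.approx(tract_entropy(p[::-1].copy()), abs=1e-12)
        assert e <= np.log(len(p)) + 1e-12


class TestEntropyDeviationScore:
    CITY = (0.4, 0.4, 0.1, 0.1)

    def test_city_matching_tract_scores_zero(self):
        assert entropy_deviation_score(self.CITY, self.CITY) == 0.0

    def test_single_group_tract_scores_one(self):
        assert entropy_deviation_score((1.0, 0.0, 0.0, 0.0), self.CITY) == pytest.approx(1.0)

    def test_tract_more_diverse_than_city_clips_to_zero(self):
        city = (0.7, 0.2, 0.05, 0.05)
        assert entropy_deviation_score((0.25, 0.25, 0.25, 0.25), city) == 0.0

    def test_single_group_city_is_an_error(self):
        with pytest.raises(ValueError, match="single-group"):
            entropy_deviation_score((0.5, 0.5), (1.0, 0.0))


class TestCitywideEntropyIndex:
    def test_identical_tracts_give_zero(self):
        counts = pd.DataFrame([[40, 40, 20]] * 5)
        assert citywide_entropy_index(counts) == pytest.approx(0.0, abs=1e-12)

    def test_fully_separated_tracts_give_one(self):
        counts = pd.DataFrame([[100, 0], [0, 100]])
        assert citywide_entropy_index(counts) == pytest.approx(1.0)

    def test_three_tract_toy_matches_direct_summation(self):
        counts = pd.DataFrame(
            [[30.0, 10.0, 5.0], [5.0, 50.0, 10.0], [20.0, 20.0, 20.0]]
        )
        # independent direct summation of H = sum t_i (E - E_i) / (E T)
        t = counts.sum(axis=1).to_numpy()
        T = t.sum()
        city_p = counts.sum(axis=0).to_numpy() / T
        E = -sum(p * np.log(p) for p in city_p if p > 0)
        H = 0.0
        for i in range(3):
            p = counts.iloc[i].to_numpy() / t[i]
            Ei = -sum(q * np.log(q) for q in p if q > 0)
            H += t[i] * (E - Ei) / (E * T)
        assert citywide_entropy_index(counts) == pytest.approx(H, abs=1e-12)

    def test_equals_population_weighted_mean_of_unclipped_scores(self, rng):
        counts = pd.DataFrame(rng.integers(1, 200, size=(6, 4)).astype(float))
        t = counts.sum(axis=1).to_numpy()
        city_p = counts.sum(axis=0).to_numpy() / t.sum()
        E = tract_entropy(city_p)
        scores = [
            (E - tract_entropy(counts.iloc[i].to_numpy() / t[i])) / E for i in range(6)
        ]
        assert citywide_entropy_index(counts) == pytest.approx(
            np.average(scores, weights=t), abs=1e-12
        )

    def test_zero_total_population_rejected(self):
        with pytest.raises(ValueError):
            citywide_entropy_index(pd.DataFrame([[0.0, 0.0]]))


def gstar_oracle(x, graph):
    """Dense-matrix G_i* z-scores coded independently from the formula."""
    n = graph.n
    idx = {a: k for k, a in enumerate(graph.area_ids)}
    W = np.eye(n)
    for a in graph.area_ids:
        for b in graph.neighbors[a]:
            W[idx[a], idx[b]] = 1.0
    xbar = np.mean(x)
    s = np.sqrt(np.mean(np.asarray(x) ** 2) - xbar**2)
    z = np.empty(n)
    for i in range(n):
        wi = W[i].sum()
        num = W[i] @ x - xbar * wi
        den = s * np.sqrt((n * wi - wi**2) / (n - 1))
        z[i] = num / den if den > 0 else 0.0
    return z


class TestLocalGstar:
    def test_constant_surface_yields_zero_with_warning(self, grid3x3):
        with pytest.warns(UserWarning, match="constant"):
            z = local_gstar(np.full(9, 3.0), grid3x3)
        assert np.all(z == 0)

    def test_single_spike_on_5x5_grid(self, grid5x5):
        x = np.zeros(25)
        center = list(grid5x5.area_ids).index("G012")
        x[center] = 1.0
        z = local_gstar(x, grid5x5)
        assert z[center] > 0
        for b in grid5x5.neighbors["G012"]:
            assert z[grid5x5.index[b]] > 0
        # far corner is depressed relative to the spike neighborhood
        assert z[grid5x5.index["G000"]] < z[center]

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_oracle_on_random_graphs(self, trial):
        rng = np.random.default_rng(4000 + trial)
        g = random_graph(rng, int(rng.integers(5, 26)))
        x = rng.normal(size=g.n)
        np.testing.assert_allclose(local_gstar(x, g), gstar_oracle(x, g), atol=1e-10)

    def test_shift_invariance_of_z(self, grid4x4, rng):
        x = rng.normal(size=16)
        np.testing.assert_allclose(
            local_gstar(x, grid4x4), local_gstar(x + 7.3, grid4x4), atol=1e-9
        )

    def test_mean_z_near_zero_for_exchangeable_input(self, grid5x5, rng):
        means = [local_gstar(rng.normal(size=25), grid5x5).mean() for _ in range(40)]
        assert abs(np.mean(means)) < 0.05

    def test_too_few_areas_rejected(self):
        from fooddesert.spatial import AreaGraph

        g = AreaGraph(("a", "b"), {"a": frozenset({"b"}), "b": frozenset({"a"})})
        with pytest.raises(ValueError):
            local_gstar(np.array([1.0, 2.0]), g)


class TestClassifyClusters:
    def test_sign_rule_with_zero_tie_broken_low(self):
        z = np.array([2.1, -0.5, 0.0])
        assert list(classify_clusters(z)) == ["high", "low", "low"]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_clusters(np.array([np.nan]))


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        X = pd.DataFrame(
            {"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0], "c": [1, -1, -1, 1.0]}
        )
        out = compute_vif(X)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-10)
        assert not out["flagged"].any()

    def test_duplicated_column_is_infinite_and_flagged(self, rng):
        a = rng.normal(size=30)
        out = compute_vif(pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=30)}))
        assert np.isinf(out.loc["a", "vif"])
        assert out.loc["a", "flagged"]

    def test_matches_regression_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x1", "x2", "x3"])
        X["x2"] += 0.8 * X["x1"]
        out = compute_vif(X)
        # independent 1/(1-R^2) oracle via statsmodels OLS
        import statsmodels.api as sm

        for k, col in enumerate(X.columns):
            others = sm.add_constant(X.drop(columns=[col]))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert out.loc[col, "vif"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)

    def test_statsmodels_variance_inflation_factor_agrees(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        X["b"] += 0.5 * X["a"]
        out = compute_vif(X)
        Xd = np.column_stack([np.ones(40), X.to_numpy()])
        for k, col in enumerate(X.columns):
            assert out.loc[col, "vif"] == pytest.approx(
                variance_inflation_factor(Xd, k + 1), rel=1e-8
            )

    def test_shape_preconditions(self, rng):
        with pytest.raises(ValueError):
            compute_vif(pd.DataFrame({"a": rng.normal(size=5)}))
        with pytest.raises(ValueError):
            compute_vif(pd.DataFrame(rng.normal(size=(3, 4))))


class TestSegregationFeatures:
    def test_feature_table_schema_and_ranges(self, grid4x4, rng):
        counts = pd.DataFrame(
            rng.integers(10, 500, size=(16, 4)),
            columns=["white", "black", "asian", "hispanic"],
            index=pd.Index(grid4x4.area_ids, name="area_id"),
        )
        feats = segregation_features(counts, grid4x4)
        assert list(feats.index) == list(grid4x4.area_ids)
        assert ((feats["entropy_score"] >= 0) & (feats["entropy_score"] <= 1)).all()
        assert set(feats["cluster_black"]) <= {"high", "low"}
        # high iff z > 0
        assert (
            (feats["gstar_z_black"] > 0) == (feats["cluster_black"] == "high")
        ).all()
        assert ((feats["pct_asian"] >= 0) & (feats["pct_asian"] <= 100)).all()
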