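import warnings
from statistics import NormalDist

import numpy as np
import pandas as pd
import pytest

from mnetclass.errors import (
    AllConstant,
    ConstantIndicatorWarning,
    FewerThanTwoObjects,
    MultipleBestWarning,
    SingularFit,
)
from mnetclass.score import (
    entropy_weights,
    fit_regression,
    probit_units,
    rank_matrix,
    score_table,
    select_best,
    standardize,
    wrsr,
)


def df(cols, index=None):
    d = pd.DataFrame(cols)
    if index is not None:
        d.index = index
    return d


class TestStandardize:
    def test_extremes_map_to_unit_interval(self):
        X = df({"a": [2.0, 4.0, 10.0]})
        Z = standardize(X, {"a": 1})
        np.testing.assert_allclose(Z["a"], [0.0, 0.25, 1.0])

    def test_negative_direction_reversed(self):
        X = df({"a": [2.0, 4.0, 10.0]})
        Z = standardize(X, {"a": -1})
        np.testing.assert_allclose(Z["a"], [1.0, 0.75, 0.0])

    def test_constant_column_warns_zero(self):
        X = df({"a": [3.0, 3.0, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.warns(ConstantIndicatorWarning):
            Z = standardize(X, {})
        np.testing.assert_allclose(Z["a"], 0.0)


class TestRankMatrix:
    def test_positive_ascending(self):
        R = rank_matrix(df({"a": [5.0, 1.0, 3.0]}), {"a": 1})
        np.testing.assert_allclose(R["a"], [3, 1, 2])

    def test_ties_get_average_rank(self):
        R = rank_matrix(df({"a": [2.0, 2.0, 7.0]}), {"a": 1})
        np.testing.assert_allclose(R["a"], [1.5, 1.5, 3])

    def test_negative_reversed(self):
        R = rank_matrix(df({"a": [5.0, 1.0, 3.0]}), {"a": -1})
        np.testing.assert_allclose(R["a"], [1, 3, 2])

    def test_each_column_is_permutation_of_ranks(self):
        rng = np.random.default_rng(0)
        X = df({c: rng.normal(size=6) for c in "abc"})
        R = rank_matrix(X, {"b": -1})
        for c in "abc":
            assert sorted(R[c]) == [1, 2, 3, 4, 5, 6]


class TestEntropyWeights:
    def test_constant_indicator_gets_zero_weight(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConstantIndicatorWarning)
            Z = standardize(
                df({"flat": [2.0, 2.0, 2.0], "var": [1.0, 2.0, 3.0]}), {}
            )
        _, _, W = entropy_weights(Z)
        assert W["flat"] == 0.0
        assert W["var"] == pytest.approx(1.0)

    def test_identical_columns_share_weight(self):
        Z = df({"a": [0.0, 0.5, 1.0], "b": [0.0, 0.5, 1.0]})
        _, _, W = entropy_weights(Z)
        np.testing.assert_allclose(W, [0.5, 0.5])

    def test_two_by_two_hand_computation(self):
        # Z = [[1,0],[0,1]]: p columns are [1,0] and [0,1], entropy 0 each
        Z = df({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        _, e, W = entropy_weights(Z)
        np.testing.assert_allclose(e, [0.0, 0.0], atol=1e-15)
        np.testing.assert_allclose(W, [0.5, 0.5])

    def test_weights_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(1)
        Z = df({c: rng.uniform(size=8) for c in "abcde"})
        p, e, W = entropy_weights(Z)
        assert W.sum() == pytest.approx(1.0)
        assert (W >= 0).all()
        assert ((e >= 0) & (e <= 1)).all()
        assert ((p.values >= 0) & (p.values <= 1)).all()

    def test_all_constant_raises(self):
        Z = df({"a": [0.0, 0.0], "b": [0.0, 0.0]})
        with pytest.raises(AllConstant):
            entropy_weights(Z)


class TestWRSR:
    def test_direct_arithmetic(self):
        R = df({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]})
        W = pd.Series({"a": 0.5, "b": 0.5})
        v, raw = wrsr(R, W)
        np.testing.assert_allclose(v, [0.25, 0.25, 0.5])
        np.testing.assert_allclose(raw, [1.5, 1.5, 3.0])

    def test_equal_weights_proportional_to_rank_sum(self):
        rng = np.random.default_rng(2)
        R = df({c: rng.permutation([1.0, 2, 3, 4]) for c in "ab"})
        W = pd.Series({"a": 0.5, "b": 0.5})
        v, _ = wrsr(R, W)
        plain = R.sum(axis=1)
        np.testing.assert_allclose(
            v / v.sum(), plain / plain.sum(), atol=1e-12
        )


class TestProbitUnits:
    def test_median_maps_to_five(self):
        v = pd.Series([0.2, 0.4, 0.6], index=list("abc"))
        cf, probit = probit_units(v)
        # middle item has cumulative frequency 2/3, bottom 1/3
        assert probit["a"] == pytest.approx(
            NormalDist().inv_cdf(1 / 3) + 5
        )

    def test_cum_freq_half_probit_five(self):
        v = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        cf, probit = probit_units(v)
        assert cf["b"] == pytest.approx(0.5)
        assert probit["b"] == pytest.approx(5.0)

    def test_last_item_correction(self):
        m = 4
        v = pd.Series([0.1, 0.2, 0.3, 0.4], index=list("abcd"))
        cf, probit = probit_units(v)
        assert cf["d"] == pytest.approx(1 - 1 / (4 * m))  # 0.9375
        assert probit["d"] == pytest.approx(
            NormalDist().inv_cdf(0.9375) + 5
        )
        assert probit["d"] == pytest.approx(6.534, abs=5e-4)

    def test_probit_increasing_in_cum_freq(self):
        rng = np.random.default_rng(3)
        v = pd.Series(rng.normal(size=9),
                      index=[f"o{i}" for i in range(9)])
        cf, probit = probit_units(v)
        order = cf.sort_values().index
        assert probit[order].is_monotonic_increasing


class TestFitRegression:
    def test_exact_linear_recovered(self):
        probit = pd.Series([4.0, 5.0, 6.0, 7.0])
        v = 0.1 + 0.05 * probit
        reg = fit_regression(v, probit)
        assert reg["a"] == pytest.approx(0.1, abs=1e-12)
        assert reg["b"] == pytest.approx(0.05, abs=1e-12)
        assert reg["r2"] == pytest.approx(1.0)

    def test_constant_probit_singular(self):
        probit = pd.Series([5.0, 5.0, 5.0])
        with pytest.raises(SingularFit):
            fit_regression(pd.Series([0.1, 0.2, 0.3]), probit)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(5, 1, size=5))
        y = pd.Series(0.2 + 0.03 * x.to_numpy() + rng.normal(0, 0.01, 5))
        reg = fit_regression(y, x)
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        assert reg["a"] == pytest.approx(beta[0], abs=1e-10)
        assert reg["b"] == pytest.approx(beta[1], abs=1e-10)


class TestScoreTable:
    def test_dominant_object_ranks_first(self):
        # object "top" dominates every positive indicator and is smallest
        # on the negative one
        X = df(
            {
                "pos1": [10.0, 5.0, 1.0, 3.0],
                "pos2": [9.0, 2.0, 4.0, 1.0],
                "neg": [0.5, 2.0, 3.0, 4.0],
            },
            index=["top", "b", "c", "d"],
        )
        rep = score_table(X, {"pos1": 1, "pos2": 1, "neg": -1})
        assert select_best(rep) == "top"
        assert rep.final_rank["top"] == 1

    def test_all_constant_indicators_raise(self):
        X = df({"a": [1.0, 1.0], "b": [2.0, 2.0]}, index=["x", "y"])
        with pytest.raises(AllConstant):
            score_table(X, {})

    def test_tied_objects_share_rank_one(self):
        X = df(
            {"a": [1.0, 1.0, 0.0], "b": [2.0, 2.0, 0.0]},
            index=["x", "y", "z"],
        )
        with pytest.warns(MultipleBestWarning):
            rep = score_table(X, {})
        assert rep.final_rank["x"] == 1
        assert rep.final_rank["y"] == 1
        assert select_best(rep) == "x"  # deterministic id tie-break

    def test_distinct_wrsr_reverse_order(self):
        X = df({"a": [1.0, 2.0, 3.0]}, index=["lo", "mid", "hi"])
        rep = score_table(X, {"a": 1})
        assert list(rep.final_rank[["hi", "mid", "lo"]]) == [1, 2, 3]

    def test_single_object_rejected(self):
        with pytest.raises(FewerThanTwoObjects):
            score_table(df({"a": [1.0]}, index=["only"]), {})

    def test_weights_sum_one_and_ranks_bijective(self):
        rng = np.random.default_rng(5)
        X = df({c: rng.normal(size=7) for c in "abcd"},
               index=[f"o{i}" for i in range(7)])
        rep = score_table(X, {"b": -1})
        assert rep.weights.sum() == pytest.approx(1.0)
        assert sorted(rep.final_rank) == list(range(1, 8))

    def test_published_indicator_table_winner(self):
        """The composite model applied to the published saliva subnetwork
        indicator table selects the 32-node subnetwork, not the 5-clique."""
        cols = ["node_count", "edge_count", "graph_diameter",
                "graph_density", "average_degree", "edge_connectivity",
                "node_connectivity", "clustering_coefficient", "modularity",
                "average_path_length"]
        rows = {
            "sub1": [32, 68, 4.194, 0.137, 4.250, 1, 1, 0.331, 0.466, 2.185],
            "sub5": [24, 67, 4.137, 0.243, 5.583, 1, 1, 0.472, 0.237, 1.747],
            "sub4": [12, 19, 4.077, 0.288, 3.167, 1, 1, 0.476, 0.263, 1.772],
            "sub2": [9, 11, 3.323, 0.306, 2.444, 1, 1, 0.250, 0.252, 1.690],
            "sub16": [5, 10, 0.969, 1.000, 4.000, 4, 4, 1.000, -0.080,
                      0.924],
        }
        from mnetclass.topology import SUBNETWORK_INDICATORS

        X = pd.DataFrame(rows, index=cols).T
        rep = score_table(X, dict(SUBNETWORK_INDICATORS))
        assert select_best(rep) == "sub1"
        assert rep.final_rank["sub1"] == 1

    def test_monotone_indicator_transform_keeps_rank_part(self):
        # rank matrix depends only on within-column order
        X = df({"a": [1.0, 4.0, 9.0], "b": [3.0, 1.0, 2.0]})
        R1 = rank_matrix(X, {})
        X2 = X.copy()
        X2["a"] = np.sqrt(X2["a"])
        R2 = rank_matrix(X2, {})
        pd.testing.assert_frame_equal(R1, R2)
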