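import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mnetclass.errors import (
    ConstantTaxonWarning,
    DegenerateFitWarning,
    EmptyNetworkWarning,
    NoValidThreshold,
)
from mnetclass.netbuild import (
    adjust_pvalues,
    powerlaw_r2,
    select_threshold,
    sparsify,
    spearman_matrix,
)
from mnetclass.preprocess import AbundanceTable
from mnetclass.synthdata import make_planted_abundance

from conftest import make_network


def spearman_oracle(x, y):
    """Rank transform with average ties, then the Pearson formula."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def _table(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"t{i}" for i in range(rows.shape[0])]
    df = pd.DataFrame(rows, index=ids,
                      columns=[f"s{j}" for j in range(rows.shape[1])])
    return AbundanceTable(df)


class TestSpearmanMatrix:
    def test_identical_rank_order(self):
        t = _table([[1, 2, 3, 4], [10, 20, 30, 40]])
        rho, _ = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        t = _table([[1, 2, 3, 4], [8, 6, 4, 2]])
        rho, _ = spearman_matrix(t)
        assert rho.iloc[0, 1] == pytest.approx(-1.0)

    def test_tied_pair_matches_rank_pearson_oracle(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]  # one tie
        y = [2.0, 7.0, 1.0, 8.0, 2.0, 8.0]
        rho, _ = spearman_matrix(_table([x, y]))
        assert rho.iloc[0, 1] == pytest.approx(spearman_oracle(x, y),
                                               abs=1e-12)

    def test_symmetry_zero_diagonal_and_bounds(self):
        rng = np.random.default_rng(3)
        t = _table(rng.gamma(1.0, 1.0, size=(6, 15)))
        rho, pvals = spearman_matrix(t)
        np.testing.assert_allclose(rho.values, rho.values.T)
        np.testing.assert_allclose(np.diag(rho.values), 0.0)
        assert (np.abs(rho.values) <= 1 + 1e-12).all()
        assert ((pvals.values >= 0) & (pvals.values <= 1)).all()

    def test_constant_taxon_warns_and_zeroes(self):
        t = _table([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        with pytest.warns(ConstantTaxonWarning):
            rho, pvals = spearman_matrix(t)
        assert rho.iloc[0, 1] == 0.0
        assert pvals.iloc[0, 1] == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(2.0, 1.0, size=(5, 12))
        rho1, _ = spearman_matrix(_table(x))
        # strictly monotone per-sample transform (exp is rank-preserving)
        rho2, _ = spearman_matrix(_table(np.exp(x)))
        np.testing.assert_allclose(rho1.values, rho2.values, atol=1e-12)


class TestSparsify:
    @staticmethod
    def _mats(rho01, p01):
        ids = ["a", "b"]
        rho = pd.DataFrame([[0.0, rho01], [rho01, 0.0]], index=ids, columns=ids)
        p = pd.DataFrame([[1.0, p01], [p01, 1.0]], index=ids, columns=ids)
        return rho, p

    def test_below_threshold_dropped(self):
        rho, p = self._mats(0.75, 0.001)
        with pytest.warns(EmptyNetworkWarning):
            net = sparsify(rho, p, 0.8, p_adjust="none")
        assert net.n_edges == 0
        assert net.n_nodes == 2  # isolated nodes retained

    def test_insignificant_dropped(self):
        rho, p = self._mats(0.9, 0.2)
        with pytest.warns(EmptyNetworkWarning):
            net = sparsify(rho, p, 0.8, p_adjust="none")
        assert net.n_edges == 0

    def test_negative_edge_keeps_sign(self):
        rho, p = self._mats(-0.9, 0.01)
        net = sparsify(rho, p, 0.8, p_adjust="none")
        assert net.graph.edges["a", "b"]["rho"] == pytest.approx(-0.9)

    def test_edge_count_monotone_in_threshold(self, random_relative_table):
        rho, p = spearman_matrix(random_relative_table)
        counts = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyNetworkWarning)
            for thr in [0.0, 0.2, 0.4, 0.6, 0.8]:
                counts.append(sparsify(rho, p, thr, alpha=1.1,
                                       p_adjust="none").n_edges)
        assert counts == sorted(counts, reverse=True)

    def test_near_one_threshold_empty_but_nodes_kept(
            self, random_relative_table):
        rho, p = spearman_matrix(random_relative_table)
        with pytest.warns(EmptyNetworkWarning):
            net = sparsify(rho, p, 0.999, p_adjust="none")
        assert net.n_edges == 0
        assert net.n_nodes == random_relative_table.n_taxa

    def test_bh_adjustment_matches_statsmodels_on_triangle(self):
        ids = list("abc")
        p = pd.DataFrame(np.ones((3, 3)), index=ids, columns=ids)
        raw = [0.01, 0.02, 0.04]
        p.iloc[0, 1] = p.iloc[1, 0] = raw[0]
        p.iloc[0, 2] = p.iloc[2, 0] = raw[1]
        p.iloc[1, 2] = p.iloc[2, 1] = raw[2]
        adj = adjust_pvalues(p, "bh")
        # BH: sorted p * n/k with monotonicity enforcement
        assert adj.iloc[0, 1] == pytest.approx(0.03)
        assert adj.iloc[0, 2] == pytest.approx(0.03)
        assert adj.iloc[1, 2] == pytest.approx(0.04)


class TestPowerlawFit:
    def test_exact_power_law_r2_one(self):
        # frequencies lying exactly on f(d) = 100 d^-2
        from mnetclass.netbuild import _fit_powerlaw

        d = np.array([1.0, 2.0, 4.0, 5.0])
        f = 100.0 * d**-2
        c, gamma, r2 = _fit_powerlaw(d, f)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert gamma == pytest.approx(2.0, abs=1e-6)
        assert c == pytest.approx(100.0, rel=1e-6)

    def test_regular_graph_degenerate(self):
        net = make_network([("a", "b", 0.9), ("c", "d", 0.9)])
        with pytest.warns(DegenerateFitWarning):
            fit = powerlaw_r2(net, n_perm=10, seed=0)
        assert np.isnan(fit.r2)

    def test_preferential_attachment_matches_grid_oracle(self):
        g = nx.barabasi_albert_graph(500, 2, seed=42)
        for u, v in g.edges:
            g[u][v]["rho"] = 1.0
        from mnetclass.netbuild import CorrelationNetwork, _degree_frequency

        net = CorrelationNetwork(graph=g, threshold=0.0, alpha=1.0)
        fit = powerlaw_r2(net, n_perm=50, seed=0)
        d, f = _degree_frequency(net)
        r2_oracle = grid_search_powerlaw_r2(d, f)
        assert fit.r2 == pytest.approx(r2_oracle, abs=1e-6)
        assert 0 < fit.pvalue <= 1


def grid_search_powerlaw_r2(d, f, n_zoom=12):
    """Exhaustive (c, gamma) grid refinement least-squares oracle."""
    c_lo, c_hi = 1e-3, 10 * f.max()
    g_lo, g_hi = -5.0, 8.0
    best = None
    for _ in range(n_zoom):
        cs = np.linspace(c_lo, c_hi, 41)
        gs = np.linspace(g_lo, g_hi, 41)
        ss = np.array(
            [[np.sum((f - c * d**-g) ** 2) for g in gs] for c in cs]
        )
        ci, gi = np.unravel_index(np.argmin(ss), ss.shape)
        best = (cs[ci], gs[gi], ss[ci, gi])
        dc = (c_hi - c_lo) / 40
        dg = (g_hi - g_lo) / 40
        c_lo, c_hi = best[0] - 2 * dc, best[0] + 2 * dc
        g_lo, g_hi = best[1] - 2 * dg, best[1] + 2 * dg
    ss_tot = np.sum((f - f.mean()) ** 2)
    return 1.0 - best[2] / ss_tot


class TestSelectThreshold:
    def test_planted_matrix_matches_independent_refit(self):
        ds = make_planted_abundance(seed=3)
        thr, fits = select_threshold(ds.table(), n_perm=99, seed=3)
        # oracle: refit every grid point's degree-frequency table by grid
        # search and take the argmax of R^2 among significant fits
        best_thr, best_r2 = None, -np.inf
        rho, pvals = spearman_matrix(ds.table())
        for fit in fits:
            if np.isnan(fit.r2) or fit.pvalue > 0.05 or fit.n_edges == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyNetworkWarning)
                net = sparsify(rho, pvals, fit.threshold)
            from mnetclass.netbuild import _degree_frequency

            d, f = _degree_frequency(net)
            r2 = grid_search_powerlaw_r2(d, f)
            assert r2 == pytest.approx(fit.r2, abs=1e-5)
            if r2 > best_r2:
                best_thr, best_r2 = fit.threshold, r2
        assert thr == best_thr

    def test_no_valid_threshold_raises(self):
        # tiny noise table: no grid point yields a significant scale-free fit
        rng = np.random.default_rng(0)
        t = _table(rng.gamma(1.0, 1.0, size=(5, 10)))
        with pytest.raises(NoValidThreshold), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            select_threshold(t, n_perm=19, seed=0)
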