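"""Spearman co-occurrence network construction with scale-free threshold choice.

Pairwise Spearman rank correlations between taxa are sparsified in two steps:
an absolute-correlation threshold and a multiplicity-corrected significance
test.  The threshold itself is not arbitrary: a grid of candidate thresholds
(0 to 1 in steps of 0.1) is scanned and, for each, the degree distribution of
the resulting graph is fitted to a power law f(d) = c * d**(-gamma) by
nonlinear least squares.  The threshold whose network best matches the
scale-free property (highest R^2 among permutation-significant fits) wins —
the same soft-threshold logic popularized by co-expression network analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConstantTaxonWarning,
    DegenerateFitWarning,
    EmptyNetworkWarning,
    NoValidThreshold,
)
from .preprocess import AbundanceTable

__all__ = [
    "CorrelationNetwork",
    "ScaleFreeFit",
    "spearman_matrix",
    "sparsify",
    "powerlaw_r2",
    "select_threshold",
    "write_edge_list",
    "write_graphml",
    "write_fit_table",
]

DEFAULT_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class CorrelationNetwork:
    """Undirected weighted taxon co-occurrence graph.

    ``graph`` is a :class:`networkx.Graph` whose nodes are taxon ids with a
    ``weight`` attribute (mean relative abundance, when available) and an
    optional ``phylum`` attribute; edges carry the signed Spearman ``rho``
    and the adjusted p-value ``p_adj``.  Isolated taxa stay in the node set.
    """

    graph: nx.Graph
    threshold: float
    alpha: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> pd.DataFrame:
        """Symmetric signed adjacency matrix with a zero diagonal."""
        nodes = list(self.graph.nodes)
        a = nx.to_pandas_adjacency(self.graph, nodelist=nodes, weight="rho")
        np.fill_diagonal(a.values, 0.0)
        return a

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


@dataclass
class ScaleFreeFit:
    """Power-law goodness of fit for one candidate threshold."""

    threshold: float
    r2: float  # NaN when the fit is degenerate
    pvalue: float  # permutation p-value, NaN when r2 is NaN
    c: float
    gamma: float
    n_edges: int
    n_distinct_degrees: int


def spearman_matrix(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p-values between taxa.

    Taxa that are constant across samples have undefined rank correlations;
    their pairs are reported as rho = 0, p = 1 with a warning.  The diagonal
    of rho is set to 0, matching the self-correlation-free adjacency
    convention.
    """
    X = table.values.to_numpy(dtype=float)
    p, k = X.shape
    if k < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    if p < 2:
        raise ValueError("need at least 2 taxa")
    constant = np.ptp(X, axis=1) == 0
    if constant.any():
        bad = [table.taxon_ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"taxa constant across samples (correlations set to 0): {bad}",
            ConstantTaxonWarning,
            stacklevel=2,
        )
    # rank-transform rows (average ties), then Pearson on the ranks; the
    # significance test is the usual t approximation with n-2 df
    ranks = stats.rankdata(X, axis=1)
    sd = ranks.std(axis=1)
    safe = ranks.copy()
    safe[sd == 0] += np.arange(k)  # placeholder ranks, overwritten below
    rho = np.corrcoef(safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((k - 2) / (1.0 - rho**2))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=k - 2)
    pval[np.isclose(np.abs(rho), 1.0)] = 0.0
    rho[np.isnan(rho)] = 0.0
    pval[np.isnan(pval)] = 1.0
    if constant.any():
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
        pval[constant, :] = 1.0
        pval[:, constant] = 1.0
    np.fill_diagonal(rho, 0.0)
    np.fill_diagonal(pval, 1.0)
    ids = table.taxon_ids
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(pval, index=ids, columns=ids),
    )


def adjust_pvalues(pvals: pd.DataFrame, method: str = "bh") -> pd.DataFrame:
    """Multiplicity-adjust the upper-triangle p-values of a symmetric matrix.

    ``method`` is one of ``none``, ``bonferroni``, ``bh`` (Benjamini-Hochberg,
    the default).
    """
    method = method.lower()
    if method == "none":
        return pvals.copy()
    smmethod = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if smmethod is None:
        raise ValueError(f"unknown p_adjust method: {method!r}")
    p = pvals.to_numpy(dtype=float)
    iu = np.triu_indices_from(p, k=1)
    adj = multipletests(p[iu], method=smmethod)[1]
    out = np.ones_like(p)
    out[iu] = adj
    out.T[iu] = adj
    return pd.DataFrame(out, index=pvals.index, columns=pvals.columns)


def sparsify(
    rho: pd.DataFrame,
    pvals: pd.DataFrame,
    threshold: float,
    alpha: float = 0.05,
    p_adjust: str = "bh",
    node_weights: pd.Series | None = None,
    taxon_meta: dict[str, str] | None = None,
) -> CorrelationNetwork:
    """Keep edges with |rho| > threshold and adjusted p < alpha.

    Edge weights keep the sign of rho; isolated nodes remain in the graph.
    """
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    p_adj = adjust_pvalues(pvals, p_adjust)
    g = nx.Graph(threshold=threshold, alpha=alpha)
    ids = list(rho.index)
    for t in ids:
        attrs: dict = {}
        if node_weights is not None:
            attrs["weight"] = float(node_weights[t])
        if taxon_meta is not None and t in taxon_meta:
            attrs["phylum"] = taxon_meta[t]
        g.add_node(t, **attrs)
    r = rho.to_numpy()
    q = p_adj.to_numpy()
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = (np.abs(r[iu, ju]) > threshold) & (q[iu, ju] < alpha)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(ids[i], ids[j], rho=float(r[i, j]), p_adj=float(q[i, j]))
    if g.number_of_edges() == 0:
        warnings.warn(
            f"no edge survives threshold={threshold}, alpha={alpha}",
            EmptyNetworkWarning,
            stacklevel=2,
        )
    return CorrelationNetwork(graph=g, threshold=threshold, alpha=alpha)


def _degree_frequency(network: CorrelationNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Degree-frequency table over strictly positive degrees, ascending."""
    degs = [d for _, d in network.graph.degree() if d >= 1]
    counts = Counter(degs)
    d = np.array(sorted(counts), dtype=float)
    f = np.array([counts[int(x)] for x in d], dtype=float)
    return d, f


def _fit_powerlaw(d: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Nonlinear least-squares fit of f = c * d**(-gamma); returns (c, gamma, R^2).

    Starting values come from a log-log OLS line when possible; if the
    Levenberg-Marquardt iteration fails to converge the starting values are
    kept and R^2 evaluated at them.
    """
    pos = f > 0
    if pos.sum() >= 2 and np.ptp(np.log(d[pos])) > 0:
        slope, intercept = np.polyfit(np.log(d[pos]), np.log(f[pos]), 1)
        p0 = (float(np.exp(intercept)), float(-slope))
    else:
        p0 = (float(f.max()), 2.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singular covariance is fine
            popt, _ = curve_fit(
                lambda x, c, g: c * np.power(x, -g), d, f, p0=p0, maxfev=5000
            )
        c, gamma = float(popt[0]), float(popt[1])
    except RuntimeError:
        c, gamma = p0
    pred = c * np.power(d, -gamma)
    ss_res = float(np.sum((f - pred) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return c, gamma, r2


def powerlaw_r2(
    network: CorrelationNetwork,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = 0,
) -> ScaleFreeFit:
    """Goodness of fit of the degree distribution to a power law.

    Builds the degree-frequency table over degrees >= 1, fits
    f(d) = c * d**(-gamma) by nonlinear least squares, and reports
    R^2 = 1 - SS_res / SS_tot.  Significance is assessed by permuting the
    frequency values across the observed degree values ``n_perm`` times,
    refitting, and counting permuted R^2 >= observed with the (b+1)/(n+1)
    correction.  Fewer than three distinct degrees make the fit degenerate
    (R^2 = NaN).
    """
    d, f = _degree_frequency(network)
    n_edges = network.n_edges
    if len(d) < 3:
        warnings.warn(
            f"only {len(d)} distinct degree value(s); power-law fit degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return ScaleFreeFit(network.threshold, np.nan, np.nan, np.nan, np.nan,
                            n_edges, len(d))
    c, gamma, r2 = _fit_powerlaw(d, f)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        _, _, r2_perm = _fit_powerlaw(d, rng.permutation(f))
        if not np.isnan(r2_perm) and r2_perm >= r2 - 1e-12:
            exceed += 1
    pvalue = (exceed + 1) / (n_perm + 1)
    return ScaleFreeFit(network.threshold, r2, pvalue, c, gamma, n_edges, len(d))


def select_threshold(
    table: AbundanceTable,
    grid: Sequence[float] = DEFAULT_GRID,
    alpha: float = 0.05,
    p_adjust: str = "bh",
    n_perm: int = 1000,
    seed: int | None = 0,
    p_max: float = 0.05,
) -> tuple[float, list[ScaleFreeFit]]:
    """Scan a threshold grid and pick the scale-free optimum.

    For every grid threshold the sparsified network's degree distribution is
    fitted to a power law; the threshold with the highest R^2 among fits with
    permutation p <= ``p_max`` is returned, together with the full fit table.

    Raises
    ------
    NoValidThreshold
        When no grid point yields a significant, non-degenerate fit.
    """
    rho, pvals = spearman_matrix(table)
    rng = np.random.default_rng(seed)
    fits: list[ScaleFreeFit] = []
    for thr in grid:
        if not 0 <= thr <= 1:
            raise ValueError("grid thresholds must lie in [0, 1]")
        if thr >= 1.0:
            # |rho| > 1 is impossible: empty network by construction
            fits.append(ScaleFreeFit(thr, np.nan, np.nan, np.nan, np.nan, 0, 0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptyNetworkWarning)
            net = sparsify(rho, pvals, thr, alpha=alpha, p_adjust=p_adjust)
        if net.n_edges == 0:
            fits.append(ScaleFreeFit(thr, np.nan, np.nan, np.nan, np.nan, 0, 0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateFitWarning)
            fits.append(powerlaw_r2(net, n_perm=n_perm, seed=rng))
    valid = [ft for ft in fits
             if not np.isnan(ft.r2) and ft.pvalue <= p_max and ft.n_edges >= 1]
    if not valid:
        raise NoValidThreshold(
            "no grid threshold gives a permutation-significant power-law fit; "
            "set a manual threshold"
        )
    best = max(valid, key=lambda ft: (ft.r2, -ft.threshold))
    return best.threshold, fits


def write_edge_list(network: CorrelationNetwork, path: str | Path) -> None:
    """Write the edge list as TSV (source, target, rho, p_adj)."""
    rows = [
        (u, v, d["rho"], d["p_adj"])
        for u, v, d in sorted(network.graph.edges(data=True))
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "rho", "p_adj"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(network: CorrelationNetwork, path: str | Path) -> None:
    """Write the network as GraphML with node weight/phylum attributes."""
    nx.write_graphml(network.graph, str(path))


def write_fit_table(fits: Iterable[ScaleFreeFit], path: str | Path) -> None:
    """Write the per-threshold fit table as TSV (threshold, R2, pvalue, ...)."""
    df = pd.DataFrame(
        [
            (ft.threshold, ft.r2, ft.pvalue, ft.c, ft.gamma, ft.n_edges,
             ft.n_distinct_degrees)
            for ft in fits
        ],
        columns=["threshold", "r2", "pvalue", "c", "gamma", "n_edges",
                 "n_distinct_degrees"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
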