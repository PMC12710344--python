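"""Integrated rank-sum ratio / entropy-weight (RSR-EWM) composite scoring.

Multi-criteria evaluation of m objects (subnetworks, or the nodes of one
subnetwork) on n indicators of heterogeneous scale:

1. min-max standardize each indicator to [0, 1], reversing "smaller is
   better" columns;
2. rank objects within each indicator (average ranks on ties; larger is
   better gets the larger rank, reversed for negative indicators);
3. weight indicators objectively by the entropy-weight method — indicators
   with more dispersion carry less entropy and hence more weight; a constant
   indicator gets weight zero;
4. combine into the weighted rank-sum ratio WRSR_i = (1/mn) sum_j W_j R_ij;
5. convert the downward cumulative frequencies of the sorted WRSR to probit
   units (standard normal quantile + 5, top item corrected to 1 - 1/(4m));
6. regress WRSR on the probit unit and use the fitted line for grade
   binning; rank objects by WRSR (rank 1 = best).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AllConstant,
    ConstantIndicatorWarning,
    FewerThanTwoObjects,
    MultipleBestWarning,
    NegativeSlopeWarning,
    SingularFit,
)
from .topology import TopologyTable

__all__ = [
    "ScoreReport",
    "standardize",
    "rank_matrix",
    "entropy_weights",
    "wrsr",
    "probit_units",
    "fit_regression",
    "score_table",
    "select_best",
]

DEFAULT_BIN_EDGES: tuple[float, float] = (4.5, 5.5)


@dataclass
class ScoreReport:
    """Complete RSR-EWM evaluation of one object set."""

    Z: pd.DataFrame
    R: pd.DataFrame
    p_mat: pd.DataFrame
    entropies: pd.Series
    weights: pd.Series
    wrsr: pd.Series
    weighted_rank_sum: pd.Series  # sum_j W_j R_ij without the 1/(mn) factor
    cum_freq: pd.Series
    probit: pd.Series
    regression: dict[str, float]  # a, b, r2, pvalue
    fitted: pd.Series
    grades: pd.Series
    final_rank: pd.Series

    @property
    def object_ids(self) -> list:
        return list(self.wrsr.index)

    def table(self) -> pd.DataFrame:
        """Score table in rank order (best first)."""
        df = pd.DataFrame(
            {
                "WRSR": self.wrsr,
                "weighted_rank_sum": self.weighted_rank_sum,
                "cum_freq": self.cum_freq,
                "probit": self.probit,
                "fitted": self.fitted,
                "grade": self.grades,
                "rank": self.final_rank,
            }
        )
        return df.sort_values(["rank", "WRSR"], ascending=[True, False])

    def write(self, path: str | Path) -> None:
        self.table().to_csv(path, sep="\t", float_format="%.6g",
                            index_label="object")


def standardize(X: pd.DataFrame, directions: dict[str, int]) -> pd.DataFrame:
    """Min-max standardize to [0, 1]; negative indicators are reversed.

    Constant columns map to all zeros (with a warning): they cannot separate
    objects and receive zero entropy weight downstream.
    """
    if X.shape[0] < 2:
        raise FewerThanTwoObjects("standardization needs >= 2 objects")
    Z = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi == lo:
            warnings.warn(f"indicator {col!r} is constant; standardized to 0",
                          ConstantIndicatorWarning, stacklevel=2)
            Z[col] = 0.0
            continue
        z = (x - lo) / (hi - lo)
        if directions.get(col, 1) < 0:
            z = 1.0 - z
        Z[col] = z
    return Z


def rank_matrix(X: pd.DataFrame, directions: dict[str, int]) -> pd.DataFrame:
    """Within-indicator average ranks; better values get larger ranks.

    Positive indicators are ranked ascending (the largest value receives
    rank m); negative indicators are ranked descending.  NaNs (e.g. a path
    length on a singleton) are treated as worst and share the lowest ranks.
    """
    R = pd.DataFrame(index=X.index, columns=X.columns, dtype=float)
    m = X.shape[0]
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        sign = directions.get(col, 1)
        vals = x if sign >= 0 else -x
        # push NaN to the bottom of the ranking
        worst = np.nanmin(vals) - 1.0 if np.isnan(vals).any() else None
        if worst is not None:
            vals = np.where(np.isnan(vals), worst, vals)
        R[col] = stats.rankdata(vals, method="average")
    assert R.shape[0] == m
    return R


def _proportion_entropy_weights(
    M: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Entropy weights from column proportions of a non-negative matrix.

    p_ij = M_ij / sum_i M_ij; e_j = -(1/ln m) sum_i p_ij ln p_ij with the
    0 ln 0 = 0 convention; W_j = (1 - e_j) / sum_j (1 - e_j).  A column
    whose proportions are uniform (e.g. a constant rank column) or whose
    sum is zero has maximum entropy and weight zero.
    """
    m = M.shape[0]
    if m < 2:
        raise FewerThanTwoObjects("entropy weights need >= 2 objects")
    z = M.to_numpy(dtype=float)
    col_sum = z.sum(axis=0)
    p = np.zeros_like(z)
    nonzero = col_sum > 0
    p[:, nonzero] = z[:, nonzero] / col_sum[nonzero]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    e = -plogp.sum(axis=0) / math.log(m)
    e[~nonzero] = 1.0  # no information: max entropy, zero weight
    e = np.clip(e, 0.0, 1.0)  # guard rounding at the uniform limit
    one_minus = 1.0 - e
    total = one_minus.sum()
    if total <= 0:
        raise AllConstant("every indicator is constant; weights undefined")
    w = one_minus / total
    cols = M.columns
    return (
        pd.DataFrame(p, index=M.index, columns=cols),
        pd.Series(e, index=cols, name="entropy"),
        pd.Series(w, index=cols, name="weight"),
    )


def entropy_weights(
    Z: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Entropy-weight method on a min-max standardized matrix.

    The literal textbook formulation: proportions are taken over the
    standardized values, so a constant (all-zero) column gets weight 0.
    Note that because standardized minima are exactly 0, columns with one
    dominant object concentrate their proportion mass and can draw most of
    the weight; :func:`score_table` therefore defaults to taking the
    proportions over the rank matrix instead (``weight_basis='ranks'``),
    which reproduces the published behavior of the composite model on
    rank-ordered inputs.
    """
    z = Z.to_numpy(dtype=float)
    if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
        raise ValueError("Z must be standardized to [0, 1]")
    return _proportion_entropy_weights(Z)


def wrsr(R: pd.DataFrame, W: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Weighted rank-sum ratio and the raw weighted rank sum.

    WRSR_i = (1/(m n)) sum_j W_j R_ij.  The unscaled sum_j W_j R_ij is also
    returned: orderings agree, only the scale differs.
    """
    m, n = R.shape
    raw = (R * W.reindex(R.columns)).sum(axis=1)
    return raw / (m * n), raw.rename("weighted_rank_sum")


def probit_units(wrsr_values: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Downward cumulative frequencies of WRSR and their probit units.

    Objects are ranked by WRSR ascending with average ranks on ties; the
    cumulative frequency of object i is Rbar_i / m, the top item corrected
    to 1 - 1/(4m) so the normal quantile stays finite.  The probit unit is
    the standard normal quantile of the cumulative frequency plus five.
    """
    m = len(wrsr_values)
    if m < 2:
        raise FewerThanTwoObjects("probit conversion needs >= 2 objects")
    ranks = stats.rankdata(wrsr_values.to_numpy(), method="average")
    cf = ranks / m
    cf = np.where(cf >= 1.0, 1.0 - 1.0 / (4 * m), cf)
    probit = stats.norm.ppf(cf) + 5.0
    idx = wrsr_values.index
    return (
        pd.Series(cf, index=idx, name="cum_freq"),
        pd.Series(probit, index=idx, name="probit"),
    )


def fit_regression(wrsr_values: pd.Series,
                   probit: pd.Series) -> dict[str, float]:
    """OLS of WRSR on the probit unit: WRSR_hat = a + b * probit."""
    if len(wrsr_values) < 3:
        raise FewerThanTwoObjects("regression needs >= 3 objects")
    x = probit.to_numpy(dtype=float)
    y = wrsr_values.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise SingularFit("probit values are constant; cannot fit")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        warnings.warn("WRSR ~ probit slope is not positive",
                      NegativeSlopeWarning, stacklevel=2)
    return {
        "a": float(res.intercept),
        "b": float(res.slope),
        "r2": float(res.rvalue**2),
        "pvalue": float(res.pvalue),
    }


def _grades(probit: pd.Series,
            edges: tuple[float, float] = DEFAULT_BIN_EDGES) -> pd.Series:
    lo, hi = edges
    out = []
    for v in probit:
        if v < lo:
            out.append("low")
        elif v <= hi:
            out.append("middle")
        else:
            out.append("high")
    return pd.Series(out, index=probit.index, name="grade")


def _final_ranks(wrsr_values: pd.Series, raw: pd.Series) -> pd.Series:
    """Rank 1 = best (largest WRSR); ties by larger raw rank sum, then id."""
    order = sorted(
        wrsr_values.index,
        key=lambda i: (-wrsr_values[i], -raw[i], str(i)),
    )
    rank = pd.Series(0, index=wrsr_values.index, dtype=int, name="rank")
    prev_key = None
    r = 0
    for pos, i in enumerate(order, start=1):
        key = (wrsr_values[i], raw[i])
        if key != prev_key:
            r = pos
            prev_key = key
        rank[i] = r
    return rank


def score_table(
    X: TopologyTable | pd.DataFrame,
    directions: dict[str, int] | None = None,
    bin_edges: tuple[float, float] = DEFAULT_BIN_EDGES,
    weight_basis: str = "ranks",
) -> ScoreReport:
    """Run the full RSR-EWM evaluation on an objects x indicators matrix.

    ``weight_basis`` selects the matrix whose column proportions feed the
    entropy weights: ``'ranks'`` (default — the model evaluates rank-ordered
    values, and this basis reproduces the published composite rankings on
    printed indicator tables) or ``'standardized'`` (proportions over the
    min-max standardized values).
    """
    if isinstance(X, TopologyTable):
        mat, dirs = X.indicators, X.directions
    else:
        mat, dirs = X, directions or {}
    if mat.shape[0] < 2:
        raise FewerThanTwoObjects("RSR-EWM needs >= 2 objects")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantIndicatorWarning)
        Z = standardize(mat, dirs)
    R = rank_matrix(mat, dirs)
    if weight_basis == "ranks":
        p_mat, e, W = _proportion_entropy_weights(R)
    elif weight_basis == "standardized":
        p_mat, e, W = entropy_weights(Z)
    else:
        raise ValueError(f"unknown weight_basis: {weight_basis!r}")
    w_ratio, raw = wrsr(R, W)
    w_ratio = w_ratio.rename("WRSR")
    cf, probit = probit_units(w_ratio)
    if mat.shape[0] >= 3 and np.ptp(probit.to_numpy()) > 0:
        reg = fit_regression(w_ratio, probit)
        fitted = reg["a"] + reg["b"] * probit
    else:
        reg = {"a": math.nan, "b": math.nan, "r2": math.nan,
               "pvalue": math.nan}
        fitted = probit.copy() * math.nan
    grades = _grades(probit, bin_edges)
    ranks = _final_ranks(w_ratio, raw)
    if (ranks == 1).sum() > 1:
        warnings.warn("multiple objects tie for the best composite score",
                      MultipleBestWarning, stacklevel=2)
    return ScoreReport(
        Z=Z, R=R, p_mat=p_mat, entropies=e, weights=W, wrsr=w_ratio,
        weighted_rank_sum=raw, cum_freq=cf, probit=probit, regression=reg,
        fitted=fitted.rename("fitted"), grades=grades, final_rank=ranks,
    )


def select_best(report: ScoreReport):
    """Id of the rank-1 object (deterministic under the tie-break rules)."""
    best = report.final_rank[report.final_rank == 1].index
    return sorted(best, key=str)[0]
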