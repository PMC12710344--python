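"""Abundance table container, total-sum-scaling normalization and taxon filtering.

The entry point of the pipeline is a non-negative taxa-by-samples matrix of
read counts (or pre-computed relative abundances).  Counts are made comparable
across samples by total sum scaling (TSS): each sample column is divided by
its column sum so that relative abundances sum to one per sample.  Rare taxa
are then removed with a joint abundance/prevalence filter, which reduces the
sparsity of the matrix before correlations are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import AllFiltered, EmptySample

__all__ = [
    "AbundanceTable",
    "read_abundance",
    "read_taxonomy",
    "normalize_tss",
    "filter_taxa",
]


@dataclass(frozen=True)
class AbundanceTable:
    """A taxa x samples abundance matrix with optional taxon->phylum metadata.

    Parameters
    ----------
    values
        DataFrame with taxa as rows and samples as columns; entries are raw
        read counts or relative abundances, all non-negative and finite.
    taxon_meta
        Optional mapping from taxon id to phylum (or any higher-rank label),
        carried along as node metadata for network export and plotting.
    is_relative
        True when values are on the relative-abundance scale.  Freshly
        TSS-normalized columns sum to one; after taxon filtering the column
        sums drop below one (filtering never re-normalizes), which
        ``is_filtered`` records.
    """

    values: pd.DataFrame
    taxon_meta: dict[str, str] | None = None
    is_relative: bool = False
    is_filtered: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.isna().any().any():
            raise ValueError("abundance matrix contains missing values")
        if (v.to_numpy() < 0).any():
            raise ValueError("abundance matrix contains negative entries")
        if v.index.duplicated().any():
            raise ValueError("taxon ids are not unique")
        if v.columns.duplicated().any():
            raise ValueError("sample ids are not unique")
        if self.is_relative and not self.is_filtered:
            sums = v.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("is_relative set but columns do not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_taxa(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def mean_abundance(self) -> pd.Series:
        """Mean (relative) abundance of each taxon across samples."""
        return self.values.mean(axis=1)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon has a strictly positive value."""
        return (self.values > 0).mean(axis=1)


def read_abundance(path: str | Path, *, is_relative: bool = False,
                   taxon_meta: dict[str, str] | None = None) -> AbundanceTable:
    """Read a TSV/CSV abundance table (first column taxon id, header sample ids)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return AbundanceTable(df.astype(float), taxon_meta=taxon_meta,
                         is_relative=is_relative)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (taxon, phylum) TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy table needs at least two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def normalize_tss(table: AbundanceTable) -> AbundanceTable:
    """Total-sum-scaling: divide each sample column by its sum.

    Raises
    ------
    EmptySample
        If any sample column sums to zero.
    """
    sums = table.values.sum(axis=0)
    empty = sums[sums == 0].index.tolist()
    if empty:
        raise EmptySample(f"sample columns with zero total counts: {empty}")
    rel = table.values.div(sums, axis=1)
    return replace(table, values=rel, is_relative=True)


def filter_taxa(
    table: AbundanceTable,
    abundance_min: float = 2e-4,
    prevalence_min: float = 0.30,
    abundance_mode: Literal["mean", "max"] = "mean",
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Remove low-abundance / low-frequency taxa from a relative-abundance table.

    A taxon is retained when its abundance summary (mean across samples by
    default, maximum with ``abundance_mode='max'``) is at least
    ``abundance_min`` AND its prevalence (fraction of samples where it is
    strictly positive) is at least ``prevalence_min``.  Boundary values are
    retained.  Columns are deliberately NOT re-normalized after filtering:
    downstream Spearman correlations depend only on within-sample ranks,
    which a per-sample rescale cannot change.

    Returns
    -------
    (filtered_table, removal_log)
        The filtered table and a DataFrame (taxon, mean_abundance,
        prevalence, reason) for every removed taxon.

    Raises
    ------
    AllFiltered
        If no taxon survives.
    """
    if not table.is_relative:
        raise ValueError("filter_taxa expects a TSS-normalized table")
    if abundance_mode == "mean":
        abun = table.mean_abundance()
    elif abundance_mode == "max":
        abun = table.values.max(axis=1)
    else:
        raise ValueError(f"unknown abundance_mode: {abundance_mode!r}")
    prev = table.prevalence()
    keep = (abun >= abundance_min) & (prev >= prevalence_min)
    if not keep.any():
        raise AllFiltered("no taxon passes the abundance/prevalence filter")
    removed = table.values.index[~keep]
    reasons = []
    for t in removed:
        why = []
        if abun[t] < abundance_min:
            why.append(f"abundance<{abundance_min:g}")
        if prev[t] < prevalence_min:
            why.append(f"prevalence<{prevalence_min:g}")
        reasons.append(";".join(why))
    log = pd.DataFrame(
        {
            "taxon": list(removed),
            "mean_abundance": abun[removed].to_numpy(),
            "prevalence": prev[removed].to_numpy(),
            "reason": reasons,
        }
    )
    kept = table.values.loc[keep]
    meta = None
    if table.taxon_meta is not None:
        meta = {t: p for t, p in table.taxon_meta.items() if t in kept.index}
    filtered = AbundanceTable(kept, taxon_meta=meta, is_relative=True,
                              is_filtered=True)
    return filtered, log
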