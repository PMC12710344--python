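"""Planted-bicluster abundance matrices with ground-truth member labels.

The generator emulates a bicluster-style benchmark: a taxa x samples matrix
of i.i.d. Gaussian background noise, on top of which each planted cluster
adds a rank-one signal — the outer product of per-taxon loadings and
per-sample factors — over a predefined block of rows and columns.  Taxa of
the same block therefore co-vary strongly across the block's samples, which
a co-occurrence network should recover as one community.  The matrix is
min-shifted to non-negativity and TSS-normalized so it behaves like a
relative-abundance table.  Block positions and sizes are deterministic
functions of the parameters; only loadings, factors and noise are random,
making every dataset bit-for-bit reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidBlocks
from .preprocess import AbundanceTable

__all__ = [
    "PlantedDataset",
    "planted_block_layout",
    "make_planted_abundance",
    "make_benchmark_suite",
    "write_dataset",
]


@dataclass
class PlantedDataset:
    """A synthetic abundance matrix plus its ground-truth cluster labels."""

    matrix: pd.DataFrame  # taxa x samples, non-negative, TSS-normalized
    true_clusters: list[frozenset]
    params: dict

    def table(self) -> AbundanceTable:
        return AbundanceTable(self.matrix, is_relative=True)

    def labels(self) -> pd.DataFrame:
        rows = [
            (t, k + 1)
            for k, cluster in enumerate(self.true_clusters)
            for t in sorted(cluster)
        ]
        return pd.DataFrame(rows, columns=["taxon", "cluster_id"])


def planted_block_layout(
    n_taxa: int,
    n_samples: int,
    n_clusters: int,
    size_min: int,
    size_max: int,
    sample_width: int,
) -> list[tuple[range, range]]:
    """Deterministic (taxon rows, sample columns) block positions.

    Cluster sizes are evenly spread between ``size_min`` and ``size_max``;
    taxon blocks are consecutive and disjoint starting at row 0; sample
    blocks of fixed width are staggered evenly across the columns (they may
    overlap between clusters — only taxon membership defines the truth).
    """
    if n_clusters < 1:
        raise InvalidBlocks("need at least one cluster")
    sizes = np.rint(np.linspace(size_min, size_max, n_clusters)).astype(int)
    if sizes.sum() > n_taxa:
        raise InvalidBlocks(
            f"cluster sizes sum to {sizes.sum()} > n_taxa={n_taxa}"
        )
    if sample_width > n_samples:
        raise InvalidBlocks("sample_width exceeds n_samples")
    blocks = []
    row = 0
    for b, s in enumerate(sizes):
        if n_clusters == 1:
            start = 0
        else:
            start = round(b * (n_samples - sample_width) / (n_clusters - 1))
        blocks.append((range(row, row + int(s)),
                       range(start, start + sample_width)))
        row += int(s)
    return blocks


def make_planted_abundance(
    n_taxa: int = 100,
    n_samples: int = 50,
    n_clusters: int = 5,
    size_min: int = 10,
    size_max: int = 15,
    sample_width: int | None = None,
    signal_strength: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> PlantedDataset:
    """Generate one planted-cluster abundance matrix.

    ``signal_strength`` is the standard deviation of the per-taxon loadings
    (factors are standard normal), so the planted signal dominates the unit
    background noise by that ratio on average.  ``sample_width`` defaults to
    half the samples, giving within-block correlations strong enough to
    survive co-occurrence thresholds while the other half of each taxon's
    profile stays pure noise.
    """
    if sample_width is None:
        sample_width = n_samples // 2
    blocks = planted_block_layout(
        n_taxa, n_samples, n_clusters, size_min, size_max, sample_width
    )
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, noise_sd, size=(n_taxa, n_samples))
    for rows, cols in blocks:
        loadings = rng.normal(0.0, signal_strength, size=len(rows))
        factors = rng.normal(0.0, 1.0, size=len(cols))
        X[np.ix_(list(rows), list(cols))] += np.outer(loadings, factors)
    X -= X.min()  # min-shift to non-negativity
    col_sums = X.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    X = X / col_sums
    width = len(str(n_taxa))
    taxa = [f"taxon_{i + 1:0{width}d}" for i in range(n_taxa)]
    samples = [f"sample_{j + 1:02d}" for j in range(n_samples)]
    matrix = pd.DataFrame(X, index=taxa, columns=samples)
    clusters = [frozenset(taxa[i] for i in rows) for rows, _ in blocks]
    params = {
        "n_taxa": n_taxa,
        "n_samples": n_samples,
        "n_clusters": n_clusters,
        "size_min": size_min,
        "size_max": size_max,
        "sample_width": sample_width,
        "signal_strength": signal_strength,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return PlantedDataset(matrix, clusters, params)


def make_benchmark_suite(
    n_datasets: int = 50,
    base_seed: int = 0,
    **params,
) -> list[PlantedDataset]:
    """A suite of planted datasets with seeds base_seed .. base_seed+n-1."""
    return [
        make_planted_abundance(seed=base_seed + k, **params)
        for k in range(n_datasets)
    ]


def write_dataset(ds: PlantedDataset, outdir: str | Path,
                  prefix: str = "dataset") -> None:
    """Write abundance TSV, labels TSV and params JSON for one dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.matrix.to_csv(outdir / f"{prefix}_abundance.tsv", sep="\t",
                     float_format="%.8g", index_label="taxon")
    ds.labels().to_csv(outdir / f"{prefix}_labels.tsv", sep="\t", index=False)
    (outdir / f"{prefix}_params.json").write_text(
        json.dumps(ds.params, indent=2, sort_keys=True) + "\n"
    )
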