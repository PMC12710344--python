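"""Sensitivity / positive predictive value / geometric accuracy of a
predicted key-subnetwork taxon set against planted ground-truth clusters.

The predicted set is matched to the true cluster with the largest overlap;
Sn = TP / |cluster| (how much of the true cluster was found), PPV =
TP / |predicted| (how much of the prediction is real), and Acc is their
geometric mean, balancing the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import NoTruth

__all__ = ["ClusterEvaluation", "evaluate_prediction", "write_evaluations"]


@dataclass(frozen=True)
class ClusterEvaluation:
    sn: float
    ppv: float
    acc: float
    tp: int
    fp: int
    fn: int
    matched_cluster: int  # index into the truth list, -1 for empty prediction


def evaluate_prediction(
    predicted: Iterable, truth: Sequence[Iterable]
) -> ClusterEvaluation:
    """Score a predicted taxon set against the best-overlapping true cluster.

    An empty prediction scores (0, 0, 0).  Ties in overlap are broken toward
    the smaller cluster (higher Sn), then by truth order, deterministically.
    """
    truth_sets = [frozenset(c) for c in truth]
    if not truth_sets:
        raise NoTruth("no true clusters to evaluate against")
    pred = frozenset(predicted)
    if not pred:
        return ClusterEvaluation(0.0, 0.0, 0.0, 0, 0, 0, -1)
    overlaps = [len(pred & c) for c in truth_sets]
    best = min(
        range(len(truth_sets)),
        key=lambda k: (-overlaps[k], len(truth_sets[k]), k),
    )
    cluster = truth_sets[best]
    tp = overlaps[best]
    sn = tp / len(cluster)
    ppv = tp / len(pred)
    return ClusterEvaluation(
        sn=sn,
        ppv=ppv,
        acc=sqrt(sn * ppv),
        tp=tp,
        fp=len(pred) - tp,
        fn=len(cluster) - tp,
        matched_cluster=best,
    )


def write_evaluations(rows: Sequence[tuple[str, ClusterEvaluation]],
                      path: str | Path) -> None:
    """Write (dataset_id, sn, ppv, acc) rows as TSV."""
    df = pd.DataFrame(
        [(name, ev.sn, ev.ppv, ev.acc) for name, ev in rows],
        columns=["dataset_id", "sn", "ppv", "acc"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
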