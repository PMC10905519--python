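"""Evaluation harness: confusion-matrix metrics, rank correlations, and
cross-designer agreement matrices (consensus and Jaccard)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts plus derived rates; a rate whose denominator is zero is None
    with the reason recorded, never silently 0."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    recall: float | None
    accuracy: float
    f1: float | None
    undefined: dict[str, str]


def confusion_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMetrics:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("need equal-length non-empty binary vectors")
    if set(np.unique(yt)) - {0, 1} or set(np.unique(yp)) - {0, 1}:
        raise ValueError("vectors must be binary (0/1)")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    undefined: dict[str, str] = {}
    precision = recall = f1 = None
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        undefined["precision"] = "no positive predictions (TP+FP=0)"
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        undefined["recall"] = "no positive truths (TP+FN=0)"
    accuracy = (tp + tn) / yt.size
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.setdefault("f1", "precision+recall zero or undefined")
    return ConfusionMetrics(tp, fp, tn, fn, precision, recall, accuracy, f1, undefined)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of mid-ranks (average ranks on ties)."""
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def kendall(x: Sequence[float], y: Sequence[float]) -> float:
    """Kendall tau-b (tie-corrected), usable on binary vectors."""
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


def consensus_matrix(pred_sets: Mapping[str, set[Hashable]]) -> pd.DataFrame:
    """C[i][j] = |P_i intersect P_j| / |P_i|: the fraction of designer i's
    recommendations also made by j. Diagonal 1; not symmetric in general."""
    names = list(pred_sets)
    mat = np.zeros((len(names), len(names)))
    for a, na in enumerate(names):
        pa = pred_sets[na]
        if not pa:
            raise ValueError(f"empty recommendation set for {na!r}")
        for b, nb in enumerate(names):
            mat[a, b] = len(pa & pred_sets[nb]) / len(pa)
    return pd.DataFrame(mat, index=names, columns=names)


def jaccard_matrix(pred_sets: Mapping[str, set[Hashable]]) -> pd.DataFrame:
    """J[i][j] = |P_i intersect P_j| / |P_i union P_j|; symmetric, diag 1."""
    names = list(pred_sets)
    mat = np.zeros((len(names), len(names)))
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            union = pred_sets[na] | pred_sets[nb]
            if not union:
                raise ValueError(f"both sets empty: {na!r}, {nb!r}")
            mat[a, b] = len(pred_sets[na] & pred_sets[nb]) / len(union)
    return pd.DataFrame(mat, index=names, columns=names)


def guide_key(
    guide: str,
    chrom: str | None = None,
    start: int | None = None,
    strand: str | None = None,
) -> Hashable:
    """Set-membership key for a recommended guide: coordinates when known,
    otherwise the bare sequence — avoids spurious matches across loci."""
    if chrom is not None and start is not None and strand is not None:
        return (chrom, start, strand, guide)
    return guide
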