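"""Accuracy measures for inferred skeletons against a gold standard.

All counts are over the n(n-1)/2 unordered gene pairs (self-pairs excluded);
directed gold standards are symmetrized upstream since the inference output
is an undirected skeleton.  Standard definitions are used throughout:

    ACC = (TP + TN) / (TP + FP + TN + FN)
    TPR = TP / (TP + FN)        FPR = FP / (FP + TN)
    PPV = TP / (TP + FP)        F1  = 2 TP / (2 TP + FP + FN)

The ROC sweeps all score thresholds with tied scores grouped into single
curve steps; the trapezoidal AUC then equals the Mann-Whitney statistic
(probability that a random gold edge outscores a random non-edge, ties
counted one half).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .netgen import GoldStandard

__all__ = ["ConfusionCounts", "RocCurve", "confusion", "metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_pair_set(pred: Iterable[tuple[int, int]]) -> set[tuple[int, int]]:
    out = set()
    for e in pred:
        i, j = int(e[0]), int(e[1])
        if i == j:
            raise ValueError(f"self-pair ({i}, {j}) in prediction")
        out.add((min(i, j), max(i, j)))
    return out


def confusion(
    pred: Iterable[tuple[int, int]], gold: GoldStandard
) -> ConfusionCounts:
    """Confusion counts of a predicted edge set over all unordered pairs."""
    pred_set = _as_pair_set(pred)
    for i, j in pred_set:
        if not (0 <= i < gold.n and 0 <= j < gold.n):
            raise ValueError(
                f"predicted pair ({i}, {j}) outside the gold standard's "
                f"{gold.n} genes"
            )
    gold_set = set(gold.edges)
    total = gold.n * (gold.n - 1) // 2
    tp = len(pred_set & gold_set)
    fp = len(pred_set - gold_set)
    fn = len(gold_set - pred_set)
    tn = total - tp - fp - fn
    return ConfusionCounts(tp, fp, tn, fn)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                      stacklevel=3)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> Mapping[str, float]:
    """ACC, TPR, FPR, PPV and F1 from confusion counts."""
    return {
        "ACC": _safe_div(c.tp + c.tn, c.total, "ACC"),
        "TPR": _safe_div(c.tp, c.tp + c.fn, "TPR"),
        "FPR": _safe_div(c.fp, c.fp + c.tn, "FPR"),
        "PPV": _safe_div(c.tp, c.tp + c.fp, "PPV"),
        "F1": _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn, "F1"),
    }


def roc_auc(scores: np.ndarray, gold: GoldStandard) -> RocCurve:
    """ROC curve and AUC of a per-pair ranking against the gold standard.

    ``scores`` is a symmetric n x n matrix of finite ranking scores (the
    upper triangle is used).  Raises on an empty or complete gold standard,
    for which the ROC is degenerate.
    """
    scores = np.asarray(scores, dtype=float)
    n = gold.n
    if scores.shape != (n, n):
        raise ValueError(f"scores must be {n}x{n}")
    iu = np.triu_indices(n, 1)
    s = scores[iu]
    if not np.all(np.isfinite(s) | np.isposinf(s)):
        raise ValueError("all pair scores must be defined (finite or +inf)")
    labels = np.zeros(len(s), dtype=bool)
    idx = {(i, j): k for k, (i, j) in enumerate(zip(*map(np.ndarray.tolist, iu)))}
    for e in gold.edges:
        labels[idx[e]] = True
    n_pos = int(labels.sum())
    n_neg = len(s) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("gold standard is empty or complete: ROC degenerate")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    lab_sorted = labels[order]
    # group tied scores into single steps
    distinct = np.nonzero(np.diff(s_sorted))[0]
    step_ends = np.r_[distinct, len(s) - 1]
    tp_cum = np.cumsum(lab_sorted)[step_ends]
    fp_cum = np.cumsum(~lab_sorted)[step_ends]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, auc)
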