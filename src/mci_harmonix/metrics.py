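"""Confusion-table statistics for two-class screening problems.

The converter group (uHC) is the positive / "condition existing" class.
Alongside accuracy, F1 and the rate statistics, the module reports the
Matthews correlation coefficient and its normalized variant
MCC' = 0.5 * (1 + MCC), which lives in [0, 1] and compares visually with
accuracy and F1. AROC equals the Mann-Whitney U statistic normalized by
n+ * n-, with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionTable", "MetricSet", "confusion", "compute_metrics", "aroc"]

POSITIVE_CLASS = "uHC"


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total < 1:
            raise ValueError("confusion table must contain at least one case")

    @property
    def ce(self) -> int:  # condition existing
        return self.tp + self.fn

    @property
    def ca(self) -> int:  # condition absent
        return self.fp + self.tn

    @property
    def ep(self) -> int:  # examination positive
        return self.tp + self.fp

    @property
    def en(self) -> int:  # examination negative
        return self.fn + self.tn

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fn + other.fn,
            self.fp + other.fp, self.tn + other.tn,
        )


@dataclass(frozen=True)
class MetricSet:
    acc: float
    f1: float
    mcc: float
    mcc_prime: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    aroc: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        d = {
            "acc": self.acc, "f1": self.f1, "mcc": self.mcc,
            "mcc_prime": self.mcc_prime, "tpr": self.tpr, "tnr": self.tnr,
            "ppv": self.ppv, "npv": self.npv,
        }
        if self.aroc is not None:
            d["aroc"] = self.aroc
        return d


def confusion(labels_true, labels_pred, positive_class: str = POSITIVE_CLASS) -> ConfusionTable:
    """Cross-tabulate true vs predicted labels with the converter class positive."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.size == 0:
        raise ValueError("empty input")
    if yt.shape != yp.shape:
        raise ValueError("labels_true and labels_pred must have equal length")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    return ConfusionTable(
        tp=int(np.sum(pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    """num/den with the 0-margin convention: 0 when the denominator is 0."""
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(ct: ConfusionTable, scores=None, labels_true=None) -> MetricSet:
    """All derived statistics of a confusion table.

    MCC with any zero margin is defined as 0 (independence convention) and the
    result is flagged degenerate; likewise zero-denominator PPV/NPV/TPR/TNR.
    If ``scores`` and ``labels_true`` are given, AROC is included.
    """
    acc = (ct.tp + ct.tn) / ct.total
    tpr, d1 = _ratio(ct.tp, ct.ce)
    tnr, d2 = _ratio(ct.tn, ct.ca)
    ppv, d3 = _ratio(ct.tp, ct.ep)
    npv, d4 = _ratio(ct.tn, ct.en)
    f1, d5 = _ratio(2 * ppv * tpr, ppv + tpr)
    denom = ct.ce * ct.ca * ct.ep * ct.en
    if denom == 0:
        mcc, d6 = 0.0, True
    else:
        mcc = (ct.tp * ct.tn - ct.fp * ct.fn) / math.sqrt(denom)
        d6 = False
    area = None
    if scores is not None and labels_true is not None:
        area = aroc(scores, labels_true)
    return MetricSet(
        acc=acc, f1=f1, mcc=mcc, mcc_prime=0.5 * (1.0 + mcc),
        tpr=tpr, tnr=tnr, ppv=ppv, npv=npv, aroc=area,
        degenerate=any((d1, d2, d3, d4, d5, d6)),
    )


def aroc(scores, labels_true, positive_class: str = POSITIVE_CLASS) -> float:
    """Area under the ROC curve via the normalized Mann-Whitney U statistic."""
    s = np.asarray(scores, dtype=float)
    yt = np.asarray(labels_true) == positive_class
    n_pos, n_neg = int(yt.sum()), int((~yt).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("aroc requires at least one sample in each class")
    ranks = rankdata(s)  # midranks: ties count one half
    u = ranks[yt].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
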