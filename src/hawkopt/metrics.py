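"""One-vs-rest confusion-count metrics for multiclass classifiers.

Each class contributes four counts (TP, FP, TN, FN) against the rest; the
nine derived metrics are

    TPR = TP/(TP+FN)   sensitivity / recall        TNR = TN/(TN+FP)  specificity
    PPV = TP/(TP+FP)   precision                   NPV = TN/(TN+FN)
    FPR = FP/(FP+TN)                               FNR = FN/(TP+FN)
    FDR = FP/(TP+FP)                               ACC = (TP+TN)/(TP+FP+TN+FN)
    F1  = harmonic mean of PPV and TPR

Values are computed at full precision; rounding to three decimals is a
reporting choice, not part of the calculation.  A metric whose denominator
is zero is reported as None (undefined) rather than propagated as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = ["ConfusionCounts", "ClassMetrics", "class_metrics", "metrics_table"]

METRIC_COLUMNS = ["TPR", "TNR", "PPV", "NPV", "FPR", "FNR", "FDR", "ACC", "F1"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.tn, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    tpr: Optional[float]
    tnr: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    fdr: Optional[float]
    acc: Optional[float]
    f1: Optional[float]

    def as_dict(self) -> dict:
        return {
            "TPR": self.tpr, "TNR": self.tnr, "PPV": self.ppv, "NPV": self.npv,
            "FPR": self.fpr, "FNR": self.fnr, "FDR": self.fdr, "ACC": self.acc,
            "F1": self.f1,
        }


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    """All nine one-vs-rest metrics from the four counts."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("need at least one positive and one negative example")
    tpr = _ratio(c.tp, c.tp + c.fn)
    ppv = _ratio(c.tp, c.tp + c.fp)
    f1 = None
    if tpr is not None and ppv is not None and (tpr + ppv) > 0:
        f1 = 2.0 * ppv * tpr / (ppv + tpr)
    return ClassMetrics(
        tpr=tpr,
        tnr=_ratio(c.tn, c.tn + c.fp),
        ppv=ppv,
        npv=_ratio(c.tn, c.tn + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        fnr=_ratio(c.fn, c.tp + c.fn),
        fdr=_ratio(c.fp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
        f1=f1,
    )


def metrics_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Compute metric columns for a counts table.

    ``counts`` needs columns TP, FP, TN, FN (any index); the result carries
    the same index with the nine metric columns at full precision.
    """
    rows = []
    for _, row in counts.iterrows():
        m = class_metrics(
            ConfusionCounts(int(row["TP"]), int(row["FP"]), int(row["TN"]), int(row["FN"]))
        )
        rows.append(m.as_dict())
    return pd.DataFrame(rows, index=counts.index)
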