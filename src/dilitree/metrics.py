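"""Confusion-matrix statistics, ROC/AUC, contingency and stratified reports.

Positive class = DILI throughout.  Metrics with a zero denominator are
reported as undefined (``None``), never coerced to 0.  Printed values use
2-dp rounding, half away from zero; full precision is retained internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem.records import DiliClass

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "RocResult",
    "ContingencyReport",
    "ATCReport",
    "TrendReport",
    "confusion",
    "eq_metrics",
    "roc_auc",
    "amw_contingency",
    "atc_stratified",
    "yearly_amw_trend",
    "round_half_away",
    "ATC_FIRST_LEVEL_CODES",
]

ATC_FIRST_LEVEL_CODES = tuple("ABCDGHJLMNPRSV")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables;
    Python's builtin ``round`` is banker's rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricsReport:
    """Accuracy / sensitivity / specificity / balanced accuracy / MCC
    (undefined entries are ``None`` and listed in ``undefined``)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    balanced_accuracy: float | None
    mcc: float | None
    auc: float | None = None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity", "balanced_accuracy",
                     "mcc", "auc"):
            v = getattr(self, name)
            out[name] = None if v is None else round_half_away(v, ndigits)
        return out

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
            "auc": self.auc,
            "undefined": list(self.undefined),
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Tally TP/TN/FP/FN (positive = DILI = 1)."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty label vectors")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def eq_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Exact evaluation of the five standard statistics from a confusion
    matrix; the MCC denominator is the square root of the four marginal
    products."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []

    accuracy = (cm.tp + cm.tn) / cm.total

    if cm.tp + cm.fn > 0:
        sensitivity = cm.tp / (cm.tp + cm.fn)
    else:
        sensitivity = None
        undefined.append("sensitivity")

    if cm.tn + cm.fp > 0:
        specificity = cm.tn / (cm.tn + cm.fp)
    else:
        specificity = None
        undefined.append("specificity")

    if sensitivity is not None and specificity is not None:
        balanced_accuracy = (sensitivity + specificity) / 2.0
    else:
        balanced_accuracy = None
        undefined.append("balanced_accuracy")

    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom > 0:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    else:
        mcc = None
        undefined.append("mcc")

    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        balanced_accuracy=balanced_accuracy,
        mcc=mcc,
        undefined=tuple(undefined),
    )


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, y_true) -> RocResult:
    """ROC points at every distinct score threshold (higher score = more
    DILI-like) and trapezoid AUC, which equals the concordance probability
    with ties counted one half."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true, dtype=int)
    if s.shape != t.shape:
        raise ValueError("scores and labels length mismatch")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    # collapse tied scores into single operating points
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.r_[distinct, s.size - 1]
    tp_cum = np.cumsum(t_sorted == 1)[cut]
    fp_cum = np.cumsum(t_sorted == 0)[cut]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s_sorted[cut]]
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


@dataclass
class ContingencyRow:
    label: str
    ge: int
    lt: int

    @property
    def total(self) -> int:
        return self.ge + self.lt


@dataclass
class ContingencyReport:
    """Class-by-threshold contingency table with %-within-column cells."""

    rows: list[ContingencyRow]
    threshold: float

    ROW_ORDER = ("Most", "Less", "DILI", "no-DILI", "Total")

    def row(self, label: str) -> ContingencyRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    def percent_within_column(self, label: str, column: str, ndigits: int = 1) -> float:
        """Cell percentage relative to its column total (Total row = 100%)."""
        total_row = self.row("Total")
        r = self.row(label)
        col_total = {"ge": total_row.ge, "lt": total_row.lt, "total": total_row.total}[
            column
        ]
        count = {"ge": r.ge, "lt": r.lt, "total": r.total}[column]
        if col_total == 0:
            return float("nan")
        return round_half_away(100.0 * count / col_total, ndigits)

    def screen_metrics(self) -> MetricsReport:
        """Metrics of the 'AMW >= threshold -> positive' screen implied by
        the table (DILI row vs no-DILI row)."""
        dili = self.row("DILI")
        no = self.row("no-DILI")
        return eq_metrics(
            ConfusionMatrix(tp=dili.ge, fn=dili.lt, fp=no.ge, tn=no.lt)
        )

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "row": r.label,
                    "count_ge": r.ge,
                    "count_lt": r.lt,
                    "count_total": r.total,
                    "pct_ge": self.percent_within_column(r.label, "ge"),
                    "pct_lt": self.percent_within_column(r.label, "lt"),
                    "pct_total": self.percent_within_column(r.label, "total"),
                }
            )
        return pd.DataFrame(recs)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "rows": self.to_frame().to_dict(orient="records"),
        }


def amw_contingency(
    amw_values: Sequence[float],
    dili_classes: Sequence[DiliClass | str],
    threshold: float = 7.4,
) -> ContingencyReport:
    """Build the Most/Less/DILI/no-DILI vs AMW-threshold contingency table.

    The DILI row is the element-wise sum of the Most and Less rows; the
    boundary value itself counts as >= (positive side).
    """
    a = np.asarray(amw_values, dtype=float)
    if a.size != len(dili_classes):
        raise ValueError("amw values and classes length mismatch")
    if not np.isfinite(a).all():
        raise ValueError("all AMW values must be finite")
    classes = [c if isinstance(c, DiliClass) else DiliClass.parse(c) for c in dili_classes]

    counts = {cls: [0, 0] for cls in DiliClass}  # [ge, lt]
    for value, cls in zip(a, classes):
        counts[cls][0 if value >= threshold else 1] += 1

    most, less, no = counts[DiliClass.MOST], counts[DiliClass.LESS], counts[DiliClass.NO]
    dili = [most[0] + less[0], most[1] + less[1]]
    total = [dili[0] + no[0], dili[1] + no[1]]
    rows = [
        ContingencyRow("Most", *most),
        ContingencyRow("Less", *less),
        ContingencyRow("DILI", *dili),
        ContingencyRow("no-DILI", *no),
        ContingencyRow("Total", *total),
    ]
    return ContingencyReport(rows=rows, threshold=threshold)


@dataclass
class ATCRow:
    code: str
    cm: ConfusionMatrix
    metrics: MetricsReport
    n_dili: int
    n_nodili: int


@dataclass
class ATCReport:
    rows: list[ATCRow]
    total: ATCRow
    n_without_codes: int
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows + [self.total]:
            m = r.metrics
            recs.append(
                {
                    "atc": r.code,
                    "accuracy": m.accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "balanced_accuracy": m.balanced_accuracy,
                    "n_dili": r.n_dili,
                    "n_nodili": r.n_nodili,
                }
            )
        return pd.DataFrame(recs)

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_without_codes": self.n_without_codes,
            "rows": [
                {
                    "atc": r.code,
                    "n_dili": r.n_dili,
                    "n_nodili": r.n_nodili,
                    **r.metrics.as_dict(),
                }
                for r in self.rows + [self.total]
            ],
        }


def atc_stratified(
    amw_values: Sequence[float],
    dili_labels: Sequence[int],
    atc_codes: Sequence[Sequence[str]],
    threshold: float = 7.4,
) -> ATCReport:
    """Per-ATC-first-level performance of the AMW threshold screen.

    Drugs with several codes contribute once per code; drugs without codes
    are skipped and tallied in ``n_without_codes``; unknown letters go to an
    "other" bucket with a warning.  The Total row pools every (drug, code)
    evaluation, so pooled per-code confusion counts reproduce it exactly.
    """
    a = np.asarray(amw_values, dtype=float)
    labels = np.asarray(dili_labels, dtype=int)
    if not (a.size == labels.size == len(atc_codes)):
        raise ValueError("inputs must have equal length")

    buckets: dict[str, list[int]] = {}
    n_without = 0
    for i, codes in enumerate(atc_codes):
        codes = [c for c in codes if c]
        if not codes:
            n_without += 1
            continue
        for code in codes:
            code = code.strip().upper()
            if code not in ATC_FIRST_LEVEL_CODES:
                warnings.warn(f"unknown ATC first-level code {code!r}; using 'other'")
                code = "other"
            buckets.setdefault(code, []).append(i)

    def make_row(code: str, idx: list[int]) -> ATCRow:
        pred = (a[idx] >= threshold).astype(int)
        cm = confusion(labels[idx], pred)
        return ATCRow(
            code=code,
            cm=cm,
            metrics=eq_metrics(cm),
            n_dili=int((labels[idx] == 1).sum()),
            n_nodili=int((labels[idx] == 0).sum()),
        )

    ordered = [c for c in ATC_FIRST_LEVEL_CODES if c in buckets]
    if "other" in buckets:
        ordered.append("other")
    rows = [make_row(c, buckets[c]) for c in ordered]

    pooled_idx = [i for c in ordered for i in buckets[c]]
    if not pooled_idx:
        raise ValueError("no drug carries an ATC code; nothing to report")
    total = make_row("Total", pooled_idx)
    return ATCReport(rows=rows, total=total, n_without_codes=n_without, threshold=threshold)


@dataclass
class TrendReport:
    per_year: pd.DataFrame
    fraction_ge_threshold: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "fraction_ge_threshold": self.fraction_ge_threshold,
            "per_year": self.per_year.to_dict(orient="records"),
        }


def yearly_amw_trend(
    years: Sequence[int], amw_values: Sequence[float], threshold: float = 7.4
) -> TrendReport:
    """Per-year box-plot statistics of AMW (quartiles by linear
    interpolation, fences at 1.5*IQR) plus the overall fraction at or above
    the screening threshold."""
    y = np.asarray(years)
    a = np.asarray(amw_values, dtype=float)
    if y.size != a.size:
        raise ValueError("years and AMW values length mismatch")
    if y.size == 0:
        raise ValueError("empty input")
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("years must be integer-valued")
    y = y.astype(int)

    recs = []
    for year in np.unique(y):
        vals = a[y == year]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        recs.append(
            {
                "year": int(year),
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(iqr),
                "lower_fence": float(lo_fence),
                "upper_fence": float(hi_fence),
                "n_outliers": int(((vals < lo_fence) | (vals > hi_fence)).sum()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return TrendReport(
        per_year=pd.DataFrame(recs),
        fraction_ge_threshold=float((a >= threshold).mean()),
        threshold=threshold,
    )
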