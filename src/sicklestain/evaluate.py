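"""Diagnostic-performance statistics for screening-test validation.

Implements the evaluation stack used to validate the paper-based sickle cell
test: K-class confusion matrices, binary screening metrics (sensitivity,
specificity, PPV, NPV, accuracy) with Wilson score intervals, ROC curves
with trapezoidal AUC, Fleiss' kappa for multi-rater agreement, and
per-rater summary tables.

Two details are specific to reproducing published screening-study numbers:

* ``sensitivity = TP / (TP + FN)`` and ``NPV = TN / (TN + FN)`` — the
  standard forms (a published formula line with TP/(TP+TN) is a known typo;
  every printed result requires the standard denominators).
* Wilson intervals support two effective-n conventions: ``standard`` uses
  each metric's own denominator; ``total_n`` uses the total number of
  samples in the comparison for every metric.  Validation reports in this
  assay family print intervals only reproducible under ``total_n``, so both
  are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats import inter_rater

from .errors import DomainError

CIConvention = Literal["standard", "total_n"]

#: The three comparisons reported for a three-genotype screening study:
#: any-HbS detection, disease detection, and disease vs trait.
DEFAULT_COMPARISONS: tuple[tuple[str, frozenset[str], frozenset[str] | None], ...] = (
    ("AA vs (AS and SS)", frozenset({"AS", "SS"}), None),
    ("SS vs (AA and AS)", frozenset({"SS"}), None),
    ("AS vs SS", frozenset({"SS"}), frozenset({"AS", "SS"})),
)


# ---------------------------------------------------------------------------
# Confusion matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """K-class counts; rows are true classes, columns predicted classes."""

    labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if c.shape != (k, k):
            raise DomainError("counts must be a KxK matrix matching labels")
        if (c < 0).any():
            raise DomainError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise DomainError("cannot aggregate matrices with different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)

    def restrict(self, keep: Iterable[str]) -> "ConfusionMatrix":
        """Sub-matrix over a label subset (both true and predicted)."""
        keep_t = tuple(l for l in self.labels if l in set(keep))
        idx = [self.labels.index(l) for l in keep_t]
        return ConfusionMatrix(keep_t, self.counts[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(
    truth: Sequence[str], predicted: Sequence[str], labels: Sequence[str]
) -> ConfusionMatrix:
    """Tally a confusion matrix; aggregation over raters is elementwise sum."""
    if len(truth) != len(predicted):
        raise DomainError("truth and predicted must have equal length")
    labels_t = tuple(str(l) for l in labels)
    index = {l: i for i, l in enumerate(labels_t)}
    counts = np.zeros((len(labels_t), len(labels_t)), dtype=np.int64)
    for t, p in zip(truth, predicted):
        t, p = str(t), str(p)
        if t not in index or p not in index:
            raise DomainError(f"label outside declared set: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(labels_t, counts)


@dataclass(frozen=True)
class BinaryCounts:
    """TP/FP/TN/FN counts of one binary comparison."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize(
    cm: ConfusionMatrix,
    positive_classes: Iterable[str],
    restrict_to: Iterable[str] | None = None,
) -> BinaryCounts:
    """Collapse a K-class matrix to binary counts for one comparison.

    ``restrict_to`` first drops all other true/predicted classes (used for
    the AS-vs-SS comparison, which ignores AA entirely).
    """
    if restrict_to is not None:
        cm = cm.restrict(restrict_to)
    pos = set(positive_classes)
    if not pos or not pos < set(cm.labels):
        raise DomainError("positive classes must be a nonempty proper subset of labels")
    is_pos = np.array([l in pos for l in cm.labels])
    c = cm.counts
    tp = int(c[np.ix_(is_pos, is_pos)].sum())
    fn = int(c[np.ix_(is_pos, ~is_pos)].sum())
    fp = int(c[np.ix_(~is_pos, is_pos)].sum())
    tn = int(c[np.ix_(~is_pos, ~is_pos)].sum())
    return BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn)


# ---------------------------------------------------------------------------
# Wilson score intervals and screening metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilsonInterval:
    """Wilson score interval for a binomial proportion.

    ``n_eff`` is the effective sample size used (which under the ``total_n``
    convention may differ from the metric's own denominator).
    """

    p_hat: float
    n_eff: float
    z: float
    lower: float
    upper: float
    convention: CIConvention = "standard"


def wilson_interval(p_hat: float, n_eff: float, z: float = 1.96) -> WilsonInterval:
    """Closed-form Wilson score interval, clamped to [0, 1].

    ``z`` defaults to 1.96 (the conventional two-sided 95% critical value as
    printed, not the full-precision quantile).
    """
    if not 0.0 <= p_hat <= 1.0:
        raise DomainError("p_hat must be in [0, 1]")
    if n_eff < 1:
        raise DomainError("n_eff must be at least 1")
    z2 = z * z
    denom = 1.0 + z2 / n_eff
    center = (p_hat + z2 / (2.0 * n_eff)) / denom
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n_eff + z2 / (4.0 * n_eff**2)) / denom
    lower = float(np.clip(center - half, 0.0, 1.0))
    upper = float(np.clip(center + half, 0.0, 1.0))
    return WilsonInterval(p_hat=p_hat, n_eff=n_eff, z=z, lower=lower, upper=upper)


@dataclass(frozen=True)
class MetricValue:
    """One screening metric: a proportion with its Wilson interval.

    ``value`` is NaN and ``ci`` is None when the metric's denominator is
    zero (flagged undefined rather than silently reported as 0).
    """

    name: str
    value: float
    ci: WilsonInterval | None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


@dataclass(frozen=True)
class BinaryMetrics:
    """The five screening metrics for one binary comparison."""

    counts: BinaryCounts
    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue

    def as_dict(self) -> dict[str, MetricValue]:
        return {
            m.name: m
            for m in (self.sensitivity, self.specificity, self.ppv, self.npv, self.accuracy)
        }


def binary_metrics(
    bc: BinaryCounts,
    ci_convention: CIConvention = "standard",
    cohort_n: int | None = None,
    z: float = 1.96,
) -> BinaryMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with Wilson CIs.

    Under ``ci_convention="total_n"`` the interval of every metric uses
    ``cohort_n`` (total samples in the comparison; defaults to the counts'
    total) as effective n; under ``standard`` each metric uses its own
    denominator.
    """
    if bc.total <= 0:
        raise DomainError("metric computation needs at least one sample")
    if ci_convention == "total_n":
        n_total = cohort_n if cohort_n is not None else bc.total

    def metric(name: str, num: int, den: int) -> MetricValue:
        if den == 0:
            return MetricValue(name=name, value=float("nan"), ci=None)
        p = num / den
        n_eff = n_total if ci_convention == "total_n" else den
        ci = wilson_interval(p, n_eff, z=z)
        ci = WilsonInterval(
            p_hat=ci.p_hat, n_eff=ci.n_eff, z=ci.z,
            lower=ci.lower, upper=ci.upper, convention=ci_convention,
        )
        return MetricValue(name=name, value=p, ci=ci)

    return BinaryMetrics(
        counts=bc,
        sensitivity=metric("sensitivity", bc.tp, bc.tp + bc.fn),
        specificity=metric("specificity", bc.tn, bc.fp + bc.tn),
        ppv=metric("ppv", bc.tp, bc.tp + bc.fp),
        npv=metric("npv", bc.tn, bc.tn + bc.fn),
        accuracy=metric("accuracy", bc.tp + bc.tn, bc.total),
    )


def format_percent(x: float, decimals: int = 1) -> str:
    """Format a proportion as a percent string with half-up rounding."""
    q = Decimal(10) ** -decimals
    return str(Decimal(x * 100).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROCCurve:
    """ROC points (threshold sweep, higher score = positive) and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[bool | int]) -> ROCCurve:
    """ROC curve and AUC for a score where higher means more disease.

    Every distinct score value is swept as a threshold (positive call =
    score strictly above threshold); AUC is the trapezoidal area, which for
    this construction equals the Mann-Whitney statistic with ties counted
    one half.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if s.size != y.size or s.size == 0:
        raise DomainError("scores and labels must be equal-length and non-empty")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC needs both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[np.diff(s_sorted) != 0, True]  # last index in each tie group
    tp_cum = np.cumsum(y_sorted)[distinct]
    fp_cum = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# Inter-rater agreement
# ---------------------------------------------------------------------------


def fleiss_kappa(ratings: Sequence[Sequence[object]]) -> float:
    """Fleiss' kappa for a subjects x raters table of categorical calls.

    Every subject must be rated by the same number (>= 2) of raters and no
    cell may be missing; ragged or incomplete tables raise
    :class:`DomainError` (no generalized weighting is attempted).
    """
    rows = [list(r) for r in ratings]
    if not rows:
        raise DomainError("ratings table is empty")
    n_raters = len(rows[0])
    if n_raters < 2:
        raise DomainError("Fleiss' kappa needs at least two raters")
    for r in rows:
        if len(r) != n_raters:
            raise DomainError("every subject must be rated by the same number of raters")
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in r):
            raise DomainError("missing ratings are not supported")
    flat = pd.Series([v for r in rows for v in r])
    codes, _ = pd.factorize(flat)
    table = codes.reshape(len(rows), n_raters)
    n_cat = int(codes.max()) + 1
    counts = np.zeros((len(rows), n_cat), dtype=np.int64)
    for i in range(len(rows)):
        counts[i] = np.bincount(table[i], minlength=n_cat)
    return float(inter_rater.fleiss_kappa(counts, method="fleiss"))


def rater_summary(
    per_rater_calls: Sequence[tuple[Sequence[str], Sequence[str]]],
    comparisons: Sequence[tuple[str, frozenset[str], frozenset[str] | None]] = DEFAULT_COMPARISONS,
    labels: Sequence[str] = ("AA", "AS", "SS"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-rater screening metrics and their across-rater mean and SD.

    ``per_rater_calls`` holds one ``(truth, predicted)`` pair per rater; the
    truth vector must be identical across raters.  Returns ``(per_rater,
    summary)`` data frames: the first is tidy with columns (rater,
    comparison, metric, value); the second aggregates mean and SD (ddof=1)
    per (comparison, metric) cell.
    """
    if len(per_rater_calls) < 2:
        raise DomainError("rater summary needs at least two raters")
    truth0 = [str(t) for t in per_rater_calls[0][0]]
    records = []
    for rater_idx, (truth, predicted) in enumerate(per_rater_calls):
        if [str(t) for t in truth] != truth0:
            raise DomainError("truth vectors differ across raters")
        cm = confusion_matrix(truth, predicted, labels)
        for name, pos, restrict in comparisons:
            bm = binary_metrics(binarize(cm, pos, restrict))
            for metric in bm.as_dict().values():
                records.append(
                    {
                        "rater": rater_idx,
                        "comparison": name,
                        "metric": metric.name,
                        "value": metric.value,
                    }
                )
    per_rater = pd.DataFrame.from_records(records)
    summary = (
        per_rater.groupby(["comparison", "metric"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return per_rater, summary


__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "WilsonInterval",
    "MetricValue",
    "BinaryMetrics",
    "ROCCurve",
    "DEFAULT_COMPARISONS",
    "confusion_matrix",
    "binarize",
    "binary_metrics",
    "wilson_interval",
    "roc_auc",
    "fleiss_kappa",
    "rater_summary",
    "format_percent",
]
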