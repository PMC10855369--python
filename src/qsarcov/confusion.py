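"""Evaluation metrics for binary (mutagenic / non-mutagenic) predictions.

All metrics derive from the 2x2 confusion matrix of a model's calls on the
compounds it actually predicted.  Percent-scaled metrics (sensitivity,
specificity, accuracy, BA, PPV, NPV, F1) are reported in [0, 100]; the
Matthews correlation coefficient (MCC) is kept on its natural [-1, 1] scale.
Metrics whose denominator vanishes are flagged as undefined rather than
silently set to a number; the single conventional exception is MCC, which is
set to 0 (and flagged) when any marginal count is zero, and F1, which is 0
(and flagged) when precision and recall are both zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = ["ConfusionMatrix", "MetricSet", "compute_metrics", "allnegative_baseline"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true/false positive/negative calls."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise DomainError(f"confusion count {name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swap_labels(self) -> "ConfusionMatrix":
        """Relabel positive as negative and vice versa."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)

    def scale(self, k: int) -> "ConfusionMatrix":
        """Multiply every count by a positive integer (metrics are invariant)."""
        if k <= 0 or k != int(k):
            raise DomainError("scale factor must be a positive integer")
        return ConfusionMatrix(tp=self.tp * k, fp=self.fp * k, fn=self.fn * k, tn=self.tn * k)


@dataclass(frozen=True)
class MetricSet:
    """Metric values computed from one confusion matrix.

    Percent metrics are in [0, 100]; ``mcc`` is raw in [-1, 1].  ``undefined``
    lists the metrics whose defining ratio had a zero denominator.
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ba: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    mcc: float | None
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {
            k: getattr(self, k)
            for k in ("sensitivity", "specificity", "accuracy", "ba", "ppv", "npv", "f1", "mcc")
        }


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Compute the full metric set from a confusion matrix.

    F1 uses the harmonic mean of precision and recall; an algebraically
    identical expansion ``2*TP^2 / (2*TP^2 + TP*FP + TP*FN)`` is exercised by
    the test suite as a cross-check.  MCC is the signed phi coefficient; when
    any of its four marginal factors is zero it is set to 0 and flagged.
    """
    if cm.total == 0:
        raise DomainError("cannot compute metrics from an all-zero confusion matrix")
    tp, fp, fn, tn = (float(cm.tp), float(cm.fp), float(cm.fn), float(cm.tn))

    undefined: set[str] = set()
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, cm.total)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    for name, v in (("sensitivity", sens), ("specificity", spec), ("ppv", ppv), ("npv", npv)):
        if v is None:
            undefined.add(name)

    ba = None if sens is None or spec is None else (sens + spec) / 2.0
    if ba is None:
        undefined.add("ba")

    if sens is None or ppv is None:
        f1 = None
        undefined.add("f1")
    elif sens + ppv == 0:
        f1 = 0.0
        undefined.add("f1")
    else:
        f1 = 2.0 * ppv * sens / (ppv + sens)

    denom_factors = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_factors == 0:
        mcc = 0.0
        undefined.add("mcc")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom_factors)

    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ba=ba,
        ppv=ppv,
        npv=npv,
        f1=f1,
        mcc=mcc,
        undefined=frozenset(undefined),
    )


def allnegative_baseline(n_pos: int, n_neg: int) -> MetricSet:
    """Metrics of the constant predictor that calls every compound negative.

    On imbalanced data this trivial baseline attains a deceptively high raw
    accuracy (the negative-class prevalence) while BA is pinned at 50%,
    which is the motivation for imbalance-robust metrics.
    """
    if n_pos < 0 or n_neg < 0:
        raise DomainError("class counts must be non-negative")
    if n_pos + n_neg == 0:
        raise DomainError("at least one compound is required")
    return compute_metrics(ConfusionMatrix(tp=0, fp=0, fn=n_pos, tn=n_neg))


def f1_from_ppv_sensitivity(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of precision and recall, both in percent.

    Used to reconstruct F1 for benchmark rounds that reported PPV and
    sensitivity but not F1 itself.  The degenerate precision = recall = 0
    case is defined as 0 with a warning.
    """
    if not (0 <= ppv <= 100 and 0 <= sensitivity <= 100):
        raise DomainError("ppv and sensitivity must be percentages in [0, 100]")
    if ppv + sensitivity == 0:
        warnings.warn("F1 with precision = recall = 0 defined as 0 by convention", stacklevel=2)
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)
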