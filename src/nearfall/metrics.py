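"""Classification performance statistics and prevalence extrapolation.

Sensitivity, specificity, positive predictive value and F1 are computed
from trial-level confusion counts; the PPV can also be extrapolated to a
hypothetical prevalence via Bayes' theorem, which matters because the
practical value of a near-fall detector depends strongly on how rare
near-falls are in daily life.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .errors import InvalidInputError, UndefinedMetricError


@dataclass
class ConfusionCounts:
    """Trial-level confusion counts (all non-negative)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"count {name} must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def sensitivity(cc: ConfusionCounts) -> float:
    """True-positive rate tp / (tp + fn)."""
    if cc.positives == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive trials")
    return cc.tp / cc.positives


def specificity(cc: ConfusionCounts) -> float:
    """True-negative rate tn / (tn + fp)."""
    if cc.negatives == 0:
        raise UndefinedMetricError("specificity undefined: no negative trials")
    return cc.tn / cc.negatives


def ppv(cc: ConfusionCounts) -> float:
    """Positive predictive value tp / (tp + fp)."""
    if cc.tp + cc.fp == 0:
        raise UndefinedMetricError("PPV undefined: no positive predictions")
    return cc.tp / (cc.tp + cc.fp)


def ppv_from_prevalence(sens: float, spec: float, prevalence: float) -> float:
    """PPV via Bayes' theorem at an arbitrary prevalence.

    sens*prev / (sens*prev + (1-spec)*(1-prev)); lets a detector
    validated at one prevalence be judged at the (much lower) daily
    life near-fall rate.
    """
    for name, v in (("sensitivity", sens), ("specificity", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise InvalidInputError(f"{name} must lie in [0, 1], got {v}")
    denom = sens * prevalence + (1.0 - spec) * (1.0 - prevalence)
    if denom == 0.0:
        raise UndefinedMetricError("PPV undefined: zero detection probability")
    return sens * prevalence / denom


def f1(ppv_value: float, sens: float) -> float:
    """Harmonic mean of PPV and sensitivity."""
    if ppv_value + sens == 0:
        raise UndefinedMetricError("F1 undefined: PPV + sensitivity = 0")
    return 2.0 * ppv_value * sens / (ppv_value + sens)


@dataclass
class MetricsReport:
    """Full evaluation result of a prediction set against labels.

    Metrics whose denominator is empty (no positive trials, no negative
    trials, or no positive predictions) are reported as ``None``.
    """

    counts: ConfusionCounts
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    f1: Optional[float]
    prevalence: float
    extra_events: int = 0  # recovery calls beyond one in perturbed trials

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "f1": self.f1,
            "prevalence": self.prevalence,
            "extra_events": self.extra_events,
        }


def _as_positive_flags(predictions: Sequence) -> List[bool]:
    """A trial is positive when it holds at least one recovery call."""
    flags = []
    for p in predictions:
        if isinstance(p, (bool, np.bool_)):
            flags.append(bool(p))
        elif isinstance(p, (list, tuple)):
            flags.append(any(getattr(c, "is_recovery", bool(c)) for c in p))
        else:
            flags.append(bool(getattr(p, "is_recovery", p)))
    return flags


def _count_extra_events(predictions: Sequence, labels: Sequence[bool]) -> int:
    extra = 0
    for p, lab in zip(predictions, labels):
        if isinstance(p, (list, tuple)):
            n_rec = sum(1 for c in p if getattr(c, "is_recovery", False))
            if lab and n_rec > 1:
                extra += n_rec - 1
    return extra


def evaluate(predictions: Sequence, labels: Sequence[bool]) -> MetricsReport:
    """Trial-level evaluation of per-trial predictions against labels.

    ``predictions`` may be booleans or per-trial lists of calls (a trial
    counts positive if any call is a recovery; surplus recovery calls in
    perturbed trials are tallied separately, not double-counted).
    """
    labels = [bool(x) for x in labels]
    if len(predictions) != len(labels):
        raise InvalidInputError(
            f"{len(predictions)} predictions vs {len(labels)} labels"
        )
    flags = _as_positive_flags(predictions)
    tp = sum(1 for f, l in zip(flags, labels) if f and l)
    fp = sum(1 for f, l in zip(flags, labels) if f and not l)
    tn = sum(1 for f, l in zip(flags, labels) if not f and not l)
    fn = sum(1 for f, l in zip(flags, labels) if not f and l)
    cc = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens = sensitivity(cc) if cc.positives else None
    spec = specificity(cc) if cc.negatives else None
    the_ppv = ppv(cc) if (tp + fp) else None
    return MetricsReport(
        counts=cc,
        sensitivity=sens,
        specificity=spec,
        ppv=the_ppv,
        f1=f1(the_ppv, sens) if (the_ppv is not None and sens) else None,
        prevalence=cc.positives / cc.total,
        extra_events=_count_extra_events(predictions, labels),
    )


def prevalence_sweep(
    sens: float, spec: float, prevalences: Sequence[float]
) -> List[dict]:
    """PPV extrapolation over a prevalence grid."""
    return [
        {"prevalence": float(p), "ppv": ppv_from_prevalence(sens, spec, float(p))}
        for p in prevalences
    ]
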