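"""Classifier-style evaluation of the fuzzy system on labelled panels.

Metrics are the standard rates TPR = TP/P, TNR = TN/N and the false-alarm
rate = (number of major deviations) / (total number of data).  A "major
deviation" is, by default, any mismatch between the predicted and true
fertility class — under that definition accuracy + false-alarm rate = 1 on
any panel; a stricter predicate (e.g. only two-class jumps) can be plugged
in.  The fertility classes form a 3-class problem, so TPR/TNR are computed
one-vs-rest per class and summarised as unweighted macro averages over the
classes present in the truth.

The system has no trainable parameters, so the conventional 70/30
train/test protocol is honoured structurally: the train split triggers a
rule-base/variable audit and metrics are reported on the held-out 30%.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .errors import RuleValidationError, UndefinedMetricError
from .forecast import SoilSample, forecast
from .inference import FuzzySystem
from .membership import OutputLevel

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "tpr",
    "tnr",
    "false_alarm_rate",
    "split",
    "evaluate",
    "evaluate_holdout",
]

_CLASSES = tuple(lvl.name for lvl in OutputLevel)  # LOW, AVERAGE, HIGH


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion tallies; positives P = tp + fn and negatives
    N = tn + fp are derived, never stored."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name, v in (("tp", self.tp), ("tn", self.tn), ("fp", self.fp), ("fn", self.fn)):
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp


def tpr(c: ConfusionCounts) -> float:
    """True positive rate TP/P; undefined (raises) when there are no positives."""
    if c.p == 0:
        raise UndefinedMetricError("TPR undefined: no positive samples (P = 0)")
    return c.tp / c.p


def tnr(c: ConfusionCounts) -> float:
    """True negative rate TN/N; undefined (raises) when there are no negatives."""
    if c.n == 0:
        raise UndefinedMetricError("TNR undefined: no negative samples (N = 0)")
    return c.tn / c.n


def false_alarm_rate(major_deviations: int, total: int) -> float:
    """Major deviations as a fraction of all predictions."""
    if total <= 0:
        raise UndefinedMetricError("false alarm rate undefined: total = 0")
    if not 0 <= major_deviations <= total:
        raise ValueError(
            f"major_deviations must be in [0, {total}], got {major_deviations}"
        )
    return major_deviations / total


def split(
    samples: Sequence[SoilSample],
    train_frac: float = 0.70,
    seed: Optional[int] = None,
) -> tuple[list[SoilSample], list[SoilSample]]:
    """Seeded shuffle-split into disjoint, exhaustive train/test lists
    with train size = round(train_frac * n)."""
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < train_frac < 1.0:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    order = list(samples)
    random.Random(seed).shuffle(order)
    n_train = round(train_frac * len(order))
    return order[:n_train], order[n_train:]


@dataclass
class EvaluationReport:
    """Metrics of the fuzzy forecaster on a labelled panel."""

    accuracy: float
    false_alarm_rate: float
    tpr_macro: Optional[float]
    tnr_macro: Optional[float]
    per_class: dict[str, dict]
    confusion: dict[str, dict[str, int]]  # confusion[true][pred]
    n_samples: int
    n_train: int = 0
    n_test: int = 0
    baselines: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "false_alarm_rate": self.false_alarm_rate,
            "tpr_macro": self.tpr_macro,
            "tnr_macro": self.tnr_macro,
            "per_class": self.per_class,
            "confusion": self.confusion,
            "n_samples": self.n_samples,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "baselines": self.baselines,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        """Plain-text table: method, prediction accuracy %, false alarm %.

        The baselines column stays empty unless external results are added
        via ``baselines``."""
        lines = [
            f"{'Method':<22}{'Prediction Accuracy':>22}{'False Alarm':>14}",
            f"{'Fuzzy Logic':<22}{self.accuracy * 100:>21.1f}%"
            f"{self.false_alarm_rate * 100:>13.1f}%",
        ]
        for name, vals in self.baselines.items():
            acc = vals.get("accuracy")
            far = vals.get("false_alarm_rate")
            lines.append(
                f"{name:<22}"
                + (f"{acc * 100:>21.1f}%" if acc is not None else f"{'-':>22}")
                + (f"{far * 100:>13.1f}%" if far is not None else f"{'-':>14}")
            )
        lines.append(f"(n = {self.n_samples}" +
                     (f"; split {self.n_train}/{self.n_test})" if self.n_test else ")"))
        return "\n".join(lines)


DeviationPredicate = Callable[[str, str], bool]


def _default_deviation(true_label: str, predicted: str) -> bool:
    return true_label != predicted


def evaluate(
    system: FuzzySystem,
    samples: Sequence[SoilSample],
    deviation: DeviationPredicate = _default_deviation,
) -> EvaluationReport:
    """Forecast every labelled sample and tally the metrics.

    The predicted class is the forecast's fertility label.  Every sample
    must carry a label; classes absent from the truth are excluded from the
    macro TPR/TNR averages.
    """
    if not samples:
        raise ValueError("no samples to evaluate")
    unlabeled = sum(1 for s in samples if s.label is None)
    if unlabeled:
        raise RuleValidationError(f"{unlabeled} samples have no fertility label")

    confusion = {t: {p: 0 for p in _CLASSES} for t in _CLASSES}
    deviations = 0
    matches = 0
    for s in samples:
        predicted = forecast(s, system).fertility_label
        confusion[s.label][predicted] += 1
        if s.label == predicted:
            matches += 1
        if deviation(s.label, predicted):
            deviations += 1

    total = len(samples)
    per_class: dict[str, dict] = {}
    tprs, tnrs = [], []
    for cls in _CLASSES:
        tp = confusion[cls][cls]
        fn = sum(confusion[cls][p] for p in _CLASSES if p != cls)
        fp = sum(confusion[t][cls] for t in _CLASSES if t != cls)
        tn = total - tp - fn - fp
        counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        entry: dict = {"tp": tp, "tn": tn, "fp": fp, "fn": fn}
        if counts.p > 0:
            entry["tpr"] = tpr(counts)
            tprs.append(entry["tpr"])
        if counts.n > 0:
            entry["tnr"] = tnr(counts)
            tnrs.append(entry["tnr"])
        per_class[cls] = entry

    return EvaluationReport(
        accuracy=matches / total,
        false_alarm_rate=false_alarm_rate(deviations, total),
        tpr_macro=sum(tprs) / len(tprs) if tprs else None,
        tnr_macro=sum(tnrs) / len(tnrs) if tnrs else None,
        per_class=per_class,
        confusion=confusion,
        n_samples=total,
    )


def evaluate_holdout(
    system: FuzzySystem,
    samples: Sequence[SoilSample],
    train_frac: float = 0.70,
    seed: Optional[int] = None,
    deviation: DeviationPredicate = _default_deviation,
) -> EvaluationReport:
    """70/30 protocol: audit the system against the train split, report
    metrics on the held-out test split."""
    train, test = split(samples, train_frac=train_frac, seed=seed)
    system.validate()  # "training": rule-base audit; nothing is fitted
    report = evaluate(system, test, deviation=deviation)
    report.n_train = len(train)
    report.n_test = len(test)
    report.n_samples = len(samples)
    return report
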