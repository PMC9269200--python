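"""Confusion matrices and screening performance metrics.

Glaucoma is the positive class throughout: a true positive is a glaucoma
patient predicted as glaucoma.  From the four counts the standard
screening quantities follow:

    accuracy     ACC = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  TPR = TP / (TP + FN)
    specificity  TNR = TN / (TN + FP)
    precision    PPV = TP / (TP + FP)

``reconstruct_confusion`` inverts published sensitivity/specificity rates
back to integer counts given the group sizes, which lets printed rate
tables be checked for internal consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .data_model import GLAUCOMA, HEALTHY


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_glaucoma(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_glaucoma + self.n_healthy


@dataclass(frozen=True)
class ScreeningMetrics:
    """The four screening ratios; ``None`` marks an undefined ratio."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionCounts:
    """Count screening outcomes with glaucoma as the positive class."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    tp = fp = tn = fn = 0
    for t, p in zip(true_labels, predicted_labels):
        if t not in (HEALTHY, GLAUCOMA) or p not in (HEALTHY, GLAUCOMA):
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == GLAUCOMA:
            if p == GLAUCOMA:
                tp += 1
            else:
                fn += 1
        else:
            if p == GLAUCOMA:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionCounts) -> ScreeningMetrics:
    """Accuracy, sensitivity, specificity and precision of a matrix.

    Values are exact ratios; rounding happens only at presentation time
    (4 decimals in reports).  A zero denominator (e.g. precision with no
    positive predictions) yields ``None``.
    """
    return ScreeningMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.n),
        sensitivity=_ratio(cm.tp, cm.n_glaucoma),
        specificity=_ratio(cm.tn, cm.n_healthy),
        precision=_ratio(cm.tp, cm.tp + cm.fp),
    )


def reconstruct_confusion(
    tpr: float, tnr: float, n_glaucoma: int, n_healthy: int
) -> ConfusionCounts:
    """Integer confusion matrix implied by published rates and group sizes.

    ``TP = round(tpr * n_glaucoma)`` and ``TN = round(tnr * n_healthy)``
    (half away from zero, matching how rates rounded for print are
    inverted); FN and FP follow by complement.
    """
    if not (0.0 <= tpr <= 1.0 and 0.0 <= tnr <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    if n_glaucoma <= 0 or n_healthy <= 0:
        raise ValueError("group sizes must be positive")
    tp = int(round_half_up(tpr * n_glaucoma, 0))
    tn = int(round_half_up(tnr * n_healthy, 0))
    if not (0 <= tp <= n_glaucoma and 0 <= tn <= n_healthy):
        raise ValueError("reconstructed counts fall outside the group sizes")
    return ConfusionCounts(tp=tp, fp=n_healthy - tn, tn=tn, fn=n_glaucoma - tp)


def round_half_up(value: float, ndigits: int = 4) -> float:
    """Round half away from zero (report convention), not banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def report_row(model_id: str, xi: int, w_g: float, cm: ConfusionCounts) -> dict:
    """One evaluation-report record: counts plus 4-decimal rates."""
    m = metrics(cm)
    fmt = lambda v: None if v is None else round_half_up(v, 4)
    return {
        "model": model_id,
        "xi": xi,
        "w_g": w_g,
        "TP": cm.tp,
        "FP": cm.fp,
        "TN": cm.tn,
        "FN": cm.fn,
        "ACC": fmt(m.accuracy),
        "TPR": fmt(m.sensitivity),
        "TNR": fmt(m.specificity),
        "PPV": fmt(m.precision),
    }
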