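"""Predicted test–retest correlation and the accuracy metrics built on it.

A reliability coefficient is useful insofar as it forecasts how well a task
correlates with its own replication.  Given single-session reliabilities
``r1`` and ``r2`` of two measurements, the attenuation-style prediction

    r_predicted = sqrt(|r1| * |r2|) * min(sgn r1, sgn r2)

is defined only when the two reliabilities agree in sign; mixed signs leave
the sign of the product indeterminate and the prediction undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PredictionRecord",
    "predicted_retest",
    "prediction_ci",
    "accuracy_metrics",
    "ci_coverage",
]


def predicted_retest(r1: float, r2: float) -> float:
    """Predicted test–retest correlation from two session reliabilities.

    Returns NaN (undefined) when ``r1`` and ``r2`` have strictly opposite
    signs.  A zero reliability is sign-compatible with either sign and
    yields a prediction of zero.  Reliabilities normally lie in [-1, 1],
    but the formula is applied as-is to out-of-range inputs because some
    estimators (e.g. the Lord-combined alpha of a difference score) can
    produce them, and their deviated predictions are part of what the
    accuracy analyses measure.
    """
    if r1 * r2 < 0:
        return float("nan")
    sign = -1.0 if (r1 < 0 or r2 < 0) else 1.0
    return sign * math.sqrt(abs(r1) * abs(r2))


def prediction_ci(
    ci1: tuple[float, float] | None, ci2: tuple[float, float] | None
) -> tuple[float, float] | None:
    """Endpoint-wise mean of the two sessions' reliability CIs."""
    if ci1 is None or ci2 is None:
        return None
    return ((ci1[0] + ci2[0]) / 2.0, (ci1[1] + ci2[1]) / 2.0)


@dataclass(frozen=True)
class PredictionRecord:
    """One dataset's predicted vs. observed test–retest correlation."""

    r1: float
    r2: float
    r_observed: float
    ci: tuple[float, float] | None = None

    @property
    def r_predicted(self) -> float:
        return predicted_retest(self.r1, self.r2)


def accuracy_metrics(records: list[PredictionRecord]) -> dict[str, float]:
    """Mean deviation and RMSE of defined predictions against observations.

    Undefined predictions (mixed-sign reliabilities) are excluded and
    counted under ``n_undefined``; a negative mean deviation means the
    method systematically underestimates the test–retest correlation.
    """
    errors = []
    n_undef = 0
    for rec in records:
        pred = rec.r_predicted
        if math.isnan(pred):
            n_undef += 1
        else:
            errors.append(pred - rec.r_observed)
    if not errors:
        raise ValueError("no defined predictions")
    err = np.asarray(errors)
    return {
        "mean_deviation": float(err.mean()),
        "rmse": float(np.sqrt(np.mean(err**2))),
        "mean_absolute_error": float(np.abs(err).mean()),
        "n_defined": len(errors),
        "n_undefined": n_undef,
    }


def ci_coverage(records: list[PredictionRecord]) -> float:
    """Fraction of observations falling strictly outside the prediction CI.

    Endpoints count as inside (inclusive convention).  Records without a CI
    are ignored.
    """
    outside = total = 0
    for rec in records:
        if rec.ci is None:
            continue
        total += 1
        lo, hi = rec.ci
        if rec.r_observed < lo or rec.r_observed > hi:
            outside += 1
    if total == 0:
        raise ValueError("no records with confidence intervals")
    return outside / total
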