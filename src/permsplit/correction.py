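"""Spearman–Brown test-length correction and its negative-value policies.

A split-half correlation is computed from scores based on half the trials, so
it underestimates the reliability of the full-length task.  The
Spearman–Brown prophecy formula projects the correlation ``r11`` between two
half-tests to the reliability ``r_kk`` of a test ``k`` times as long:

    r_kk = k * r11 / (1 + (k - 1) * r11)

Applied to a negative correlation the standard formula produces extreme and
even impossible values (below -1).  The *mirrored* variant applies the same
magnitude of change to negative correlations as to positive ones:

    r_kk = k * r11 / (1 + (k - 1) * |r11|)

*Nullification* instead replaces negative correlations with zero before
correcting.  When many split correlations are aggregated, the correction can
be applied either to every raw correlation (``per_split``) or to their
aggregate (``after_aggregation``).  The recommended preset is the mirrored
formula applied after aggregation, with no nullification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .aggregation import CorrelationSample, op5_mean

__all__ = ["SBPolicy", "spearman_brown", "apply_policy", "RECOMMENDED_POLICY"]

Formula = Literal["standard", "mirrored"]


@dataclass(frozen=True)
class SBPolicy:
    """How the Spearman–Brown step treats a sample of split correlations.

    Parameters
    ----------
    formula:
        ``"standard"`` or ``"mirrored"``.
    negatives:
        ``"none"`` keeps negative correlations as they are; ``"nullify"``
        replaces them with zero before the correction.
    order:
        ``"after_aggregation"`` aggregates the raw correlations first and
        corrects the aggregate; ``"per_split"`` corrects every correlation
        and aggregates the corrected values.
    k:
        Test-length factor; 2 for split halves.
    """

    formula: Formula = "mirrored"
    negatives: Literal["none", "nullify"] = "none"
    order: Literal["after_aggregation", "per_split"] = "after_aggregation"
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("length factor k must be positive")
        if self.formula not in ("standard", "mirrored"):
            raise ValueError(f"unknown formula {self.formula!r}")
        if self.negatives not in ("none", "nullify"):
            raise ValueError(f"unknown negatives policy {self.negatives!r}")
        if self.order not in ("after_aggregation", "per_split"):
            raise ValueError(f"unknown order {self.order!r}")

    def correct(self, r):
        """Apply nullification (if any) and the Spearman–Brown formula."""
        r = np.asarray(r, dtype=float)
        if self.negatives == "nullify":
            r = np.where(r < 0, 0.0, r)
        out = spearman_brown(r, self.k, self.formula)
        return float(out) if out.ndim == 0 else out


RECOMMENDED_POLICY = SBPolicy()


def spearman_brown(r, k: float = 2.0, formula: Formula = "standard"):
    """Spearman–Brown projection of a part-test correlation to length ``k``.

    The standard formula is unbounded at ``r = -1/(k-1)``; there it returns
    signed infinity rather than raising.
    """
    if k <= 0:
        raise ValueError("length factor k must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r[np.isfinite(r)]) > 1 + 1e-12):
        raise ValueError("correlation must lie in [-1, 1]")
    if formula == "mirrored":
        denom = 1.0 + (k - 1.0) * np.abs(r)
        return k * r / denom
    if formula == "standard":
        denom = 1.0 + (k - 1.0) * r
        with np.errstate(divide="ignore"):
            return np.where(denom == 0.0, np.inf * np.sign(r), k * r / denom)
    raise ValueError(f"unknown formula {formula!r}")


def apply_policy(
    sample: CorrelationSample,
    policy: SBPolicy = RECOMMENDED_POLICY,
    aggregator: Callable[[CorrelationSample], float] = op5_mean,
) -> float:
    """Aggregate a sample of split correlations into one full-length
    reliability under ``policy``.

    With ``order="after_aggregation"`` the raw correlations are aggregated
    first and the (possibly nullified) aggregate is corrected.  With
    ``order="per_split"`` every correlation is corrected first and the
    corrected values are aggregated.  Corrected values are correlations on
    the full-test scale and stay in ``[-1, 1]`` for every policy except the
    standard formula without nullification, whose extreme outputs can only
    be averaged arithmetically.
    """
    if policy.order == "after_aggregation":
        return float(policy.correct(aggregator(sample)))
    corrected = np.asarray(policy.correct(sample.correlations), dtype=float)
    finite = corrected[np.isfinite(corrected)]
    if finite.size and np.all(np.abs(finite) <= 1.0):
        return float(aggregator(CorrelationSample(corrected, sample.n_pairs)))
    if finite.size == 0:
        raise ValueError("no defined corrected correlations to aggregate")
    return float(finite.mean())
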