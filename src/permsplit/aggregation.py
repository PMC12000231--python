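"""Averaging many split-half Pearson correlations.

The arithmetic mean of Pearson correlations is biased towards zero, and the
Fisher-z mean is biased away from it.  The five-term Olkin–Pratt estimator
(OP5) corrects the small-sample bias of each correlation before averaging and
is the default aggregation method for permutation-based split-half
reliability in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "CorrelationSample",
    "pearson",
    "simple_mean",
    "fisher_z_mean",
    "op5_mean",
]


@dataclass(frozen=True)
class CorrelationSample:
    """A set of Pearson correlations that were each computed from ``n_pairs``
    paired observations.

    Parameters
    ----------
    correlations:
        Correlation coefficients, each in ``[-1, 1]``.
    n_pairs:
        Number of participant pairs entering each correlation (the ``N`` of
        the Olkin–Pratt correction).  Must be at least 4.
    """

    correlations: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        r = np.asarray(self.correlations, dtype=float)
        object.__setattr__(self, "correlations", r)
        if r.ndim != 1 or r.size == 0:
            raise ValueError("correlations must be a nonempty 1-d array")
        if np.any(np.abs(r) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_pairs < 4:
            raise ValueError("n_pairs must be >= 4")

    def __len__(self) -> int:
        return int(self.correlations.size)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two score vectors.

    Entries where either vector is NaN (undefined scores) are excluded
    pairwise.  Returns NaN (the undefined-correlation signal) when fewer than
    4 jointly defined pairs remain or when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _finite(sample: CorrelationSample) -> np.ndarray:
    r = sample.correlations
    return r[np.isfinite(r)]


def simple_mean(sample: CorrelationSample) -> float:
    """Arithmetic mean of the correlations (biased towards zero)."""
    r = _finite(sample)
    if r.size == 0:
        raise ValueError("no defined correlations to aggregate")
    return float(r.mean())


def fisher_z_mean(sample: CorrelationSample) -> float:
    """tanh of the mean of atanh(r): biased away from zero."""
    r = _finite(sample)
    if r.size == 0:
        raise ValueError("no defined correlations to aggregate")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z is infinite at |r| = 1")
    return float(np.tanh(np.arctanh(r).mean()))


def op5_weights(n_pairs: int) -> np.ndarray:
    """Coefficients of the five-term Olkin–Pratt correction for sample size
    ``n_pairs``.

    Term ``k`` (k = 1..5) of the bracket is ``w_k * (1 - r^2)^k`` with

        w_k = Gamma(1/2 + k)^2 * Gamma((N-2)/2)
              / (Gamma(1/2)^2 * Gamma((N-2)/2 + k) * k!)

    evaluated in log space so large ``N`` cannot overflow.
    """
    if n_pairs < 5:
        raise ValueError("Olkin-Pratt correction requires n_pairs >= 5")
    k = np.arange(1, 6, dtype=float)
    half_n = (n_pairs - 2) / 2.0
    logw = (
        2.0 * gammaln(0.5 + k)
        + gammaln(half_n)
        - 2.0 * gammaln(0.5)
        - gammaln(half_n + k)
        - gammaln(k + 1.0)
    )
    return np.exp(logw)


def op5_mean(sample: CorrelationSample) -> float:
    """Olkin–Pratt (OP5) approximately unbiased mean of Pearson correlations.

    Each correlation ``r_i`` is multiplied by the five-term gamma-ratio
    bracket before averaging; the result is clamped to ``[-1, 1]`` because
    the truncated series can marginally overshoot for extreme ``r`` at very
    small ``N``.
    """
    r = _finite(sample)
    if r.size == 0:
        raise ValueError("no defined correlations to aggregate")
    w = op5_weights(sample.n_pairs)
    one_minus_r2 = np.clip(1.0 - r * r, 0.0, 1.0)
    powers = one_minus_r2[:, None] ** np.arange(1, 6)[None, :]
    bracket = 1.0 + powers @ w
    return float(np.clip(np.mean(r * bracket), -1.0, 1.0))


def op5_transform(r: np.ndarray, n_pairs: int) -> np.ndarray:
    """Vectorised per-correlation Olkin–Pratt correction (no averaging)."""
    r = np.asarray(r, dtype=float)
    w = op5_weights(n_pairs)
    one_minus_r2 = np.clip(1.0 - r * r, 0.0, 1.0)
    powers = one_minus_r2[..., None] ** np.arange(1, 6)
    return np.clip(r * (1.0 + powers @ w), -1.0, 1.0)
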