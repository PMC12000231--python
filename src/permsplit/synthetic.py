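"""Synthetic trial-level datasets with known reliability structure.

The generator emulates the trial structure of an approach-avoidance task
(AAT): participants respond to stimuli nested in one or two stimulus
categories (target/control), optionally in two response directions
(avoid/approach), with several repetitions per stimulus per direction.

Hierarchical Gaussian model.  For participant ``i`` and category ``c``:

- a true category bias  ``b_ic ~ N(0, v * alpha)``, with correlation
  ``intercategory_rho`` between the two categories' biases;
- per stimulus ``t`` a stable stimulus-specific deviation
  ``d_ict ~ N(0, p * v * (1 - alpha))`` for ``p`` stimuli per category;
- every trial adds i.i.d. noise ``eps ~ N(0, trial_sd^2)``.

With response directions, a trial's RT is
``baseline + (+1/2 if avoid else -1/2) * (b_ic + d_ict) + eps``, so the
avoid-approach contrast recovers ``b + d`` and a positive bias means the
stimulus was approached faster than avoided.  Without directions the bias
enters additively: ``baseline + b_ic + d_ict + eps``.

This split of the variance has two properties that define the study
conditions.  First, the latent per-stimulus bias scores ``b + d_t`` of a
category have Cronbach's alpha exactly ``alpha_target``
(``alpha = p sigma_b^2 / (p sigma_b^2 + sigma_d^2)``), before trial noise,
which keeps ``alpha_target = 1`` attainable with nonzero trial noise.
Second, the participant's latent category bias score ``b + mean_t d_t`` has
variance ``v * alpha + p * v * (1 - alpha) / p = v`` for *every* alpha: the
preset alpha redistributes a fixed amount of true bias variance between the
common and the stimulus-specific component, so (at zero intercategory
correlation) it moves the internal consistency of the subscores without
touching the reliability of the aggregate score.

Trial order is randomised per participant so that deterministic splitting
schemes (odd-even, first-second) behave as they would in a real session.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_model import PARTICIPANT, PRESENTATION, RT, STIMULUS, TrialTable
from .scoring import ScoreSpec

__all__ = ["SimParams", "generate_dataset", "generate_pair", "true_reliability", "calibrate_trial_sd"]

CATEGORY_FACTOR = "stimulus_type"
DIRECTION_FACTOR = "direction"
CATEGORY_LEVELS = ("target", "control")
DIRECTION_LEVELS = ("avoid", "approach")


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one synthetic dataset.

    Defaults give the double-difference design: 40 participants, two
    stimulus categories of eight stimuli, eight approach and eight avoid
    trials per stimulus -- 256 trials per participant.
    """

    n_participants: int = 40
    n_categories: int = 2
    n_stimuli: int = 8  # per category
    n_reps: int = 8  # per stimulus per direction (or per stimulus if no directions)
    has_directions: bool = True
    alpha_target: float = 0.8
    bias_variance: float = 4.0
    trial_sd: float = 6.0
    intercategory_rho: float = 0.0
    baseline: float = 700.0

    def __post_init__(self) -> None:
        if self.n_categories not in (1, 2):
            raise ValueError("n_categories must be 1 or 2")
        if not 0.0 <= self.alpha_target <= 1.0:
            raise ValueError("alpha_target must lie in [0, 1]")
        if self.bias_variance < 0 or self.trial_sd < 0:
            raise ValueError("variances must be nonnegative")
        if abs(self.intercategory_rho) > 1:
            raise ValueError("intercategory_rho must lie in [-1, 1]")

    @property
    def common_variance(self) -> float:
        """Variance ``sigma_b^2 = v * alpha`` of the shared category bias."""
        return self.bias_variance * self.alpha_target

    @property
    def stimulus_variance(self) -> float:
        """Variance ``sigma_d^2 = p * v * (1 - alpha)`` of the per-stimulus
        deviations; scaled by ``p`` so the category score variance stays
        ``v`` for every alpha."""
        return self.n_stimuli * self.bias_variance * (1.0 - self.alpha_target)

    @property
    def n_trials(self) -> int:
        per_stim = self.n_reps * (2 if self.has_directions else 1)
        return self.n_categories * self.n_stimuli * per_stim

    def score_spec(self, aggregator: str = "mean") -> ScoreSpec:
        """The score this design is built for: double difference with two
        categories and directions, single difference with one contrast,
        plain aggregate otherwise."""
        factors: list[str] = []
        orientation = {}
        if self.n_categories == 2:
            factors.append(CATEGORY_FACTOR)
            orientation[CATEGORY_FACTOR] = CATEGORY_LEVELS[0]
        if self.has_directions:
            factors.append(DIRECTION_FACTOR)
            orientation[DIRECTION_FACTOR] = DIRECTION_LEVELS[0]
        return ScoreSpec(aggregator, tuple(factors), orientation)

    @property
    def factors(self) -> tuple[str, ...]:
        f = []
        if self.n_categories == 2:
            f.append(CATEGORY_FACTOR)
        if self.has_directions:
            f.append(DIRECTION_FACTOR)
        return tuple(f)


def _draw_latents(params: SimParams, rng: np.random.Generator):
    n, C, p = params.n_participants, params.n_categories, params.n_stimuli
    sig_b = np.sqrt(params.common_variance)
    sig_d = np.sqrt(params.stimulus_variance)
    if C == 2:
        rho = params.intercategory_rho
        z = rng.standard_normal((n, 2))
        b2 = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
        b = sig_b * np.column_stack([z[:, 0], b2])
    else:
        b = rng.standard_normal((n, 1)) * sig_b
    d = rng.standard_normal((n, C, p)) * sig_d
    return b, d


def _assemble(params: SimParams, b: np.ndarray, d: np.ndarray, rng: np.random.Generator) -> TrialTable:
    n, C, p, reps = params.n_participants, params.n_categories, params.n_stimuli, params.n_reps
    n_dir = 2 if params.has_directions else 1
    T = params.n_trials

    part = np.repeat(np.arange(n), T)
    cat = np.tile(np.repeat(np.arange(C), p * n_dir * reps), n)
    stim = np.tile(np.repeat(np.arange(p), n_dir * reps), n * C)
    direction = np.tile(np.repeat(np.arange(n_dir), reps), n * C * p)

    latent = b[part, cat] + d[part, cat, stim]
    if params.has_directions:
        sign = np.where(direction == 0, 0.5, -0.5)  # avoid slower than approach
        mu = params.baseline + sign * latent
    else:
        mu = params.baseline + latent
    rt = mu + rng.standard_normal(mu.size) * params.trial_sd

    # randomised presentation order within participant
    keys = rng.random(part.size)
    order = np.lexsort((keys, part))
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    presentation = inv - part * T + 1

    width = max(3, len(str(n)))
    part_labels = np.array([f"p{i + 1:0{width}d}" for i in range(n)])
    stim_labels = np.array(
        [f"{CATEGORY_LEVELS[c]}_s{s + 1}" for c in range(C) for s in range(p)]
    )
    data = {
        PARTICIPANT: part_labels[part],
        STIMULUS: stim_labels[cat * p + stim],
        RT: rt,
        PRESENTATION: presentation,
    }
    if params.n_categories == 2:
        data[CATEGORY_FACTOR] = np.array(CATEGORY_LEVELS)[cat]
    if params.has_directions:
        data[DIRECTION_FACTOR] = np.array(DIRECTION_LEVELS)[direction]
    df = pd.DataFrame(data)
    return TrialTable(df, params.factors)


def generate_dataset(params: SimParams, rng: np.random.Generator | int | None = None) -> TrialTable:
    """One synthetic dataset drawn from the hierarchical model."""
    rng = np.random.default_rng(rng)
    b, d = _draw_latents(params, rng)
    return _assemble(params, b, d, rng)


def generate_pair(
    params: SimParams, rng: np.random.Generator | int | None = None
) -> tuple[TrialTable, TrialTable]:
    """A simulated test and retest: two datasets sharing the same
    participants (identical ``b`` and ``d`` draws) with independent trial
    noise and presentation orders."""
    rng = np.random.default_rng(rng)
    b, d = _draw_latents(params, rng)
    return _assemble(params, b, d, rng), _assemble(params, b, d, rng)


def _variance_components(params: SimParams, spec: ScoreSpec) -> tuple[float, float]:
    """(true-score variance, error variance) of the full-length mean-based
    score defined by ``spec`` on this design.

    The stimulus deviations ``d`` count as true score: a replication with
    the same stimuli shares them.
    """
    if spec.cell_aggregator != "mean" or spec.aggregator == "d_score":
        raise ValueError(
            "closed-form reliability exists only for mean-based scores; "
            "use simulation for median or D scores"
        )
    n_factors = len(spec.contrast_factors)
    expected = (1 if params.n_categories == 2 else 0) + (1 if params.has_directions else 0)
    if n_factors != expected:
        raise ValueError(
            f"spec has {n_factors} contrast factors but the design implies {expected}"
        )
    v, a, p, reps, s = (
        params.bias_variance,
        params.alpha_target,
        params.n_stimuli,
        params.n_reps,
        params.trial_sd,
    )
    # per-category true variance sigma_b^2 + sigma_d^2/p = v by construction
    if params.n_categories == 2:
        v_true = 2.0 * v * a * (1.0 - params.intercategory_rho) + 2.0 * v * (1.0 - a)
    else:
        v_true = v
    # error of a mean over p*reps trials is s^2/(p*reps); each direction
    # contrast doubles it, each category term adds another copy
    n_cells = 2 ** n_factors
    v_err = n_cells * s**2 / (p * reps)
    return v_true, v_err


def true_reliability(params: SimParams, spec: ScoreSpec) -> float:
    """Closed-form reliability of the full-length mean-based score: the
    ratio of true-score variance to total score variance."""
    v_true, v_err = _variance_components(params, spec)
    if v_true + v_err == 0:
        return float("nan")
    return v_true / (v_true + v_err)


def calibrate_trial_sd(
    params: SimParams, target_reliability: float, spec: ScoreSpec
) -> SimParams:
    """Parameters whose mean-based score has the requested reliability.

    Solves the monotone relation between trial noise and reliability for the
    trial SD in closed form; a target of exactly 0 is realised by removing
    the true-score variance (``bias_variance = 0``) instead, since no finite
    noise level can null a positive true-score variance.
    """
    if not 0.0 <= target_reliability < 1.0:
        raise ValueError("target reliability must lie in [0, 1)")
    if target_reliability == 0.0:
        return replace(params, bias_variance=0.0)
    probe = replace(params, trial_sd=1.0)
    v_true, unit_err = _variance_components(probe, spec)
    if v_true <= 0:
        raise ValueError("target unattainable: design has no true-score variance")
    s2 = v_true * (1.0 - target_reliability) / (target_reliability * unit_err)
    return replace(params, trial_sd=float(np.sqrt(s2)))
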