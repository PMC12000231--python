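"""Per-participant scores: cell aggregates, difference scores, D-scores.

A score specification names an aggregator (mean, median, or D-score) and an
ordered list of zero, one, or two contrast factors.  Zero factors give the
plain aggregate of all trials; one factor gives a single difference between
its two levels; two factors give a double difference, e.g. the
approach-avoidance bias contrast

    (avoid target - approach target) - (avoid control - approach control).

The orientation (which level is the minuend) is declared explicitly so the
sign convention of a bias score is reproducible.  The D-score divides the
mean-based score by the participant's overall RT standard deviation across
all included trials (unbiased, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import PARTICIPANT, RT, ConfigError, TrialTable

__all__ = ["ScoreSpec", "ScoreVector", "aggregate_cell", "participant_score", "score_vector"]


@dataclass(frozen=True)
class ScoreSpec:
    """How one participant score is formed from trial-level RTs.

    Parameters
    ----------
    aggregator:
        ``"mean"``, ``"median"``, or ``"d_score"``.  The D-score aggregates
        cells with means and divides the resulting score by the
        participant's overall RT standard deviation; with zero contrast
        factors it is the participant mean over their SD.
    contrast_factors:
        Ordered names of 0-2 binary factor columns to difference over.
    orientation:
        Mapping factor name -> minuend level.  Factors not listed use their
        lexicographically first level as minuend.
    """

    aggregator: str = "mean"
    contrast_factors: tuple[str, ...] = ()
    orientation: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aggregator not in ("mean", "median", "d_score"):
            raise ConfigError(f"unknown aggregator {self.aggregator!r}")
        if len(self.contrast_factors) > 2:
            raise ConfigError("at most two contrast factors are supported")
        object.__setattr__(self, "contrast_factors", tuple(self.contrast_factors))
        object.__setattr__(self, "orientation", dict(self.orientation))

    @property
    def cell_aggregator(self) -> str:
        """Aggregator applied within cells (D-scores are mean-based)."""
        return "mean" if self.aggregator == "d_score" else self.aggregator

    def ordered_levels(self, table: TrialTable, factor: str) -> tuple:
        """(minuend, subtrahend) levels of ``factor``."""
        levels = table.factor_levels(factor)
        if len(levels) != 2:
            raise ConfigError(
                f"contrast factor {factor!r} has {len(levels)} level(s); "
                "a difference score needs exactly 2"
            )
        minuend = self.orientation.get(factor, levels[0])
        if minuend not in levels:
            raise ConfigError(
                f"orientation level {minuend!r} not a level of factor {factor!r}"
            )
        other = levels[1] if levels[0] == minuend else levels[0]
        return (minuend, other)

    def cell_weights(self, table: TrialTable) -> list[tuple[dict, float]]:
        """Required cells as (factor-level dict, contrast weight) pairs.

        Zero factors: one cell with weight 1.  One factor: (+1, -1).  Two
        factors ``(f1, f2)``: weights ``+1, -1, -1, +1`` over the cells
        ``(minu, minu), (minu, sub), (sub, minu), (sub, sub)``.
        """
        if not self.contrast_factors:
            return [({}, 1.0)]
        if len(self.contrast_factors) == 1:
            f = self.contrast_factors[0]
            minu, sub = self.ordered_levels(table, f)
            return [({f: minu}, 1.0), ({f: sub}, -1.0)]
        f1, f2 = self.contrast_factors
        a_minu, a_sub = self.ordered_levels(table, f1)
        b_minu, b_sub = self.ordered_levels(table, f2)
        return [
            ({f1: a_minu, f2: b_minu}, 1.0),
            ({f1: a_minu, f2: b_sub}, -1.0),
            ({f1: a_sub, f2: b_minu}, -1.0),
            ({f1: a_sub, f2: b_sub}, 1.0),
        ]


@dataclass(frozen=True)
class ScoreVector:
    """One score per participant; NaN marks an undefined score (a required
    cell was empty).  ``scores`` is aligned with ``participants``."""

    participants: np.ndarray
    scores: np.ndarray

    def defined(self) -> np.ndarray:
        return np.isfinite(self.scores)

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=pd.Index(self.participants, name=PARTICIPANT))


def aggregate_cell(rts, aggregator: str = "mean") -> float:
    """Mean or median of one cell's RTs; NaN for an empty cell (the
    undefined-cell signal, propagated rather than raised)."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        return float("nan")
    if aggregator == "mean":
        return float(rts.mean())
    if aggregator == "median":
        return float(np.median(rts))
    raise ConfigError(f"unknown cell aggregator {aggregator!r}")


def participant_score(trials: pd.DataFrame, spec: ScoreSpec, table: TrialTable) -> float:
    """Score of a single participant's trials under ``spec``.

    ``table`` supplies the factor-level universe so the orientation is the
    same for every participant.  Returns NaN when any required cell is
    empty.
    """
    total = 0.0
    for levels, weight in spec.cell_weights(table):
        mask = np.ones(len(trials), dtype=bool)
        for f, lev in levels.items():
            mask &= (trials[f] == lev).to_numpy()
        cell = aggregate_cell(trials[RT].to_numpy()[mask], spec.cell_aggregator)
        if np.isnan(cell):
            return float("nan")
        total += weight * cell
    if spec.aggregator == "d_score":
        rt = trials[RT].to_numpy()
        if rt.size < 2:
            return float("nan")
        sd = rt.std(ddof=1)
        if sd == 0.0:
            return float("nan")
        total /= sd
    return float(total)


def score_vector(table: TrialTable, spec: ScoreSpec) -> ScoreVector:
    """One score per participant under ``spec``.

    Mean-based scores (mean and D-score) are computed with grouped sums;
    medians fall back to a per-participant loop.
    """
    for f in spec.contrast_factors:
        if f not in table.df.columns:
            raise ConfigError(f"contrast factor {f!r} not in table")
    participants = table.participants
    if spec.cell_aggregator == "mean":
        return ScoreVector(participants, _mean_scores(table, spec, participants))
    groups = table.df.groupby(PARTICIPANT, observed=True, sort=False)
    scores = np.full(len(participants), np.nan)
    index = {p: i for i, p in enumerate(participants)}
    for pid, sub in groups:
        scores[index[pid]] = participant_score(sub, spec, table)
    return ScoreVector(participants, scores)


def _mean_scores(table: TrialTable, spec: ScoreSpec, participants: np.ndarray) -> np.ndarray:
    df = table.df
    n = len(participants)
    part, uniq = pd.factorize(df[PARTICIPANT], sort=False)
    assert list(uniq) == list(participants)
    rt = df[RT].to_numpy()
    total = np.zeros(n)
    defined = np.ones(n, dtype=bool)
    for levels, weight in spec.cell_weights(table):
        mask = np.ones(len(df), dtype=bool)
        for f, lev in levels.items():
            mask &= (df[f] == lev).to_numpy()
        sums = np.bincount(part[mask], rt[mask], minlength=n)
        counts = np.bincount(part[mask], minlength=n)
        defined &= counts > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            total += weight * (sums / counts)
    if spec.aggregator == "d_score":
        counts_all = np.bincount(part, minlength=n)
        s = np.bincount(part, rt, minlength=n)
        sq = np.bincount(part, rt**2, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            var = (sq - s**2 / counts_all) / (counts_all - 1)
            sd = np.sqrt(var)
        defined &= (counts_all > 1) & (sd > 0)
        total = total / sd
    total[~defined] = np.nan
    return total
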