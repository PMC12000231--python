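"""Trial-to-half assignment schemes.

The random schemes split each participant's trials so that both halves
contain near-equal numbers of trials per condition (and, when stratifying by
stimulus, per stimulus).  The balanced splitting algorithm works bottom-up
through the stratum hierarchy participant > condition > stimulus:

(a) trials within each bottom stratum are divided into random pairs, leaving
    0 or 1 leftover trial per stratum;
(b) each pair sends one trial to each half, at random;
(c) leftover trials are pooled within the parent stratum and pair-split
    there themselves; a final odd leftover at the participant level is
    assigned to a half uniformly at random.

This keeps the half sizes within each stratum apart by at most one trial
while every balanced assignment remains reachable.  Pair membership is drawn
fresh for every split.  The deterministic schemes (odd-even and
first-second) use the trial's original presentation index, so halves stay
aligned with the experiment's alternation structure even after exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PARTICIPANT, PRESENTATION, STIMULUS, ConfigError, DataError, TrialTable

__all__ = [
    "SplitAssignment",
    "stratified_split",
    "condition_balanced_split",
    "odd_even_split",
    "first_second_split",
    "monte_carlo_resample",
]


@dataclass(frozen=True)
class SplitAssignment:
    """Half labels (1 or 2) for every trial of a table, plus scheme metadata."""

    halves: np.ndarray  # int8 array aligned with table.df rows
    scheme: str
    stratify_by_stimulus: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.halves, dtype=np.int8)
        object.__setattr__(self, "halves", h)
        if not np.isin(h, (1, 2)).all():
            raise ValueError("every trial must be assigned to half 1 or half 2")

    def mask(self, half: int) -> np.ndarray:
        return self.halves == half


def _pair_split(indices: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Randomly pair ``indices``; one of each pair to each half.

    Returns (half1, half2, leftover) index arrays; leftover has 0 or 1
    elements.  Because the pairing and the within-pair coin flips are
    exchangeable over the elements, the half-1 set is a uniformly random
    ``floor(n/2)``-subset.
    """
    n = indices.size
    perm = rng.permutation(indices)
    n_pairs = n // 2
    pairs = perm[: 2 * n_pairs].reshape(n_pairs, 2)
    flip = rng.integers(0, 2, size=n_pairs)
    half1 = pairs[np.arange(n_pairs), flip]
    half2 = pairs[np.arange(n_pairs), 1 - flip]
    leftover = perm[2 * n_pairs :]
    return half1, half2, leftover


def _balanced_split(
    table: TrialTable, rng: np.random.Generator, by_stimulus: bool, scheme: str
) -> SplitAssignment:
    if len(table) == 0:
        raise DataError("cannot split an empty table")
    df = table.df
    halves = np.zeros(len(df), dtype=np.int8)
    pos = np.arange(len(df))

    strat_cols = [PARTICIPANT, *table.factors]
    if by_stimulus:
        strat_cols = strat_cols + [STIMULUS]
        cell_cols = [PARTICIPANT, *table.factors]
    else:
        cell_cols = [PARTICIPANT]

    # bottom strata
    cell_leftovers: dict[tuple, list] = {}
    grouped = pd.DataFrame({c: df[c] for c in strat_cols}).assign(_pos=pos)
    for key, sub in grouped.groupby(strat_cols, observed=True, sort=True):
        h1, h2, left = _pair_split(sub["_pos"].to_numpy(), rng)
        halves[h1] = 1
        halves[h2] = 2
        parent = key[: len(cell_cols)] if isinstance(key, tuple) else (key,)
        if left.size:
            cell_leftovers.setdefault(parent, []).append(left[0])

    # parent stratum: pool child leftovers and pair-split them
    participant_leftovers: dict[object, list] = {}
    for parent, idxs in sorted(cell_leftovers.items(), key=lambda kv: str(kv[0])):
        h1, h2, left = _pair_split(np.asarray(idxs), rng)
        halves[h1] = 1
        halves[h2] = 2
        if left.size:
            participant_leftovers.setdefault(parent[0], []).append(left[0])

    # top (participant) stratum; a final odd trial gets a fair coin
    if by_stimulus:
        for _, idxs in sorted(participant_leftovers.items(), key=lambda kv: str(kv[0])):
            h1, h2, left = _pair_split(np.asarray(idxs), rng)
            halves[h1] = 1
            halves[h2] = 2
            if left.size:
                halves[left[0]] = rng.integers(1, 3)
    else:
        for _, idxs in participant_leftovers.items():
            for i in idxs:
                halves[i] = rng.integers(1, 3)

    return SplitAssignment(halves, scheme, by_stimulus)


def stratified_split(table: TrialTable, rng: np.random.Generator) -> SplitAssignment:
    """Random balanced split stratified by participant > condition > stimulus."""
    return _balanced_split(table, rng, by_stimulus=True, scheme="stratified")


def condition_balanced_split(table: TrialTable, rng: np.random.Generator) -> SplitAssignment:
    """Random split balanced per participant x condition (no stimulus level)."""
    return _balanced_split(table, rng, by_stimulus=False, scheme="condition_balanced")


def odd_even_split(table: TrialTable) -> SplitAssignment:
    """Deterministic split by the parity of the presentation index."""
    idx = table.df[PRESENTATION].to_numpy()
    halves = np.where(idx % 2 == 1, 1, 2).astype(np.int8)
    return SplitAssignment(halves, "odd_even")


def first_second_split(table: TrialTable) -> SplitAssignment:
    """Deterministic split at the middle of each participant's session.

    The first ``ceil(m/2)`` retained trials (by presentation order) form
    half 1.  The halves need not be balanced by condition; use
    :func:`permsplit.diagnostics` style cell counts to inspect imbalance.
    """
    df = table.df
    halves = np.zeros(len(df), dtype=np.int8)
    codes, _ = pd.factorize(df[PARTICIPANT], sort=False)
    pres = df[PRESENTATION].to_numpy()
    for code in np.unique(codes):
        pos = np.flatnonzero(codes == code)
        order = pos[pres[pos].argsort()]
        cut = (order.size + 1) // 2
        halves[order[:cut]] = 1
        halves[order[cut:]] = 2
    return SplitAssignment(halves, "first_second")


def monte_carlo_resample(
    table: TrialTable, rng: np.random.Generator
) -> tuple[TrialTable, TrialTable]:
    """Two per-participant with-replacement resamples of the table.

    Each resample draws, for every participant, as many trials as the
    participant originally had.  Because sampling is with replacement, the
    same trial can land in both resamples; this is what makes the Monte
    Carlo split-half coefficient overestimate reliability.
    """
    df = table.df.reset_index(drop=True)
    picks: list[list[int]] = [[], []]
    for _, sub in df.groupby(PARTICIPANT, observed=True, sort=False):
        rows = sub.index.to_numpy()
        for k in range(2):
            picks[k].append(rng.choice(rows, size=rows.size, replace=True))
    out = []
    for k in range(2):
        rows = np.concatenate(picks[k])
        sampled = df.loc[rows].reset_index(drop=True)
        # re-index presentations so the resample is itself a valid table
        sampled[PRESENTATION] = sampled.groupby(PARTICIPANT, observed=True).cumcount() + 1
        out.append(TrialTable(sampled, table.factors))
    return out[0], out[1]
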