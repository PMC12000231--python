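"""Vectorised split-correlation engine for complete balanced designs.

The general splitter in :mod:`permsplit.splitting` works trial by trial and
handles arbitrary cell sizes.  For the complete balanced designs produced by
the synthetic-data generator (every participant x condition x stimulus
stratum has the same even number of trials), the balanced pair-splitting
algorithm admits a much faster equivalent form: random pairing followed by a
fair coin per pair is exchangeable over the trials of a stratum, so the
half-1 set is a uniformly random half-sized subset of the stratum, drawn
independently per stratum (no leftovers exist when all strata are even).
The engine exploits this by drawing subset patterns for thousands of splits
at once and computing all per-split scores and correlations with numpy
array operations.

Three selection paths are used per stratum size ``m``:

- pattern path (``C(m, m/2) <= 512``): every half-subset of the stratum is
  enumerated once; a split draws one pattern index per stratum, and
  per-pattern half sums / half values are precomputed lookup tables;
- blocked path (larger ``m`` divisible by 8): the stratum is cut into
  blocks of 8 trials; a uniform half-subset factorises exactly into
  hypergeometric per-block counts followed by uniform within-block subsets,
  so 256-entry bit-pattern lookup tables per block replace sorting;
- argsort path (remaining sizes): random keys are drawn per trial and the
  ``m/2`` smallest keys of each stratum form half 1.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .data_model import PARTICIPANT, RT, STIMULUS, TrialTable
from .scoring import ScoreSpec

__all__ = ["BalancedDesign", "NotBalancedError", "rowwise_pearson"]

_MAX_PATTERNS = 512
_CHUNK_ELEMS = 12_000_000


class NotBalancedError(ValueError):
    """The table is not a complete equal-size balanced design."""


def rowwise_pearson(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``x`` with the same row of ``y``.

    Rows with zero variance in either argument yield NaN.
    """
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.clip(r, -1.0, 1.0)


class BalancedDesign:
    """Precomputed structure of a balanced table for fast repeated splitting.

    Requires every stratum (participant x condition cell, or additionally x
    stimulus when ``stratify_by_stimulus``) to contain the same even number
    of trials, and every cell to contain the same number of strata.
    """

    def __init__(
        self,
        table: TrialTable,
        spec: ScoreSpec,
        stratify_by_stimulus: bool = True,
    ) -> None:
        df = table.df
        if set(spec.contrast_factors) != set(table.factors):
            raise NotBalancedError(
                "engine requires the score's contrast factors to equal the "
                "table's declared factors"
            )
        self.spec = spec
        self.stratify_by_stimulus = stratify_by_stimulus

        part_codes, self.participants = pd.factorize(df[PARTICIPANT], sort=True)
        n = len(self.participants)

        cell_defs = spec.cell_weights(table)
        self.weights = np.array([w for _, w in cell_defs])
        n_cpp = len(cell_defs)
        cell_within = np.full(len(df), -1, dtype=np.int64)
        for j, (levels, _) in enumerate(cell_defs):
            m = np.ones(len(df), dtype=bool)
            for f, lev in levels.items():
                m &= (df[f] == lev).to_numpy()
            cell_within[m] = j
        if (cell_within < 0).any():
            raise NotBalancedError("trials outside the score's cells")

        cell_code = part_codes * n_cpp + cell_within
        if stratify_by_stimulus:
            stim_codes, stim_index = pd.factorize(df[STIMULUS], sort=True)
            stratum_code = cell_code * len(stim_index) + stim_codes
        else:
            stratum_code = cell_code

        order = np.argsort(stratum_code, kind="stable")
        sorted_strata = stratum_code[order]
        uniq, counts = np.unique(sorted_strata, return_counts=True)
        m = int(counts[0])
        if not (counts == m).all() or m % 2 != 0:
            raise NotBalancedError(
                "strata are not all of the same even size "
                f"(sizes {sorted(set(counts.tolist()))})"
            )
        n_strata = uniq.size
        if n_strata % (n * n_cpp) != 0:
            raise NotBalancedError("cells contain unequal numbers of strata")
        q = n_strata // (n * n_cpp)  # strata per cell

        # map each stratum to its cell and arrange strata cell-major
        stratum_cell = cell_code[order].reshape(n_strata, m)[:, 0]
        expect = np.repeat(np.arange(n * n_cpp), q)
        if not (np.sort(stratum_cell) == expect).all():
            raise NotBalancedError("cells contain unequal numbers of strata")
        cell_order = np.argsort(stratum_cell, kind="stable")

        self.n_participants = n
        self.n_cpp = n_cpp
        self.m = m
        self.q = q
        self.n_strata = n_strata
        self.half = m // 2
        self.trials_per_cell_half = q * self.half
        # strata arranged cell-major so reshape (n_cells, q) groups cells
        self.order = order.reshape(n_strata, m)[cell_order]
        self.rt_g = df[RT].to_numpy(dtype=float)[self.order]

        self.n_patterns = _n_choose_k(m, self.half)
        self.pat_positions = None
        if self.n_patterns <= _MAX_PATTERNS:
            self.path = "pattern"
            pos = np.array(list(combinations(range(m), self.half)), dtype=np.int64)
            self.pat_positions = pos  # (n_pat, half)
            sets = [frozenset(p) for p in pos]
            full = frozenset(range(m))
            lookup = {s: i for i, s in enumerate(sets)}
            self.pat_complement = np.array([lookup[full - s] for s in sets])
        elif m % 8 == 0:
            self.path = "blocked"
            self.n_blocks = m // 8
        else:
            self.path = "argsort"

    # ------------------------------------------------------------------ #

    def _chunks(self, n_splits: int, need_values: bool) -> list[int]:
        if need_values or self.path == "argsort":
            unit = self.n_strata * self.m
        elif self.path == "blocked":
            unit = self.n_strata * self.n_blocks
        else:
            unit = self.n_strata
        chunk = max(1, min(n_splits, int(_CHUNK_ELEMS / max(unit, 1))))
        sizes = [chunk] * (n_splits // chunk)
        if n_splits % chunk:
            sizes.append(n_splits % chunk)
        return sizes

    def _build_block_tables(self, need_values: bool) -> None:
        from itertools import product as iproduct
        from math import comb

        bits = ((np.arange(256)[:, None] >> np.arange(8)) & 1).astype(np.int64)
        if not hasattr(self, "_blk_sums"):
            blocks = self.rt_g.reshape(self.n_strata, self.n_blocks, 8)
            self._bit_count = bits.sum(axis=1)
            by_k = [np.flatnonzero(self._bit_count == k) for k in range(9)]
            self._k_counts = np.array([len(b) for b in by_k])
            pad = np.zeros((9, int(self._k_counts.max())), dtype=np.int64)
            for k, b in enumerate(by_k):
                pad[k, : b.size] = b
            self._k_patterns = pad
            # every way to spread the half-selection over the blocks, with
            # multivariate-hypergeometric weights
            comps = [
                c for c in iproduct(range(9), repeat=self.n_blocks)
                if sum(c) == self.half
            ]
            self._compositions = np.array(comps, dtype=np.int64)
            weights = np.array(
                [np.prod([comb(8, k) for k in c]) for c in comps], dtype=float
            )
            self._comp_cum = np.cumsum(weights / weights.sum())
            # (n_strata, n_blocks, 256) half-sums for every bit pattern
            self._blk_sums = blocks @ bits.T.astype(float)
            self._blk_sq = (blocks**2) @ bits.T.astype(float)
            self._tot = self.rt_g.sum(axis=1)
            self._tot_sq = (self.rt_g**2).sum(axis=1)
        if need_values and not hasattr(self, "_blk_vals"):
            blocks = self.rt_g.reshape(self.n_strata, self.n_blocks, 8)
            sel = bits.T[None, None].astype(bool)  # (1, 1, 8, 256)
            vals = np.where(
                sel.swapaxes(2, 3), blocks[:, :, None, :], np.inf
            )
            # (n_strata, n_blocks, 256, 8); +inf marks unselected slots
            self._blk_vals = vals.astype(np.float32)

    def _select_blocked(
        self, size: int, rng: np.random.Generator,
        need_values: bool, need_sq: bool,
    ) -> dict[str, np.ndarray]:
        """Uniform half-subset per stratum via hypergeometric block counts
        plus uniform within-block bit patterns."""
        self._build_block_tables(need_values)
        B = self.n_blocks
        shape = (size, self.n_strata)
        comp_idx = np.searchsorted(self._comp_cum, rng.random(shape))
        ks = [self._compositions[comp_idx, b] for b in range(B)]

        ar = np.arange(self.n_strata)
        out: dict[str, np.ndarray] = {}
        sum1 = np.zeros(shape)
        sq1 = np.zeros(shape) if need_sq else None
        vals1 = np.empty((size, self.n_strata, B, 8), dtype=np.float32) if need_values else None
        vals2 = np.empty_like(vals1) if need_values else None
        for b, k in enumerate(ks):
            u = (rng.random(shape) * self._k_counts[k]).astype(np.int64)
            pid = self._k_patterns[k, u]
            sum1 += self._blk_sums[ar, b, pid]
            if need_sq:
                sq1 += self._blk_sq[ar, b, pid]
            if need_values:
                vals1[:, :, b, :] = self._blk_vals[ar, b, pid]
                vals2[:, :, b, :] = self._blk_vals[ar, b, 255 - pid]
        out["sum1"] = sum1
        out["sum2"] = self._tot - sum1
        if need_sq:
            out["sq1"] = sq1
            out["sq2"] = self._tot_sq - sq1
        if need_values:
            # half the slots carry +inf padding; medians use the finite count
            out["val1"] = vals1.reshape(size, self.n_strata, self.m)
            out["val2"] = vals2.reshape(size, self.n_strata, self.m)
        return out

    def _select(
        self, size: int, rng: np.random.Generator,
        need_values: bool, need_sq: bool = False,
    ):
        """Half-1/half-2 stratum sums (plus values and sums of squares when
        requested) for ``size`` splits."""
        if self.path == "blocked":
            return self._select_blocked(size, rng, need_values, need_sq)
        out: dict[str, np.ndarray] = {}
        if self.pat_positions is not None:
            pat_idx = rng.integers(0, self.n_patterns, size=(size, self.n_strata))
            ar = np.arange(self.n_strata)
            if not hasattr(self, "_pat_sums"):
                vals = self.rt_g[:, self.pat_positions.T].swapaxes(1, 2)
                # vals: (n_strata, n_pat, half) selected values per pattern;
                # stored as float32 -- the gathers and medians are memory-bound
                # and RT values need nowhere near double precision
                self._pat_vals = np.ascontiguousarray(vals, dtype=np.float32)
                self._pat_sums = vals.sum(axis=2)
                self._pat_sq = (vals**2).sum(axis=2)
                self._tot = self.rt_g.sum(axis=1)
                self._tot_sq = (self.rt_g**2).sum(axis=1)
            out["sum1"] = self._pat_sums[ar, pat_idx]
            out["sum2"] = self._tot - out["sum1"]
            if need_sq:
                out["sq1"] = self._pat_sq[ar, pat_idx]
                out["sq2"] = self._tot_sq - out["sq1"]
            if need_values:
                out["val1"] = self._pat_vals[ar, pat_idx]
                out["val2"] = self._pat_vals[ar, self.pat_complement[pat_idx]]
            out["pat_idx"] = pat_idx
        else:
            keys = rng.random((size, self.n_strata, self.m), dtype=np.float32)
            idx = np.argsort(keys, axis=-1)
            if not hasattr(self, "_rt_g32"):
                self._rt_g32 = self.rt_g.astype(np.float32)
            rt = np.broadcast_to(self._rt_g32, (size, self.n_strata, self.m))
            val1 = np.take_along_axis(rt, idx[..., : self.half], axis=-1)
            val2 = np.take_along_axis(rt, idx[..., self.half :], axis=-1)
            # accumulate sums in float64: the D-score variance subtracts two
            # large near-equal quantities
            out["sum1"] = val1.sum(-1, dtype=np.float64)
            out["sum2"] = val2.sum(-1, dtype=np.float64)
            if need_sq:
                out["sq1"] = (val1.astype(np.float64) ** 2).sum(-1)
                out["sq2"] = (val2.astype(np.float64) ** 2).sum(-1)
            if need_values:
                out["val1"], out["val2"] = val1, val2
        return out

    def _scores(self, sel: dict, aggregator: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-split score vectors of both halves: (S, n_participants) x 2."""
        S = sel["sum1"].shape[0]
        n, n_cpp, q = self.n_participants, self.n_cpp, self.q
        out = []
        for side in (1, 2):
            if aggregator == "median":
                # value arrays carry q*half finite entries per cell; the
                # blocked path pads to q*m slots with +inf, which sorts last
                width = sel[f"val{side}"].shape[-1]
                vals = sel[f"val{side}"].reshape(S, n * n_cpp, q * width)
                cell = _padded_median(vals, self.trials_per_cell_half)
            else:
                cell = sel[f"sum{side}"].reshape(S, n * n_cpp, q).sum(-1)
                cell = cell / self.trials_per_cell_half
            scores = (cell.reshape(S, n, n_cpp) * self.weights).sum(-1)
            if aggregator == "d_score":
                tot = sel[f"sum{side}"].reshape(S, n, n_cpp * q).sum(-1)
                sq = sel[f"sq{side}"].reshape(S, n, n_cpp * q).sum(-1)
                cnt = n_cpp * q * self.half
                var = (sq - tot**2 / cnt) / (cnt - 1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    scores = scores / np.sqrt(var)
            out.append(scores)
        return out[0], out[1]

    # ------------------------------------------------------------------ #

    def split_correlations(
        self,
        n_splits: int,
        rng: np.random.Generator,
        aggregators: tuple[str, ...] = ("mean",),
    ) -> dict[str, np.ndarray]:
        """Split-half Pearson correlations of ``n_splits`` random balanced
        splits, for each requested aggregator, all aggregators sharing the
        same splits."""
        need_values = "median" in aggregators
        need_sq = "d_score" in aggregators
        res = {a: np.empty(n_splits) for a in aggregators}
        done = 0
        for size in self._chunks(n_splits, need_values):
            sel = self._select(size, rng, need_values, need_sq)
            for agg in aggregators:
                s1, s2 = self._scores(sel, agg)
                res[agg][done : done + size] = rowwise_pearson(s1, s2)
            done += size
        return res

    def full_scores(self, aggregator: str = "mean") -> np.ndarray:
        """Participant scores on the complete (unsplit) data, ordered by
        ``self.participants``."""
        n, n_cpp, q, m = self.n_participants, self.n_cpp, self.q, self.m
        cells = self.rt_g.reshape(n * n_cpp, q * m)
        if aggregator == "median":
            cell_agg = np.median(cells, axis=1)
        else:
            cell_agg = cells.mean(axis=1)
        scores = (cell_agg.reshape(n, n_cpp) * self.weights).sum(axis=1)
        if aggregator == "d_score":
            per_part = self.rt_g.reshape(n, n_cpp * q * m)
            scores = scores / per_part.std(axis=1, ddof=1)
        return scores

    def split_masks(self, n_splits: int, rng: np.random.Generator) -> np.ndarray:
        """Boolean half-1 masks, (n_splits, n_trials), in original row order.

        Intended for small numbers of splits (e.g., carving a dataset into a
        simulated test and retest half).
        """
        T = self.order.size
        masks = np.zeros((n_splits, T), dtype=bool)
        s_idx = np.arange(n_splits)[:, None, None]
        if self.path == "pattern":
            sel = self._select(n_splits, rng, need_values=False)
            offsets = self.pat_positions[sel["pat_idx"]]  # (S, n_strata, half)
            rows = self.order[np.arange(self.n_strata)[None, :, None], offsets]
        else:
            # key-sorting draws the same uniform half-subsets; fine for the
            # small split counts this method is meant for
            keys = rng.random((n_splits, self.n_strata, self.m))
            idx = np.argsort(keys, axis=-1)[..., : self.half]
            rows = np.take_along_axis(
                np.broadcast_to(self.order, (n_splits, self.n_strata, self.m)),
                idx,
                axis=-1,
            )
        masks[np.broadcast_to(s_idx, rows.shape), rows] = True
        return masks


def _padded_median(vals: np.ndarray, n_finite: int) -> np.ndarray:
    """Median over the last axis of the ``n_finite`` smallest entries;
    +inf padding beyond ``n_finite`` never reaches the median positions."""
    if n_finite % 2 == 0:
        lo, hi = n_finite // 2 - 1, n_finite // 2
        part = np.partition(vals, (lo, hi), axis=-1)
        return (part[..., lo] + part[..., hi]) / 2.0
    mid = n_finite // 2
    return np.partition(vals, mid, axis=-1)[..., mid]


def _n_choose_k(m: int, k: int) -> int:
    from math import comb

    return comb(m, k)
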