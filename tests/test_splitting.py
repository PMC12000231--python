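"""Splitting schemes: balance invariants, determinism, resampling."""

import numpy as np
import pandas as pd
import pytest

from permsplit.data_model import TrialTable
from permsplit.scoring import ScoreSpec
from permsplit.splitting import (
    condition_balanced_split,
    first_second_split,
    monte_carlo_resample,
    odd_even_split,
    stratified_split,
)
from permsplit.synthetic import SimParams, generate_dataset
from permsplit._engine import BalancedDesign, NotBalancedError
from tests.conftest import make_table


def single_factor_table(stim_sizes: dict[str, int], participant="p1"):
    """One participant, one condition level, given trials per stimulus."""
    rows = []
    for stim, m in stim_sizes.items():
        for _ in range(m):
            rows.append((participant, stim, "a", float(500 + len(rows))))
    return make_table(rows, factors=("condition",))


def half_counts(table, assignment, keys):
    df = table.df.assign(half=assignment.halves)
    return df.groupby([*keys, "half"], observed=True).size().unstack("half", fill_value=0)


class TestStratifiedBalance:
    @pytest.mark.parametrize("m", range(1, 10))
    def test_single_stratum_counts_differ_by_at_most_one(self, m):
        table = single_factor_table({"s1": m})
        for seed in range(60):
            a = stratified_split(table, np.random.default_rng(seed))
            c1, c2 = int((a.halves == 1).sum()), int((a.halves == 2).sum())
            assert c1 + c2 == m
            assert abs(c1 - c2) <= 1
            # forced counts: each half gets at least floor(m/2)
            assert min(c1, c2) == m // 2

    def test_even_stratum_forced_split(self):
        table = single_factor_table({"s1": 8})
        a = stratified_split(table, np.random.default_rng(0))
        assert (a.halves == 1).sum() == 4

    def test_leftovers_pool_to_parent_stratum(self):
        # two stimuli of 3 trials: each contributes 1/1 from its pair and
        # the two leftovers form one pair split 1/1 -> halves are 3/3
        table = single_factor_table({"s1": 3, "s2": 3})
        seen_imbalanced_stimulus = False
        for seed in range(200):
            a = stratified_split(table, np.random.default_rng(seed))
            counts = half_counts(table, a, ["stimulus"])
            assert counts.sum().sum() == 6
            assert (abs(counts[1] - counts[2]) <= 1).all()
            # overall exactly 3/3: leftovers are pair-split, not coin-flipped
            assert (a.halves == 1).sum() == 3
            if (counts[1] != counts[2]).any():
                seen_imbalanced_stimulus = True
        assert seen_imbalanced_stimulus  # leftover really moves between halves

    @pytest.mark.parametrize("sizes", [(1, 1, 1), (5, 3, 2), (7, 1, 4), (9, 9, 2)])
    def test_participant_imbalance_at_most_one(self, sizes):
        table = single_factor_table({f"s{i}": m for i, m in enumerate(sizes)})
        for seed in range(40):
            a = stratified_split(table, np.random.default_rng(seed))
            c1 = int((a.halves == 1).sum())
            assert abs(2 * c1 - sum(sizes)) <= 1
            counts = half_counts(table, a, ["stimulus"])
            assert (abs(counts[1] - counts[2]) <= 1).all()

    def test_condition_cells_balanced(self, toy_aat):
        for seed in range(30):
            a = condition_balanced_split(toy_aat, np.random.default_rng(seed))
            counts = half_counts(toy_aat, a, ["participant", "stimulus_type", "direction"])
            assert (abs(counts[1] - counts[2]) <= 1).all()

    def test_seed_reproducibility(self, toy_aat):
        a = stratified_split(toy_aat, np.random.default_rng(99))
        b = stratified_split(toy_aat, np.random.default_rng(99))
        assert (a.halves == b.halves).all()
        c = stratified_split(toy_aat, np.random.default_rng(100))
        assert (a.halves != c.halves).any()


class TestDeterministicSchemes:
    def test_odd_even_parity(self):
        rows = [("p1", "s1", "a", float(500 + i)) for i in range(4)]
        table = make_table(rows, factors=("condition",))
        a = odd_even_split(table)
        assert list(a.halves) == [1, 2, 1, 2]

    def test_odd_even_uses_original_index_after_exclusion(self):
        rows = [("p1", "s1", "a", float(500 + i)) for i in range(8)]
        table = make_table(rows, factors=("condition",))
        kept = table.subset(np.isin(table.df["presentation"], [1, 2, 5, 8]))
        a = odd_even_split(kept)
        got = dict(zip(kept.df["presentation"], a.halves))
        assert got == {1: 1, 5: 1, 2: 2, 8: 2}

    def test_first_second_halves(self):
        rows = [("p1", "s1", "a", float(500 + i)) for i in range(5)]
        table = make_table(rows, factors=("condition",))
        a = first_second_split(table)
        assert list(a.halves) == [1, 1, 1, 2, 2]

    def test_first_second_reports_condition_imbalance(self):
        # interleaved conditions front-loaded on one level
        rows = [("p1", "s1", "a", 500.0), ("p1", "s1", "a", 510.0),
                ("p1", "s1", "b", 520.0), ("p1", "s1", "b", 530.0)]
        table = make_table(rows, factors=("condition",))
        a = first_second_split(table)
        counts = half_counts(table, a, ["condition"])
        assert (counts.loc["a"] == [2, 0]).all() and (counts.loc["b"] == [0, 2]).all()


class TestMonteCarloResample:
    def test_sizes_preserved_and_forced_singleton(self):
        rows = [("p1", "s1", "a", 500.0)] + [("p2", "s1", "a", float(510 + i)) for i in range(5)]
        table = make_table(rows, factors=("condition",))
        t1, t2 = monte_carlo_resample(table, np.random.default_rng(0))
        for t in (t1, t2):
            sizes = t.df.groupby("participant").size()
            assert sizes["p1"] == 1 and sizes["p2"] == 5
            assert t.df.loc[t.df["participant"] == "p1", "rt"].iloc[0] == 500.0

    def test_distinct_fraction_matches_with_replacement_theory(self):
        m = 8
        rows = [("p1", "s1", "a", float(500 + i)) for i in range(m)]
        table = make_table(rows, factors=("condition",))
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(400):
            t1, _ = monte_carlo_resample(table, rng)
            fracs.append(t1.df["rt"].nunique() / m)
        expected = 1 - (1 - 1 / m) ** m
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)


@pytest.fixture(scope="module")
def design_setup():
    params = SimParams(n_participants=6, n_stimuli=2, n_reps=2)
    table = generate_dataset(params, np.random.default_rng(0))
    spec = params.score_spec("mean")
    return table, spec


class TestEngineEquivalence:
    """The vectorised engine must draw the same split distribution as the
    general pair-and-pool splitter on balanced even designs."""

    def test_engine_requires_balance(self, design_setup):
        table, spec = design_setup
        with pytest.raises(NotBalancedError):
            BalancedDesign(table.subset(np.arange(len(table)) > 0), spec)

    def test_half_count_invariants(self, design_setup):
        table, spec = design_setup
        design = BalancedDesign(table, spec, stratify_by_stimulus=True)
        masks = design.split_masks(50, np.random.default_rng(1))
        df = table.df
        for mask in masks:
            counts = (
                df.assign(h=mask)
                .groupby(["participant", "stimulus_type", "direction", "stimulus"])["h"]
                .agg(["sum", "size"])
            )
            assert (counts["sum"] * 2 == counts["size"]).all()

    def test_stratum_selection_uniformity(self, design_setup):
        # stratum size 2 choose 1: each trial of a pair lands in half 1
        # about half the time, independent across strata
        table, spec = design_setup
        design = BalancedDesign(table, spec, stratify_by_stimulus=True)
        masks = design.split_masks(2000, np.random.default_rng(2))
        rates = masks.mean(axis=0)
        assert abs(rates - 0.5).max() < 0.05

    def test_correlations_match_general_splitter_distribution(self, design_setup):
        from permsplit.aggregation import pearson
        from permsplit.scoring import score_vector

        params = SimParams(n_participants=12, n_stimuli=2, n_reps=2, trial_sd=3.0)
        table = generate_dataset(params, np.random.default_rng(3))
        spec = params.score_spec("mean")
        design = BalancedDesign(table, spec, stratify_by_stimulus=True)
        rng = np.random.default_rng(4)
        fast = design.split_correlations(400, rng, ("mean",))["mean"]
        slow = []
        for seed in range(400):
            a = stratified_split(table, np.random.default_rng(1000 + seed))
            s1 = score_vector(table.subset(a.mask(1)), spec).scores
            s2 = score_vector(table.subset(a.mask(2)), spec).scores
            slow.append(pearson(s1, s2))
        # same distribution: compare means within Monte Carlo tolerance
        se = np.hypot(np.std(fast) / 20, np.std(slow) / 20)
        assert abs(fast.mean() - np.mean(slow)) < 4 * se

    def test_single_stimulus_stratified_equals_condition_balanced(self):
        params = SimParams(n_participants=10, n_stimuli=1, n_reps=8, trial_sd=3.0)
        table = generate_dataset(params, np.random.default_rng(6))
        spec = params.score_spec("mean")
        rng = np.random.default_rng(7)
        strat = BalancedDesign(table, spec, True).split_correlations(600, rng, ("mean",))["mean"]
        cond = BalancedDesign(table, spec, False).split_correlations(600, rng, ("mean",))["mean"]
        se = np.hypot(np.std(strat) / np.sqrt(600), np.std(cond) / np.sqrt(600))
        assert abs(strat.mean() - cond.mean()) < 4 * se
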