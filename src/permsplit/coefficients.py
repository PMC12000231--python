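"""The reliability estimators: internal-consistency and split-half families.

Five single-session estimators are provided:

- ``alpha_pipeline``: Cronbach's alpha over stimulus-specific subscores,
  combined across stimulus categories with Lord's difference-score formula
  when the score is a difference of two stimulus sets.  Provided because it
  is common practice, not because it is recommended: it ignores trial-level
  variance and systematically underestimates reliability.
- ``single_splithalf``: one split (e.g. odd-even), Pearson correlation,
  Spearman-Brown correction.
- ``permutation_splithalf``: many random balanced splits; the raw split
  correlations are aggregated (Olkin-Pratt by default) and the aggregate is
  corrected with the mirrored Spearman-Brown formula.  The recommended
  estimator, ideally with stimulus-level stratification.
- ``monte_carlo_splithalf``: correlations of with-replacement resamples,
  no length correction.  Provided to demonstrate its overestimation; the
  same trial can land in both resamples, which inflates the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .aggregation import CorrelationSample, op5_mean, pearson
from .correction import RECOMMENDED_POLICY, SBPolicy, apply_policy
from .data_model import PARTICIPANT, RT, STIMULUS, DataError, TrialTable
from .scoring import ScoreSpec, score_vector
from .splitting import (
    SplitAssignment,
    condition_balanced_split,
    monte_carlo_resample,
    stratified_split,
)
from ._engine import BalancedDesign, NotBalancedError

__all__ = [
    "ReliabilityEstimate",
    "cronbach_alpha",
    "lord_difference_alpha",
    "subscore_matrix",
    "alpha_pipeline",
    "single_splithalf",
    "permutation_splithalf",
    "monte_carlo_splithalf",
]


@dataclass(frozen=True)
class ReliabilityEstimate:
    """A reliability point estimate with optional CI and raw correlations."""

    method: str
    point: float
    ci: tuple[float, float] | None = None
    correlations: CorrelationSample | None = None
    n_splits: int = 0
    policy: SBPolicy | None = None

    def __str__(self) -> str:  # pragma: no cover - presentation only
        s = f"{self.method}: r = {self.point:.4f}"
        if self.ci is not None:
            s += f", 95% CI [{self.ci[0]:.4f}, {self.ci[1]:.4f}]"
        if self.n_splits:
            s += f" ({self.n_splits} splits)"
        return s


# --------------------------------------------------------------------- #
# internal-consistency family


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of a complete participants x items score matrix.

    alpha = p/(p-1) * (1 - sum_i Var(X_i) / sum_ij Cov(X_i, X_j))

    Sample (n-1) variances and covariances are used; the ratio is invariant
    to that common choice of denominator.  Missing entries are an error:
    alpha has no missing-data mechanism, which is one of its documented
    limitations for trial-level RT data.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise DataError("alpha needs a 2-d matrix with at least 2 items")
    if not np.isfinite(m).all():
        raise DataError(
            "subscore matrix has missing entries; Cronbach's alpha is "
            "undefined with missing data"
        )
    if m.shape[0] < 2:
        raise DataError("alpha needs at least 2 participants")
    p = m.shape[1]
    cov = np.cov(m, rowvar=False, ddof=1)
    total = cov.sum()
    if total == 0:
        raise DataError("total covariance is zero; alpha undefined")
    return float(p / (p - 1) * (1.0 - np.trace(cov) / total))


def lord_difference_alpha(
    r_a: float, r_b: float, s_a: float, s_b: float, r_ab: float
) -> float:
    """Reliability of the difference of two scores from their separate
    reliabilities, SDs, and intercorrelation:

        r_(a-b) = (r_a s_a^2 + r_b s_b^2 - 2 r_ab s_a s_b)
                  / (s_a^2 + s_b^2 - 2 r_ab s_a s_b)

    Returns NaN when the denominator (the difference-score variance) is
    zero, i.e. perfectly correlated equal-variance components.
    """
    if s_a <= 0 or s_b <= 0:
        raise ValueError("score SDs must be positive")
    denom = s_a**2 + s_b**2 - 2.0 * r_ab * s_a * s_b
    if denom <= 0:
        return float("nan")
    return float((r_a * s_a**2 + r_b * s_b**2 - 2.0 * r_ab * s_a * s_b) / denom)


def _within_factor_split(table: TrialTable, spec: ScoreSpec):
    """Partition contrast factors into the between-stimulus (category)
    factor and the within-stimulus factor, by nesting structure."""
    between, within = [], []
    for f in spec.contrast_factors:
        nested = table.df.groupby(STIMULUS, observed=True)[f].nunique()
        (between if (nested == 1).all() else within).append(f)
    if len(between) > 1 or len(within) > 1:
        raise DataError(
            "alpha pipeline supports at most one between-stimulus and one "
            "within-stimulus contrast factor"
        )
    return (between[0] if between else None), (within[0] if within else None)


def subscore_matrix(
    table: TrialTable, spec: ScoreSpec, within: str | None = None
) -> pd.DataFrame:
    """Participants x stimuli matrix of stimulus-specific (bias) subscores.

    With a within-stimulus factor, the subscore is the difference of the
    cell aggregates of its two levels (minuend first); otherwise it is the
    plain aggregate of the stimulus's trials.  NaN marks empty cells.
    """
    agg = spec.cell_aggregator
    df = table.df
    if agg == "mean":
        part, parts = pd.factorize(df[PARTICIPANT], sort=False)
        stim, stims = pd.factorize(df[STIMULUS], sort=True)
        rt = df[RT].to_numpy()
        nP, nS = len(parts), len(stims)

        def cell_means(mask):
            code = part[mask] * nS + stim[mask]
            sums = np.bincount(code, rt[mask], minlength=nP * nS)
            counts = np.bincount(code, minlength=nP * nS)
            with np.errstate(invalid="ignore", divide="ignore"):
                return (sums / counts).reshape(nP, nS)

        if within is None:
            data = cell_means(np.ones(len(df), dtype=bool))
        else:
            minu, sub = spec.ordered_levels(table, within)
            wcol = df[within].to_numpy()
            data = cell_means(wcol == minu) - cell_means(wcol == sub)
        return pd.DataFrame(data, index=parts, columns=stims)
    if within is None:
        mat = df.pivot_table(index=PARTICIPANT, columns=STIMULUS, values=RT, aggfunc=agg)
    else:
        minu, sub = spec.ordered_levels(table, within)
        piv = df.pivot_table(
            index=PARTICIPANT, columns=[STIMULUS, within], values=RT, aggfunc=agg
        )
        mat = piv.xs(minu, axis=1, level=within) - piv.xs(sub, axis=1, level=within)
    return mat.reindex(index=pd.unique(df[PARTICIPANT]))


def alpha_pipeline(table: TrialTable, spec: ScoreSpec) -> ReliabilityEstimate:
    """Cronbach's alpha of stimulus subscores, Lord-combined across two
    stimulus categories when the score subtracts one stimulus set from
    another.

    Every required participant x stimulus (x within-level) cell must be
    nonempty; this pipeline deliberately has no missing-data mechanism.
    """
    between, within = _within_factor_split(table, spec)
    if between is None:
        mat = subscore_matrix(table, spec, within)
        return ReliabilityEstimate("alpha", cronbach_alpha(mat))
    cat_minu, cat_sub = spec.ordered_levels(table, between)
    sub_factors = tuple(f for f in table.factors if f != between)
    alphas, sds, scores = {}, {}, {}
    for cat in (cat_minu, cat_sub):
        mask = (table.df[between] == cat).to_numpy()
        sub_tab = TrialTable(table.df.loc[mask], sub_factors)
        mat = subscore_matrix(sub_tab, spec, within)
        mat = mat.reindex(index=pd.unique(table.df[PARTICIPANT]))
        alphas[cat] = cronbach_alpha(mat)
        cat_scores = mat.mean(axis=1).to_numpy()
        scores[cat] = cat_scores
        sds[cat] = float(np.std(cat_scores, ddof=1))
    r_ab = pearson(scores[cat_minu], scores[cat_sub])
    point = lord_difference_alpha(
        alphas[cat_minu], alphas[cat_sub], sds[cat_minu], sds[cat_sub], r_ab
    )
    return ReliabilityEstimate("alpha", point)


# --------------------------------------------------------------------- #
# split-half family


def _split_scores(table: TrialTable, spec: ScoreSpec, assignment: SplitAssignment):
    s1 = score_vector(table.subset(assignment.mask(1)), spec).as_series()
    s2 = score_vector(table.subset(assignment.mask(2)), spec).as_series()
    joint = s1.index.intersection(s2.index)
    x = s1.reindex(joint).to_numpy()
    y = s2.reindex(joint).to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def single_splithalf(
    table: TrialTable,
    spec: ScoreSpec,
    assignment: SplitAssignment,
    policy: SBPolicy = RECOMMENDED_POLICY,
) -> ReliabilityEstimate:
    """Correlate the scores of the two halves of one split and project the
    correlation to full test length."""
    x, y = _split_scores(table, spec, assignment)
    if x.size < 4:
        raise DataError("fewer than 4 participants with defined scores in both halves")
    r = pearson(x, y)
    if np.isnan(r):
        raise DataError("split-half correlation undefined (zero variance)")
    return ReliabilityEstimate(
        f"single_splithalf[{assignment.scheme}]",
        float(policy.correct(r)),
        correlations=CorrelationSample(np.array([r]), x.size),
        n_splits=1,
        policy=policy,
    )


def _finalize_permutation(
    method: str,
    corrs: np.ndarray,
    counts: np.ndarray,
    policy: SBPolicy,
    aggregator,
    corrected_ci: bool = True,
) -> ReliabilityEstimate:
    ok = np.isfinite(corrs)
    if not ok.any():
        raise DataError("all splits produced undefined correlations")
    n_pairs = int(np.median(counts[ok]))
    sample = CorrelationSample(corrs[ok], n_pairs)
    point = apply_policy(sample, policy, aggregator)
    lo, hi = np.quantile(corrs[ok], [0.025, 0.975])
    if corrected_ci:
        lo, hi = float(policy.correct(lo)), float(policy.correct(hi))
    return ReliabilityEstimate(
        method, point, ci=(lo, hi), correlations=sample,
        n_splits=int(corrs.size), policy=policy,
    )


def permutation_splithalf(
    table: TrialTable,
    spec: ScoreSpec,
    n_splits: int = 6000,
    stratify_by_stimulus: bool = True,
    policy: SBPolicy = RECOMMENDED_POLICY,
    aggregator: Callable[[CorrelationSample], float] = op5_mean,
    rng: np.random.Generator | int | None = None,
) -> ReliabilityEstimate:
    """Permutation-based split-half reliability.

    Repeats {balanced split, score both halves, Pearson-correlate}
    ``n_splits`` times; the point estimate applies ``policy`` (by default:
    Olkin-Pratt aggregate of the raw correlations, then the mirrored
    Spearman-Brown formula), and the 95% CI takes the 2.5%/97.5% empirical
    quantiles of the raw correlations through the same correction.

    Splits are stratified by stimulus within participant and condition when
    ``stratify_by_stimulus``; otherwise balanced per condition only.
    Complete balanced designs are dispatched to a vectorised engine that
    draws the identical split distribution.
    """
    rng = np.random.default_rng(rng)
    method = "stratified_permutation" if stratify_by_stimulus else "permutation"
    try:
        design = BalancedDesign(table, spec, stratify_by_stimulus)
    except NotBalancedError:
        design = None
    if design is not None:
        corrs = design.split_correlations(n_splits, rng, (spec.aggregator,))[
            spec.aggregator
        ]
        counts = np.full(n_splits, design.n_participants)
    else:
        corrs = np.empty(n_splits)
        counts = np.zeros(n_splits)
        splitter = stratified_split if stratify_by_stimulus else condition_balanced_split
        for i in range(n_splits):
            x, y = _split_scores(table, spec, splitter(table, rng))
            counts[i] = x.size
            corrs[i] = pearson(x, y) if x.size >= 4 else np.nan
    return _finalize_permutation(method, corrs, counts, policy, aggregator)


def monte_carlo_splithalf(
    table: TrialTable,
    spec: ScoreSpec,
    n_draws: int = 1000,
    aggregator: Callable[[CorrelationSample], float] = op5_mean,
    rng: np.random.Generator | int | None = None,
) -> ReliabilityEstimate:
    """Monte Carlo split-half: correlate two with-replacement resamples of
    the data, repeat, and aggregate -- with no Spearman-Brown step, since
    the resamples are as large as the original data.

    Included to demonstrate its bias: shared trials between the resamples
    make it overestimate reliability, most visibly on noise-only data.
    """
    rng = np.random.default_rng(rng)
    corrs = np.empty(n_draws)
    counts = np.zeros(n_draws)
    for i in range(n_draws):
        t1, t2 = monte_carlo_resample(table, rng)
        s1 = score_vector(t1, spec).as_series()
        s2 = score_vector(t2, spec).as_series()
        joint = s1.index.intersection(s2.index)
        x, y = s1.reindex(joint).to_numpy(), s2.reindex(joint).to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        counts[i] = ok.sum()
        corrs[i] = pearson(x[ok], y[ok]) if ok.sum() >= 4 else np.nan
    ok = np.isfinite(corrs)
    if not ok.any():
        raise DataError("all draws produced undefined correlations")
    n_pairs = int(np.median(counts[ok]))
    sample = CorrelationSample(corrs[ok], n_pairs)
    point = float(aggregator(sample))
    lo, hi = np.quantile(corrs[ok], [0.025, 0.975])
    return ReliabilityEstimate(
        "monte_carlo", point, ci=(float(lo), float(hi)),
        correlations=sample, n_splits=int(n_draws),
    )
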