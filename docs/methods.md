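# Methods

`permsplit` estimates the single-session reliability of trial-level
reaction-time (RT) measures — mean, median, or D-scored (difference) scores —
and ships simulation harnesses that probe how well those estimators forecast
a task's test–retest correlation.

## The estimation problem

A bias score such as the approach–avoidance contrast

    score = (avoid_target − approach_target) − (avoid_control − approach_control)

is computed per participant from noisy trials. Its reliability — the squared
correlation between the observed score and the participant's true score —
bounds every correlation the score can show with anything else, so it should
be reported alongside the score. Classical internal-consistency coefficients
transfer poorly to trial-level RT data; the estimators here quantify
exactly how, and provide the recommended alternative.

## Estimators

**Stratified permutation-based split-half (recommended).** Repeat many times:
split every participant's trials into two halves balanced per condition cell
and, when stratifying, per stimulus; score each half; Pearson-correlate the
two half-score vectors. The raw split correlations `r_i` (each over `N`
participants) are aggregated with the five-term Olkin–Pratt estimator

    OP5(r) = r [ 1 + Σ_{k=1..5} Γ(1/2+k)² Γ((N−2)/2) /
                 (Γ(1/2)² Γ((N−2)/2+k) k!) · (1−r²)^k ]

(the arithmetic mean of correlations is biased toward zero, the Fisher-z
mean away from it; OP5 approximately removes the bias). The aggregate is
projected to full test length with the **mirrored Spearman–Brown** formula

    r_kk = k·r / (1 + (k−1)·|r|),   k = 2 for halves,

which applies the same magnitude of change to negative aggregates that the
standard formula applies to positive ones, instead of exploding below −1.
The 95% CI takes the 2.5%/97.5% quantiles (linear interpolation) of the raw
split correlations through the same projection; it describes the dispersion
of single splits and empirically under-covers slightly (Study-3 harness).

Nullification (zeroing negative correlations) and the standard formula, in
either application order (per split or after aggregation), remain available
as `SBPolicy` options for comparison; per-split corrected values are
aggregated with the requested method when they are valid correlations and
with an arithmetic mean in the one case (standard formula, no nullification)
whose outputs can leave [−1, 1].

**Balanced splitting.** Within each stratum (stimulus within condition cell
within participant), trials are paired at random and one member of each pair
goes to each half; a leftover trial per odd stratum is pooled with its
siblings at the parent stratum and pair-split there; a final odd trial is
assigned by a fair coin. Half counts per stratum therefore differ by at most
one. Pairings are redrawn every split. Because the procedure is exchangeable
over a stratum's trials, the half-1 set of an even stratum is exactly a
uniformly random half-sized subset — the property the vectorised engine
exploits (below).

**Deterministic split-halves.** Odd–even splits by the parity of the
original presentation index (kept through exclusions, so halves stay aligned
with the task's alternation structure); first–second splits at the session
midpoint. Both feed the same Spearman–Brown step.

**Monte Carlo split-half.** Correlates two per-participant with-replacement
resamples of the full data, aggregated without length correction. Shared
trials between the two resamples make it overestimate reliability — the
harnesses include it to demonstrate that failure mode, not for use.

**Alpha pipeline.** Per stimulus category: per-stimulus bias subscores
(within-stimulus contrast of cell aggregates), Cronbach's alpha

    α = p/(p−1) · (1 − Σ Var(X_i) / ΣΣ Cov(X_i, X_j))

over the participants × stimuli matrix (sample, n−1 denominators; the ratio
is invariant to that choice), and, for two-category difference scores,
Lord's combination

    r_{a−b} = (r_a s_a² + r_b s_b² − 2 r_ab s_a s_b) /
              (s_a² + s_b² − 2 r_ab s_a s_b)

using the category score SDs and their correlation. The pipeline
deliberately has no missing-data mechanism (an empty participant × stimulus
cell is an error) and is blind to trial-level variance once subscores are
fixed — both are the documented reasons it misestimates RT reliability.

**Predicted test–retest correlation.** Two session reliabilities predict
the cross-session correlation as `sqrt(|r1·r2|) · min(sgn r1, sgn r2)`,
undefined when the signs disagree; the prediction CI averages the two
sessions' CI endpoints. A reliability of exactly 0 is treated as
sign-compatible with either sign (prediction 0). Out-of-range inputs (the
Lord pipeline can produce estimates below −1) are transformed as-is, since
their deviated predictions are part of what the accuracy analyses measure.

## Synthetic data

`SimParams` describes an AAT-like design: `n` participants, one or two
stimulus categories of `p` stimuli, optional approach/avoid directions,
`reps` trials per stimulus per direction. The generative model per
participant `i`, category `c`, stimulus `t`:

    b_ic ~ N(0, v·α),  corr(b_i,target, b_i,control) = ρ
    d_ict ~ N(0, p·v·(1−α))
    RT = baseline ± (b_ic + d_ict)/2 + N(0, s²)      (avoid +, approach −)

(without directions the bias enters additively). Two properties define this
parameterization: the latent per-stimulus bias scores of a category have
Cronbach's alpha exactly `α`, and the latent category bias score
`b + mean_t d_t` has variance `v` for *every* `α` — the preset alpha
redistributes a fixed amount of true variance between the common and the
stimulus-specific component rather than adding variance. This makes the
observed test–retest correlation independent of `α` (at ρ = 0) and the
observed subscore alpha linear in `α` with noise dilution, which is the
behaviour the estimator-accuracy study requires of its grid. `α` is defined
on latent subscores, so `α = 1` is attainable with nonzero trial noise.

Defaults are the double-difference study design: 40 participants, 8 stimuli
per category, 8 approach + 8 avoid trials per stimulus (256 trials),
α = 0.8, v = 4, s = 6, ρ = 0. The baseline RT is 700 (a typical AAT-scale
mean RT; every estimator is invariant to it, and it keeps RTs positive).
Trial order is shuffled per participant so deterministic splits behave as
in a real session.

`true_reliability` gives the closed form for mean-based scores,
`V_T/(V_T+V_E)` with

    V_T = 2vα(1−ρ) + 2v(1−α)          (double difference; v for one category)
    V_E = (number of cells) · s² / (p·reps)

Stimulus deviations count as true score because a replication reuses the
stimuli (`generate_pair` shares `b` and `d`, redrawing only trial noise).
`calibrate_trial_sd` inverts the relation for `s` in closed form; a target
of exactly 0 is realised by removing the true variance (`v = 0`), since no
finite noise nulls a positive `V_T`. Median and D-score reliabilities have
no closed form; the harnesses that need them at a given true reliability
calibrate against the mean-based score of the same design.

**What the generator does not emulate:** right-skewed RT distributions,
sequential autocorrelation, learning/fatigue trends, errors and outliers.
Passing harness results therefore validate the estimators' behaviour under
clean Gaussian noise, not under every pathology of real RT data; the
absolute values of noise-sensitive statistics (notably the required-splits
study) depend on these choices, as discussed below.

## Study harnesses and scaled profiles

All harnesses are deterministic given `(config, seed)` and run at
configurable scale; the shipped profiles were sized so each harness
finishes in minutes on one CPU. Estimates of aggregate statistics lose very
little from reduced split counts, because split-count noise (~σ/√S) is far
below dataset-level scatter at the profile sizes.

**Estimator accuracy (Study-1-style; `run_study1`).** Full grid:
6 subscore-alpha targets × 5 bias variances {2..10} × 5 trial SDs {2..10} ×
3 intercategory correlations {−.5, 0, .5} × 2 replicates = 900
double-difference datasets (40 participants, 256 trials). Each dataset is
carved into a simulated test and retest half by one stimulus-stratified
split (an unstratified carve empties some participant × stimulus ×
direction cells and makes alpha incomputable, so a balanced carve is the
only option compatible with computing alpha at all). Each half is scored by
the selected estimators; their Eq.-5-style predictions are compared with
the observed between-half correlation. The profile used by the tests runs
the four cheap estimators at 200 splits; the full-scale figure is 10,000.
Monte Carlo is selectable but excluded from the default method set — it is
by far the slowest estimator, and its positive bias shows on a coarse grid.

**Required splits (Study-2-style; `run_study2`).** Per design cell,
each replicate dataset contributes a pool of split correlations (pool size
20,000 — the pool defines the grand reference and its size is part of the
measured quantity; the finite-pool term meaningfully shifts the answer for
small samples, so the 30-participant cell keeps the full pool, while the
120-participant safe-splits sweep uses a 10,000 pool, where the finite-pool
term is ~2% at the observed crossing). Pools are turned into incrementally grown random-permutation
prefixes (sampling without replacement) at sizes 100, 200, …; the *required
splits* of a cell is the size after the largest one at which fewer than 95%
of subset estimates fall within 0.01 of the grand estimate. The criterion is
evaluated on the corrected (Olkin–Pratt + mirrored Spearman–Brown)
reliability scale — the quantity whose stability a user cares about; the
raw-correlation scale is selectable (`corrected` threshold semantics,
see `_stability_deviations`). Aggregators (mean, median, D) share the same
splits within a dataset.

**CI calibration (Study-3-style; `run_study3`).** Pairs of datasets sharing
participants and stimuli (score structure × true-score variability
{none: v=0, medium: v=4, large: v=8} × sample size {30, 60, 120, 240}; 256
trials each; all structures keep 8 stimuli per category and scale
repetitions). Per dataset: stratified permutation split-half with its
quantile CI; per pair: the predicted cross-dataset correlation with the
averaged CI versus the observed one. Reported: the fraction of observed
correlations strictly outside the CI (endpoints count as inside) and the
mean absolute prediction error binned by sample size × predicted-correlation
quartile. Pairs with an undefined (mixed-sign) prediction are excluded from
the analysis; negative predictions stay in the coverage count but fall
outside the error-table binning. Scaled profile: 20–30 pairs per cell,
600–1,000 splits (full scale: 200 pairs per cell, 10,000 splits).

## Numerical and performance choices

- Olkin–Pratt gamma ratios are computed with log-gammas (no overflow at any
  N); results are clamped to [−1, 1] because the truncated series can
  marginally overshoot at extreme r and tiny N. Accuracy against an
  arbitrary-precision oracle is ≤ 1e−10 over r ∈ [−0.99, 0.99],
  N ∈ [5, 200].
- Undefined split correlations (zero-variance or < 4 joint participants)
  are dropped from the aggregation; participants with an undefined score in
  one half are dropped from that split's correlation only. The `N` used by
  the Olkin–Pratt correction is the median joint count over splits.
- The vectorised engine (`BalancedDesign`) applies only to complete designs
  whose strata all share one even size; it draws uniform half-subsets per
  stratum, which is distributionally identical to the pair-split algorithm
  there (verified against the trial-level splitter). Three selection paths:
  enumerated half-subset lookup tables for small strata, an exact
  hypergeometric block decomposition for strata divisible by 8, and random
  key sorting otherwise. Value tables use float32 (memory-bound medians;
  RT precision requirements are far below single precision); all sums and
  variances accumulate in float64. Unbalanced data automatically fall back
  to the trial-level splitter.
- Medians of an even number of values are midpoints; the engine computes
  them by partial sorting with +inf padding where block selection leaves
  variable slot counts.

## Known limitations and open points

- The alpha pipeline requires complete participant × stimulus (× direction)
  cells; this is intrinsic to subscore-based alpha, not an implementation
  limit.
- The quantile-based CI describes split dispersion, not estimator sampling
  error; the CI-calibration harness quantifies the resulting mild
  under-coverage rather than correcting it. An analytic CI variant is not
  implemented.
- On noise-only data the corrected estimate of a single dataset scatters
  with SD ≈ 1.4/√n (the dataset's realized noise acts as a pseudo true
  score); more splits do not shrink this, only more participants do.
- Absolute required-splits values depend on the within-dataset dispersion
  of split correlations, which in turn depends on the trial-noise shape the
  generator assumes (Gaussian). Their monotone structure — fewer splits
  with more participants and higher reliability, medians needing the most —
  is robust to that choice; the printed values are not.
- Exclusions are applied before splitting; whether preprocessing should
  instead happen per half is an open methodological question, flagged in
  the data-model documentation.
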