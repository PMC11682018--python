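# Methods

## The measurement model

Smartphone EMA protocols for cognitive control present each task twice per
prompt (two blocks), so every scheduled occasion yields two parallel
indicators of the same score. `lstema` decomposes an indicator
`Y_itn` (block *i*, occasion *t*, person *n*) into a person trait at the
first occasion, a shared occasion factor, a linear time trend and
measurement error:

```
Y_itn  = ξ_1n + OCC_tn + β·time_t + ε_itn
OCC_1n = ζ_1n,   OCC_tn = φ·OCC_{t−1,n} + ζ_tn
```

Assumptions: Gaussian trait, innovations and errors, mutually independent;
equal innovation variance over occasions and equal error variance over
blocks and occasions; a fixed autoregressive slope φ shared by all
persons; both indicators load 1 on trait and occasion factor (parallel
blocks, no indicator intercepts). Trait change over the study is carried
by the fixed linear trend β alone; `time_t = t − 1` is the scheduled
prompt index, so μ_ξ is the trait level at the first prompt. The occasion
grid is materialized for every subject and unanswered prompts are treated
as missing completely at random: the likelihood marginalizes the missing
coordinates, no imputation.

The occasion process is *started*, `OCC_1 = ζ_1`, i.e. Var(OCC_t) =
Var(ζ)·(1−φ^2t)/(1−φ²) grows toward the stationary value; a
`stationary_init` flag switches to the stationary initialization for
sensitivity analyses.

## Estimation

The marginal likelihood integrates trait and occasion process exactly.
Two implementations coexist deliberately:

* `build_joint_covariance` / `loglik_direct` construct the full
  2T-dimensional Gaussian per subject from the model equations — the
  brute-force oracle;
* `loglik` runs a Kalman filter with state (ξ, OCC), vectorized over
  subjects. At a complete occasion the indicator pair is replaced by its
  mean (noise Var(ε)/2) plus an independent N(0, 2·Var(ε)) difference,
  which is an exact orthogonal split.

The test suite holds the two equal to 1e−8 on random instances, including
random missingness. Fitting maximizes the Kalman likelihood over
(μ_ξ, log Var(ξ), β, atanh φ, log Var(ζ), log Var(ε)) with L-BFGS-B from a
moment-based start plus two fixed perturbed starts; the best final
likelihood wins, so fits are deterministic given data. Standard errors
come from the observed information (central-difference Hessian on the
unconstrained scale, delta method back). The estimator is maximum
likelihood rather than Bayesian MCMC: the model and indices are
identical, fits are deterministic and take about a second at study
dimensions (70 subjects × 56 occasions), and an MCMC backend could be
added behind the same interface.

## Variance-decomposition indices

`compute_indices` reports, with Var(OCC) truncated at four lags
(Var(ζ)·(1+φ²+φ⁴+φ⁶+φ⁸)) and Var(Y) = Var(ξ) + Var(OCC) + Var(ε):

* Rel = (Var(ξ)+Var(OCC))/Var(Y), Con = Var(ξ)/Var(Y),
  Spe = Var(ζ)/Var(Y), Rel_within = Var(OCC)/(Var(OCC)+Var(ε)).

Because Var(OCC) ≥ Var(ζ), Con + Spe ≤ Rel with equality exactly at
φ = 0; the package reports both sides and asserts no identity between
them. The exact stationary occasion variance Var(ζ)/(1−φ²) is reported
alongside the truncated value, labeled, for sensitivity. All indices are
invariant to affine rescaling of the score's unit. A zero total variance
yields missing indices rather than an error.

## Scoring and screening

Scores per block: incongruent error rate and incongruent−congruent mean
correct RT difference (Stroop); no-go commission rate and mean correct go
RT (go/no-go). Restrictions: trials with a registered response faster
than 150 ms are invalid (strict `<`); RT aggregates use correct responses
only; a block-task score requires at least 10 valid trials in each of its
conditions, otherwise the score is missing with a cleared validity flag
(never an error). Conventions that the literature leaves open are
explicit switches: RT-Diff uses means, not medians; incongruent Stroop
trials with no response before the deadline count as errors by default
(`stroop_nonresponse_error=False` treats them as missing); go-trial
omissions contribute neither to the commission rate nor to RT. Practice
trials are expected to be absent or flagged `practice=1`, in which case
they are dropped.

Careless-responding screening applies four rules in order, with all
cut-offs frozen once per dataset and written into the report so every
removal is reconstructible: (1) prompts with mean questionnaire item time
< 1 s are removed entirely; (2) Stroop blocks whose longstring — longest
run of identical consecutive responses — exceeds the sample mean + 3 SD
remove that prompt's Stroop scores; (3) occasions whose task error rate
exceeds the per-task mean + 3 SD drop that task's scores; (4) subjects
with fewer than 5 complete assessments (both tasks valid on both blocks;
the definition is configurable and printed in the report) are flagged for
exclusion from model fitting. The 3-SD cuts for rules 2–3 are computed on
the post-rule-1 dataset, pooled across subjects; a per-subject variant
would be equally defensible, so the pooling choice is recorded in the
report. Note that a 3-SD cut on a continuous or max-run statistic flags
the extreme sample tail by construction, so "clean" data can legitimately
lose a fraction of a percent of blocks; exactness is only guaranteed for
planted violations against a controlled background, which is how the
tests exercise it.

## Reliability of change

`estimate_components` fits `Y = μ + person + person×occasion + residual`
by REML. The implementation reduces each subject to cell means and
within-cell sums of squares and inverts the person-level covariance by a
rank-one Sherman–Morrison identity, so a fit costs microseconds and the
per-trial-count curves stay cheap; an expected-mean-squares
method-of-moments solution (`method="mom"`) is available for balanced
complete data and agrees with REML there (and with statsmodels MixedLM on
unbalanced data, which the tests verify). Negative method-of-moments
components are truncated at zero, with the raw values kept in the result.
R_c = σ²_{p·t}/(σ²_{p·t} + σ²_ε/m) with m the number of parallel blocks.

Curves: `rc_by_trialcount` rescores blocks from the first n trials of
each condition in presentation order (n = step, 2·step, …) and
re-estimates the components per n — the literal reading of "considering
increasing numbers of trials"; no minimum-trial rule applies to subset
scores, so denominators equal n. Each score's curve extends to the trial
count of the conditions that feed it (go trials for go RT, no-go trials
for the commission rate, both Stroop conditions for RT-Diff).
`rc_by_day` estimates the components within each study day, skipping days
with fewer than two occasions per subject.

## Validity and context

`within_between_corr` decomposes an association into the Pearson
correlation of per-subject means (between; unweighted by observation
count) and the Pearson correlation of person-mean-centered observations
pooled over prompts (within; subjects need ≥ 2 paired observations to
contribute). Two-sided p-values use t-distributions with
n_subjects − 2 and n_observations − n_subjects − 1 degrees of freedom.
P-values are reported raw, without multiplicity correction.

`fit_context_model` regresses a task score on beep number (categorical,
beep 1 reference), social context, location and tiredness with a random
intercept per subject (statsmodels MixedLM, REML). Continuous variables
are first within-subject-centered and then divided by the pooled SD of
the centered values — the only reading of "grand-mean standardized" that
yields unit variance after centering, and it is recorded in the result
metadata. The explained within-subject variance is var(Xβ)/(var(Xβ) +
residual variance) on the within-centered outcome, a marginal-R²
construction; since centering removes the between-person variance the
random-intercept variance is near zero, and if the mixed fit degenerates
the model falls back to OLS, its exact limit.

## Synthetic data generator

Two modes share one latent model per score. *Score level* emits the two
block indicators directly from the model equations — the mode used for
parameter-recovery experiments, where exactness matters. *Trial level*
emits raw trials whose aggregates track the latent states: error
probabilities are the inverse logit of the latent state (so error-rate
latents live on the logit scale), congruent Stroop RTs are lognormal
around a subject-specific base with the latent interference added to
incongruent trials, and go RTs are normal around the latent go-RT state —
so expected block aggregates equal the latent states at the configured
trial counts.

Defaults encode the main-protocol conditions: 70 subjects, 4 prompts/day
× 14 days (T = 56), 51% compliance (missing completely at random per
prompt), Stroop blocks of 24 congruent + 24 incongruent trials (1200 ms
deadline), go/no-go blocks of 80 go + 20 no-go trials (650 ms deadline).
The per-score latent parameters are derived from the protocol's reported
index pattern and between-person spreads: for each score the total
block-level variance is split so that consistency dominates for the
Stroop scores (Con ≈ .51/.38, Spe ≈ .11/.01) and occasion specificity is
substantial for go/no-go (Spe ≈ .16/.37), with φ backed out of the gap
between Rel − Con and Spe (0.16, 0.76, 0.05, 0.05 for stroop_er,
stroop_rtdiff, gng_er, gng_rt). The two error-rate latents are coupled
(trait correlation 0.57, innovation correlation 0.40) so the tasks show
convergent validity at both levels; context covariates shift the emitted
occasion states with coefficients matching the reported standardized
effects (e.g. higher go/no-go ER at beeps 3–4, lower Stroop ER when
tired); a self-report composite couples to the go/no-go ER latent
(between 0.30, within 0.05).

How block-level error variance splits between trial-sampling noise and
block-specific disturbances is not identified by any block-level
analysis, so the generator treats it as a knob: by default it adds
per-block latent noise of variance max(Var(ε) − expected trial-sampling
variance, 0), making block aggregates carry approximately the configured
error variance. For the error rates at realistic trial counts the
binomial floor alone exceeds the target (e.g. p(1−p)/24 on the proportion
scale), the adjustment floors at zero, and observed-scale Stroop indices
sit below the configured logit-scale decomposition — the same test-length
attenuation that the R_c-versus-trial-count curves quantify.

Reproducibility: one RNG stream per dataset keyed by the seed, with a
sub-stream per subject, so output is byte-identical across runs and
adding subjects never perturbs earlier subjects' draws.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: circadian RT structure beyond beep effects,
practice curvature beyond the linear trend, post-error slowing,
RT–accuracy trade-offs, device timing jitter, and informative
missingness (compliance is independent of state).

## Numerical choices and test dimensions

Variances are optimized on the log scale and φ through tanh, so
constraints hold by construction; near-zero variance estimates are
reported as found (the REML components are floored at a 1e−10 relative
threshold). Screening treats a sample SD below 1e−10 (relative) as
degenerate — zero up to float cancellation — and then excludes nothing,
with a warning. Likelihood oracle agreement is asserted at 1e−8; index
closed forms at 1e−12.

Simulation-based checks use: 100 replications at 70 subjects × 56
occasions for parameter recovery (median estimates within 10% per
variance, φ within 0.05, indices within 0.03 — at these dimensions the
per-replication sampling SD of the trait variance is ≈ 0.18, so medians
across replications, not per-replication errors, are the meaningful
recovery criterion for that parameter); 200 subjects × 20 occasions for
variance-component recovery with moment-matched effect draws; 50
replications of 14-day studies for the per-day R_c flatness check
(Kendall trend test, null retained in ≥ 90%). The end-to-end pipeline and
examples run on 6–40 subjects to stay fast; dimensions are stated in each
test.

## Known limitations

Maximum-likelihood variance estimates at N = 70 subjects carry ≈ 17%
sampling error on the trait variance — single-study indices inherit that
uncertainty, which is why the fitted SEs matter. The model assumes equal
error variances across blocks and fixed φ across persons; violations bias
the decomposition and are not currently testable inside the package.
Logit-scale error-rate latents mean observed-proportion-scale indices are
attenuated relative to the latent configuration at low trial counts. The
screening rules are the protocol's fixed 3-SD heuristics, not
model-based careless-responding detection.
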