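# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices and the known limitations of the package. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Matched dataset construction

Self-reports are weekly, clinician assessments roughly monthly, so analyses
run on a matched dataset. Concurrent matching is *unique nearest-first*:
within each patient, all (assessment, report) pairs with |Δ| ≤ 3 days are
enumerated, sorted by (|Δ| ascending, report-before-assessment preferred,
earlier assessment date, earlier report date) and accepted greedily while
both endpoints are unused. The tie-break order is a package decision fixed
for reproducibility: "nearest and unique" does not determine ties, and a
globally optimal assignment is not claimed — greedy-by-distance is the
direct reading of a nearest-match rule. Lagged reports (windows 4–10 and
11–17 days before the assessment, inclusive) are attached to the report
closest to the window centre (7 / 14 days back), ties resolved to the more
recent report, and are *not* consumed: a report that is one record's
concurrent match may be another record's lag, because the uniqueness
requirement concerns concurrent matching only.

Degenerate inputs: assessments with no eligible report are counted in the
`MatchingReport`, never silently erased; duplicate (patient, date) rows are
a hard error because the matcher assumes uniqueness; missing scales and
questionnaires are never imputed.

## Internal structure

The PCA is an eigen-decomposition of the sample covariance matrix of the
raw 0–4 item scores — not the correlation matrix. This choice is the one
consequential reverse-engineering decision in the package: the published
component SD row sums in squares to ≈ 3.77, far from the value 10 that a
correlation-matrix PCA of ten standardised items must produce, so the
original analysis used raw covariances. It should be revisited if item
variances are ever rescaled. Components are ordered by decreasing SD, and
each loading column's sign is fixed so its largest-magnitude entry is
positive (PCA signs are otherwise arbitrary and would break test
reproducibility). All matched records enter the PCA; the within-patient
dependence this induces is acknowledged, not corrected. Zero-variance
items are reported and the decomposition still runs.

Cronbach α uses the standard formula `k/(k−1) · (1 − Σ var(itemᵢ) /
var(total))` with n−1 variances, over the fixed item groups Q1–4, Q5–8,
Q9–10 and the combined sets Q1–4+9–10 and Q5–8+9–10.

The response rate is filled reports divided by weeks in study, where
`weeks_in_study = floor((exit − enrollment)/7) + 1`: a patient enrolled for
any part of a week owes one report. The ratio is deliberately not capped at
1 (extra reports are possible).

## Mixed-effects models

**Gaussian LME (convergent validity).** `y = Xβ + Z uᵢ + ε` with patient
random intercept and slope (full 2×2 covariance by default), fitted by
REML. The implementation profiles the fixed effects and residual variance
out of the REML criterion and evaluates it from per-cluster sufficient
statistics (cluster Gram matrices), leaving a 1–3 parameter optimisation
over the scaled random-effect Cholesky factor (L-BFGS-B on a smooth
criterion). This makes one fit cost a few milliseconds, which is what makes
the two-level case bootstrap (tens of thousands of refits) and the
Monte-Carlo recovery suites affordable. The implementation is cross-checked
in the test suite against statsmodels `MixedLM` (REML) to 1e-3 on the fixed
effects. On convergence failure the random structure falls back full →
diagonal → intercept-only, each step logged and the structure used
recorded. Single-cluster data and zero-variance predictors are rejected.
For the single-predictor model the criterion kernel is JIT-compiled, and
the case bootstrap of the LME slope has a dedicated path
(`bootstrap_lme_slope`) that rebuilds the per-cluster Gram sums for each
resample and runs the whole resample-refit loop compiled; a test checks
its resample distribution against the generic DataFrame-level bootstrap of
the same statistic.

**Logistic mixed model (relapse detection).** `logit P(y=1) = Xβ + b₀ᵢ`
fitted by maximising the Laplace approximation of the marginal likelihood;
the inner per-cluster modes are found by Newton iterations (vectorised
across clusters for the random-intercept case), the outer optimisation runs
L-BFGS-B over (β, log σ) with the random-effect SD bounded in log-space.
Development cross-checks against lme4's `glmer` agreed to ~0.01 on fixed
effects and RE SD for a random-intercept model; one such fit is frozen as a
test expectation. Held-out rows of patients seen in training are scored
with that patient's posterior mode (the grouped holdout design puts every
patient in both sets); unseen patients score with a zero random effect.

*Separation*: when the unpenalised fit diverges (non-finite parameters or
|β| > 25), the model refits with a weak ridge penalty (1e-4 per
observation on the non-intercept coefficients), flags `separation_` and
logs the event; predicted orderings remain intact so training AUROC is
unaffected. *Random slopes* exist behind a flag but are weakly identified
at small cluster sizes — under within-cluster separation the Laplace
surface is nearly flat towards infinite slope variance (reference
implementations show the same boundary degeneracy), so the Cholesky
entries are bounded and the default model ladder uses random intercepts
only, which is also the structure of both best reported models.

**Case bootstrap.** Patients are resampled with replacement, then
observations within each drawn patient; a patient drawn twice contributes
two clusters under fresh labels (required for the mixed model to stay
well-posed). The two-sided p-value is the sign-crossing rule with +1
smoothing, `p = 2·min((1+#{θ*≤0})/(B+1), (1+#{θ*≥0})/(B+1))` capped at 1;
the CI is the percentile 95% interval. The source analysis does not state
how its bootstrap p-values were computed; this rule is the package's
documented choice and its size is verified by simulation (nominal-rate
rejection under a null generator). No Wald or Satterthwaite inference is
provided — the bootstrap is the single inferential route. Resample
statistics may fail (non-convergence); failures above 10% abort with
diagnostics.

**Weighted group correlation.** Per-patient Pearson r, pooled with weights
∝ nᵢ. Patients need ≥ 3 observations and nonzero variance in both
variables (a two-point patient always has |r| = 1, and zero variance makes
r undefined); exclusions are counted and reported. The threshold of 3 is a
package decision.

## Relapse detection and validation

Relapse is scale-based: MADRS ≥ 15 (depressive) or YMRS ≥ 15 (manic);
below threshold is the interepisode state. Only patients with both relapse
and nonrelapse records enter a detection cohort. Feature rows are
complete-case per model specification (a spec using the lag-1 subscore
drops rows without a lag-1 report; counts are logged).

The grouped 70:30 split assigns, per patient with nᵢ ≥ 2 records,
`round(0.7·nᵢ)` records to training, clamped so both sets are nonempty;
single-record patients go to training (their random-effect mode must be
estimable). The decision threshold is the smallest candidate — midpoints
of adjacent distinct negative-class training probabilities plus sentinels —
whose training specificity (negatives strictly below t; ties at t predict
relapse) reaches the 90% target, so training specificity ≥ 0.90 holds in
every repetition by construction. AUROC is the rank statistic with half
credit for ties, verified against all-pairs enumeration.

The dominance walk compares adjacent ladder models on shared split plans
built over the full record set (each model then restricted to its
complete-case rows, so both see the same patient-level partition). The
comparison metric is test AUROC alone — threshold-free, hence the cleanest
single criterion where "performance measures" is otherwise unspecified —
and ties count as "not better", conservative toward the simpler model. The
full metric table is returned so the rule is auditable. The default
ladders reconstruct the published narrative (depression: current-week
DEPNSP → +1-week lag → +2-week lag, random intercept, preceded by a
no-random-effect model; mania: current-week MAN → +1-week lag): the exact
original candidate list is not available, so the ladder is configurable.

Splits whose training set lacks a class are redrawn (≤ 10 times, then
counted as failed) — whether the original 999 repetitions redrew such
splits is unstated.

## Synthetic cohort generator

The generator's defaults are the study conditions and are not tuned per
test:

| parameter | default | rationale |
|---|---|---|
| patients | 99 | reported cohort size |
| follow-up weeks | trunc-normal(108, 38), min 8 | reported 754 (SD 266) days; the distribution *shape* is a choice — only mean/SD are reported |
| assessment cadence | every 4th week, jitter U{−3..+3} days | monthly phone interviews |
| weekly transitions | stay-euthymic .95, enter-dep .035, enter-mania .015, stay-episode .85 | episodic course with ~6–7-week episodes; yields relapse shares near the reported 17.4% / 9.9% among matched detection-cohort assessments |
| latent severity | episode mean 2.5 + AR(1) (φ=.7, innov SD .357) | smooth within-episode course, stationary residual SD 0.5 |
| clinician map | total = gain 8 · severity + N(0, 3), clipped | places episode MADRS near 20, euthymic near 0 |
| item model | dep items load (1,0), manic (0,1), nonspecific (.8,.3); thresholds (.5,1.25,2.0,2.75); item noise SD .6 | nonspecific items track depression more than mania, as observed |
| adherence | Beta(mean .78, SD .183), MCAR per week | reported 78.1% (SD 18.3%) response rate |

When item-level clinician scores are generated (the default), each MADRS
item gets gain 8/10 and noise SD 3/√10 (YMRS: 8/11, 3/√11) and the total
is the item sum, so the type invariant (items sum to the total) holds while
the total keeps the configured gain and noise scale. Mixed states are not
modelled (relapse labels are per-pole); a patient can satisfy both
thresholds only through noise, which is allowed, not prevented. Clinician
noise is Gaussian and independent across visits — the simplest model
supporting LME recovery. Missingness is completely at random per week (no
mechanism is reported); a state-dependent extension exists but is off by
default. Infeasible adherence SDs are shrunk to 0.99× the feasible maximum
with a logged warning.

**Implied true slope.** The population slope of the clinician total on the
self-report subscore is computed deterministically from the generator
parameters by Gauss–Hermite quadrature over the stationary latent mixture
(Markov-chain stationary distribution × AR(1) stationary residual):
ordinal item moments are exact threshold-probability sums, the clipped
clinician mean uses the doubly-truncated-normal closed form, and only the
clinician-item rounding is neglected. This gives recovery tests an exact
target instead of a re-simulated one; a test checks the quadrature against
a pooled empirical regression on a large cohort.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: reporting biased by symptom state (adherence is
MCAR), impaired insight during mania, instrument saturation at high
severity (the latent-to-item map is linear before thresholding), mixed
episodes, medication effects, and clinician rating drift. Synthetic
cohorts are also cleaner than the real data: convergent correlations and
detection AUROCs come out higher than the reported ones, so those
magnitudes are generator properties, not claims about the instrument.

## Problem sizes used by the checks

Monte-Carlo suites are sized to what the analyses need, not more: slope
recovery uses 100 cohorts of ~50 patients × ~60 weeks with bootstrap
B = 500 (CI coverage target ≥ 90/100; logistic sign recovery ≥ 95/100);
bootstrap size uses 200 null cohorts of 30 patients × ~40 weeks at B = 500
(rejection in [0.02, 0.09] at the 5% level); specificity calibration uses
a 60-patient cohort with 150 holdout repetitions. `scripts/acceptance.py`
runs the full pipeline at the study's 99 patients with B = 2000 and 200
holdout repetitions. The package defaults remain B = 10,000 and 999
repetitions.

## Known limitations

* Random-slope logistic models are weakly identified on small clusters
  (see above); results with `random_structure="slope"` should be treated
  as exploratory.
* The PCA covariance-matrix choice is inferred, not stated, in the source
  analysis (see Internal structure).
* Bootstrap p-values below 2/(B+1) are not resolvable by construction.
* The matcher's tie-breaks and the lag-window non-uniqueness are fixed
  conventions where the original procedure is unstated; both are local to
  `asertval.matching` and configurable in principle.
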