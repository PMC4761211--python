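# Methods

This note documents the statistical machinery in `consig`: the models and
conventions, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical details a user
reproducing or extending the analyses will need.

## Survival core

**Kaplan–Meier.** Standard product-limit estimator. Observations censored
exactly at an event time are counted as at risk through that event time
(the `time >= t` convention). Curves are emitted as step-function
coordinates (time, survival, at-risk, events), not rendered plots.

**Log-rank.** Two-group observed-minus-expected chi-square with 1 df and
the hypergeometric variance, pooled over event times. With zero events
the statistic is 0/0; it is returned as 0 with p = 1 and a warning rather
than an error, because screens legitimately encounter all-censored
subsets.

**Cox proportional hazards.** Newton–Raphson maximization of the partial
likelihood, with Efron tie handling by default and Breslow selectable
(they coincide when no event times tie — a property the tests exercise).
Options: stratification (separate baseline hazards, shared coefficients),
any number of covariates. Numerics: covariates are standardized
internally for conditioning (results are reported on the original scale,
which the scaling-equivariance tests pin down); step-halving guarantees
ascent; convergence requires the max coefficient update to fall below
1e-9 within 100 iterations. Monotone likelihoods (perfect separation) are
detected — a coefficient drifting past 20 on the standardized scale, or a
singular information matrix with a large drifting coefficient — and
raised as `SeparationError` naming the covariate. Constant covariates
(overall or within every stratum) are rejected up front. Confidence
intervals are 95% Wald intervals `exp(coef ± z·se)`; the score test at
β = 0 is also computed, since for a single binary covariate it equals the
log-rank statistic (an exact equivalence with untied times; the tests
verify it to 1e-8).

**Two-group fast path.** A probe screen runs tens of thousands of
median-split tests against one cohort's fixed outcomes. For a binary
covariate the partial likelihood depends on the data only through
per-event-time at-risk/event counts in the high group, so `consig`
evaluates whole label matrices at once (`_twogroup`): cumulative-sum
tabulation, then a vectorized scalar-Newton per probe. The tests enforce
agreement with the general implementation to 1e-8; probes with monotone
likelihood get HR 0 or ∞, direction from the score sign, and their
log-rank p.

**Weighted aggregation.** Per-cohort hazard ratios are combined as an
arithmetic mean weighted by cohort size, `Σ w·HR / Σ w`. This is a fixed
convention of the pipeline (not an inverse-variance meta-analysis);
full precision is kept in files and a 1-decimal rounding is added for
reporting.

## Consensus selection

Each probe is dichotomized at its within-cohort median, high = strictly
above, ties going low. The vote selects a probe when (a) the sign of its
unrounded two-group log-HR is identical and non-zero in all cohorts and
(b) its log-rank p is below α in at least `min_significant` cohorts. The
log-rank p feeds the vote (it is the designated significance test for the
two groups); the Cox Wald p is retained in the grid for reporting.
Probes not measured in every cohort are dropped (with a log message)
rather than imputed; an incomplete grid is an error listing the missing
cells.

**Error calculus.** Under the null, per-cohort rejections are independent
Bernoulli(α), so the per-probe rate of the significance vote is the
binomial tail `P(X ≥ m)`, X ~ B(n, α) — 1.05 × 10⁻⁷ for 6-of-7 at
α = 0.05. The direction requirement multiplies in `P(all n signs equal)
= 2^(1−n)` under an independent symmetric-sign null; because the sign and
the magnitude of a symmetric two-sided test statistic are independent
under the null, the product is exact for that model. Family-wise bounds
are Bonferroni, `min(1, n_tests × rate)`; the `type1` CLI prints the
bound both for the binomial-tail rate and for the cruder `α^m` per-probe
rate, since both conventions appear in practice. `monte_carlo_type1`
checks the calculus empirically on freshly simulated null cohorts and
refuses criteria under which fewer than 10 hits are expected (the
estimate would be uninformative); it returns a Wilson binomial CI.

## Scoring and stratification

A signature score is the per-sample unweighted mean of log2 expression
over the signature probes present in the matrix; absent probes are
skipped with a warning and surfaced in `n_probes_used` (needed when a
signature defined on one platform is applied to another), zero overlap is
an error. Matrices flagged linear-scale are transformed `log2(x + 1)`
first; RNA-seq-style inputs should additionally be passed through
`normalize_by_sample_mean` (divide each sample by its own mean gene
expression) before scoring, which removes per-sample scale factors
exactly. Stratification cuts the score at empirical quantiles
(`numpy.quantile`, linear interpolation) at k/n for n ∈ {2, 4}; a score
equal to a cut point goes to the lower group, so the two-group case
reproduces the probe-level "high iff strictly above the median" rule
exactly (asserted in code). Group 1 is always the lowest-score group.

## Evaluation

All per-cohort fits run on the identical included-sample set (the
intersection of expression and clinical samples). Four analyses per
cohort: median-split two-group Cox + log-rank + KM pair; continuous-score
Cox (HR per unit of score, i.e. per doubling when the score is a mean
log2 expression); multivariate Cox with the median-split group indicator,
a stage II-vs-I indicator, and age in years, stratified by gender; and
quartile KM curves. Design choices here: stage enters as a binary I/II
indicator (sub-stages are not modelled); gender is a stratum rather than
a covariate; the score enters the multivariate model as the group
indicator by default so the adjusted HR is comparable to the unadjusted
median-split HR (`multivariate_continuous=True` switches to the raw
score). A multivariate fit whose covariate is constant in a cohort is
skipped with a warning instead of failing the whole evaluation. Endpoint
semantics (OS vs RFS) are a per-cohort metadata label carried in the
manifest; the code never mixes endpoints inside one fit.

Inclusion filtering keeps stages in a configurable set (default {I, II})
and optionally drops rows flagged `treated`; `censor_at_treatment`
implements follow-up censoring at treatment initiation (time :=
treatment_start, event := 0 for rows treated before their observed time),
which creates a treatment-unexposed subcohort without excluding patients.

## Synthetic cohorts

The generator produces the structure the analysis assumes, not a
microarray emulator:

* **Expression.** Prognostic probes: equicorrelated multivariate normal
  (pairwise correlation ρ, default 0.9, matching the strong mutual
  correlation of proliferation/CIN-type signature genes). Null probes:
  independent standard normal. Values are on a log2-like scale and used
  as-is downstream.
* **Survival.** Exponential proportional hazards: event time ~
  Exp(h₀·exp(Σ βᵢzᵢ)) with zᵢ the within-cohort standardized expression
  of prognostic probe i. Censoring = min(Exp(c), admin cutoff).
  Defaults: h₀ = 0.01/month, c = 0.005/month, cutoff = 120 months, giving
  a median survival around five years and ~40% censoring. These censoring
  defaults are documented choices, not estimates from any dataset.
* **Effect sizes.** `log_hazard_effects` are conditional log HRs per SD
  per probe. The default (0.158 per probe) is chosen so that each probe's
  *marginal* per-SD hazard ratio in the default 7-probe ρ = 0.9 block is
  ≈ 2.75 (marginal log HR = β(1 + (m−1)ρ)), which puts the dichotomized
  two-group HRs in the upper part of the 1.5–4.5 range that strongly
  prognostic probes display in cohorts of these sizes.
* **Covariates.** Stage ~ Bernoulli(0.3) for II, age ~ N(65, 10²),
  gender ~ Bernoulli(0.5), all independent of expression — they exist to
  exercise the adjusted fits, not to model confounding.
* **Determinism.** One global seed drives `SeedSequence.spawn`
  per-cohort substreams (expression and survival separately), so adding
  cohorts never perturbs earlier ones and identical (config, seed) is
  bit-reproducible.

Default cohort sizes are (51, 32, 207, 84, 204, 35, 127) — seven cohorts
of realistic early-stage sizes spanning small (32) to large (207).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: probe-level microarray artifacts (RNA
degradation, 3'/5' bias, background), RNA-seq count noise, non-normal
expression marginals, confounding between expression and clinical
covariates, non-proportional hazards, informative censoring, and
cross-cohort platform/batch heterogeneity (the common-effect model is the
default; a per-cohort effect table is accepted but not defaulted).

## Problem sizes used in the checked experiments

The automated checks run at desk scale, chosen as the smallest sizes at
which the statistical statements are sharp: oracle comparisons on 100
random 40-sample datasets (log-rank vs lifelines; Cox vs R
`survival::coxph` at eps = 1e-12) plus 8-observation brute-force
maximizations; null calibration on 1,000 single-probe replicates
(Kolmogorov–Smirnov on the p distribution) and 20,000 vectorized null
probes against the analytic rate at relaxed 2-of-3 criteria; recovery on
seven cohorts with the default sizes, 7 planted probes among 10,000
nulls, 20 replicates; and dichotomization attenuation measured against a
100,000-sample Monte-Carlo oracle rather than assumed.

## Known limitations

* The Cox implementation covers right-censored data with fixed
  covariates; no time-varying covariates, penalization, robust variance,
  or proportionality diagnostics.
* The weighted-mean HR is a reporting convention; it has no variance and
  should not be read as a meta-analytic pooled estimate.
* The binomial error calculus assumes independent cohorts; overlapping
  patients would inflate the real error rate.
* Quantile stratification requires enough distinct scores; heavily tied
  scores (e.g. low-resolution data) raise rather than silently merging
  groups.
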