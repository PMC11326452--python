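# Methods

## Model

The outcome is ordinal with categories j = 1..J (here J = 3: mild <
moderate < severe). Given a reference-coded design row x (one indicator per
non-reference level of each categorical predictor), the cumulative-logit
proportional-odds model is

    logit P(Y ≤ j | x) = θ_j − xᵀβ,    θ_1 < … < θ_{J−1}.

Assumptions: proportional odds (one slope vector shared across cut-points),
independent records, and categorical predictors entering only as main
effects. The sign convention puts positive β on the side of *more severe*
outcomes, so exp(β) reads directly as the odds ratio of worse outcome per
level versus its reference.

All likelihood quantities are stored as negative log-likelihoods (nats).
The likelihood-ratio statistic against the intercept-only null is
χ² = 2(nll_null − nll_final) on df = k (the slope count); AIC = 2·nll + 2p
and BIC = 2·nll + p·ln n count every free parameter, cut-points included
(p = J − 1 + k). McFadden = 1 − nll_final/nll_null; Cox–Snell =
1 − exp(−2ΔLL/n); Nagelkerke rescales Cox–Snell by its attainable maximum
1 − exp(−2·nll_null/n).

## Estimation

Fitting maximises the likelihood with L-BFGS-B on an unconstrained
reparameterisation — the first cut-point plus log-increments — which makes
cut-point monotonicity automatic. Gradients are analytic; the
log-probability of each observation and the density-to-probability ratios
in the gradient are evaluated in log space, so observations deep in a tail
keep finite values instead of underflowing. Initialisation is the empirical
cumulative logits with zero slopes (for the intercept-only model this *is*
the MLE, so that case is exact); bootstrap refits warm-start from the
full-data solution. Defaults: gradient tolerance 1e−8, relative objective
tolerance 1e−14, 500 iterations.

`FitResult.converged` is deliberately strict: it requires a small gradient,
i.e. a genuine interior optimum. Separated data — where some coefficient's
MLE is infinite — stall with the gradient still large and are flagged, with
`diagnostics` recording the optimizer state.

Standard errors come from the inverse of the observed information,
differentiated numerically (central differences, step 1e−5 scaled per
coordinate) in the natural (θ, β) parameterisation at the optimum. Wald
p-values are two-sided normal with no multiplicity adjustment; the
coefficient table exposes estimate, SE, z, p and exp(estimate), with
cut-point rows labelled `"Mild|moderate"`-style.

## Bootstrap

The bootstrap resamples the N records uniformly with replacement, refits
per replicate, and aggregates: estimate = across-replicate mean; SE per
`se_mode`. Replicate RNG substreams are spawned from the seed
(`numpy.random.SeedSequence`), so results are independent of evaluation
order and bit-reproducible.

**Degenerate resamples.** The design matrix is encoded once from the full
data and shared across replicates so coefficients stay comparable. A
resample that fails to re-observe some outcome category or predictor level
is redrawn from the replicate's own substream (cap: 100 redraws, then an
error).

**Separation in replicates.** With n = 30 records and 14 parameters, most
30-row resamples are perfectly separated — the replicate MLE does not
exist. This is structural (it occurs even when the true effects are zero)
and cannot be removed by moderating the generator. Replicate refits are
therefore box-constrained (|parameter| ≤ 15 on the unconstrained scale,
`replicate_bound`) with a bounded iteration budget (100,
`replicate_maxiter`): a separated coefficient pegs at the box and the
replicate still returns finite values. This mirrors how fixed-budget
ordinal-regression software behaves on separated resamples, and it is the
mechanism that makes small-sample coefficient bootstraps of this kind
produce finite summaries at all. Beyond logit 15 a level's fitted
probabilities are within 3e−7 of 0/1, so the box does not bind for any
realistically estimable effect. Pegged/stalled replicates are retained by
default (`include_stalled=True`); setting it to `False` restricts
aggregation to replicates with a strict interior optimum, which on
separated small samples can leave very few (or zero) usable replicates.
Consequence to keep in mind: when separation is common, the replicate
spread partly reflects the box and budget, not only sampling variability —
bootstrap summaries of such data are descriptive, not confidence-calibrated.

**SE conventions.** `standard` (default) is the conventional bootstrap SE:
the across-replicate standard deviation (ddof = 1), which converges to a
constant as B grows and, on well-identified data, tracks the true sampling
SD of the MLE (checked at n = 200 against 500 independent cohorts).
`replicate_mean` divides by √B — the standard error of the replicate mean. It
shrinks like 1/√B, so z-statistics grow and p-values fall as more
replicates are drawn; it quantifies Monte-Carlo precision of the bootstrap
average, not estimator uncertainty, and is provided for reproducing
replication-sweep layouts that report exactly that behaviour. 95%
percentile intervals are attached in both modes.

**Aggregate likelihoods** (`nll_mode`): `mean` (default) — mean
per-replicate NLL, with the intercept-only counterpart computed in closed
form per resample; `at_aggregate` — NLL of the averaged coefficients on the
original data; `replication_style` — B × (mean NLL)/N, an aggregation whose
magnitude grows linearly in B, with BIC then using n_effective = B. The
comparison table records which convention produced each column. The
single-number "Standard error" row in the comparison layout is the mean SE
across coefficient rows (the layout's source never defines it; this is the
package's choice).

## Synthetic cohorts

`simulate_dataset` draws each predictor independently from configurable
level probabilities and the outcome from the model's category
probabilities — i.e. data generated exactly under the assumptions the
estimator makes. What it does *not* emulate about real clinical data:
correlated predictors, missingness, misclassification, or any violation of
proportional odds. Passing tests therefore demonstrate that the machinery
is correct and calibrated under the model, not that the model suits any
particular dataset.

`make_study_like_config` is the study-like preset: n = 30, the five-
predictor coding scheme with uniform level frequencies (no mass on the
never-observed "after meal" brushing frequency, so the encoded design has
k = 12 slope columns), cut-points (−1.5, 0.5) giving roughly (0.33, 0.38,
0.29) expected category shares, and true slopes in [−1.25, 1.25] whose
signs follow the study's direction of association (harsher brushes and
abrasive paste raise severity; gentler technique lowers it). Magnitudes are
deliberately moderate: they keep the n = 30 full-data fit convergent for
~90% of seeds while still producing the large Wald SEs (typically > 1)
characteristic of 14-parameter fits on 30 records. Effects at the strength
the published odds ratios imply (|β| up to ~9) put even the full-data fit
into separation; that regime is available by scaling the preset's slopes
up, but is not the default.

`parameter_recovery_experiment` repeatedly simulates at a chosen size,
refits, and scores per-coefficient bias, RMSE and Wald-CI coverage,
redrawing (and counting) unfittable cohorts; optionally it compares a
standard-mode bootstrap SE against the empirical SD across cohorts.

## Problem sizes used in the checks

Validation experiments run on a compact two-predictor, three-category
configuration (k = 4) rather than the full coding scheme — the claims
checked (consistency, coverage, bootstrap calibration, test calibration)
do not depend on the schema: 200 cohorts of n = 2000 for recovery and
coverage; 500 cohorts of n = 200 plus one B = 1000 bootstrap for SE
calibration; 500 null cohorts of n = 200 for type-I error. The SE scaling
law is checked on the study-like n = 30 cohort across
B ∈ {100, 300, 500, 1000}.

## Known limitations

* Proportional odds is assumed, not tested; no partial/non-proportional
  odds, probit/cloglog links, interactions, continuous covariates, weights,
  or random effects.
* Wald inference at n = 30 with 14 parameters is asymptotic in name only;
  the package reports it because the reporting format requires it, and the
  validation battery quantifies when it becomes trustworthy (n in the
  hundreds for the small schema).
* On separated data the bootstrap summaries depend on the replicate box and
  iteration budget (see above); percentile intervals and the convergence
  diagnostics should be read together.
* BCa/studentized intervals, stratified resampling and parallel execution
  are out of scope.
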