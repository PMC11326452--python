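# polrboot

Bootstrap-enhanced proportional-odds regression for small ordinal health
datasets — built around a tooth-sensitivity (dentin hypersensitivity) case
study: ~30 patients, a three-level severity outcome (mild < moderate <
severe), and five categorical risk factors (age group, toothpaste type,
toothbrush type, brushing frequency, brushing method).

## The model

For an ordered outcome with categories j = 1..J and reference-coded
predictors x, the cumulative-logit (proportional-odds) model is

    logit P(Y ≤ j | x) = θ_j − xᵀβ,   j = 1..J−1,

with strictly increasing cut-points θ and one shared slope vector β, so
exp(β_k) is the odds ratio of a *more severe* outcome for level k versus
its reference. The package provides:

* maximum-likelihood fitting with analytic gradients and Wald inference
  (`polr_core`),
* the model-fit battery — likelihood-ratio χ², AIC/BIC, McFadden,
  Cox–Snell and Nagelkerke pseudo-R² (`fit_metrics`),
* a bootstrap engine that resamples records with replacement, refits per
  replicate, and aggregates coefficient distributions across replicate
  counts B ∈ {100, 300, 500, 1000} (`bootstrap_engine`),
* a synthetic-cohort generator with known ground truth (`synthetic_data`),
  plus schema/IO utilities (`data_model`) and a CLI/pipeline (`cli_report`).

Two standard-error conventions are implemented. `standard` is the
conventional bootstrap SE (the across-replicate standard deviation, which
stabilises as B grows); `replicate_mean` divides it by √B — the SE of the replicate
*mean*, which shrinks like 1/√B and drives ever-smaller p-values as B
rises. The second is kept behind an explicit flag because it measures the
precision of the bootstrap average, not the sampling variability of the
estimator; see `docs/methods.md`.

## Worked example

```sh
python analysis/01_simulate_cohort.py          # 30-patient synthetic cohort
python analysis/02_fit_ordinal_model.py        # single proportional-odds fit
python analysis/03_bootstrap_sweep.py --replication-style
python analysis/04_validation_experiments.py   # recovery / calibration checks
```

The fit step prints (seed 0):

```
n = 30, slope columns k = 12
NLL: intercept-only 32.281, final 25.425; LR chi-square 13.713 on 12 df (p = 0.3194)
AIC 78.849, BIC 98.466, McFadden 0.212, Cox-Snell 0.367, Nagelkerke 0.415
```

`k = 12` is the design's slope count (12 non-reference levels across the
five predictors); the LR χ² compares the final model to the intercept-only
null; at n = 30 with 14 free parameters individual Wald SEs are large
(~1.2–2.3 on the logit scale), which is exactly the small-sample regime the
bootstrap sweep probes. The sweep then prints the comparison battery per
replicate count, and the validation script reports (seed 0): mean absolute
bias 0.008 at n = 2000, 95% Wald-CI coverage 0.953, bootstrap-SE /
empirical-SD ratio 1.05, and LR type-I error 0.050 at α = 0.05.

Equivalently through the CLI: `polrboot report --synthetic --seed 0 --out out/`
(subcommands: `simulate`, `fit`, `bootstrap`, `sweep`, `report`).

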