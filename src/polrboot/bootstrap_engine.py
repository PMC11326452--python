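"""Bootstrap resampling of the proportional-odds fit.

The procedure: (1) choose a replicate count B; (2) for each replicate draw N
records with replacement from the observed data; (3) refit the model on the
resample; (4) summarise each coefficient's distribution across replicates.
A replication sweep repeats this for several B and lays the summaries next
to the single-fit baseline.

Two standard-error conventions are provided.  ``standard`` is the
conventional bootstrap SE — the sample standard deviation of a coefficient
across replicates, which converges to a constant as B grows.  ``replicate_mean``
divides that by sqrt(B) (the standard error of the replicate MEAN), which
shrinks as B grows; it is kept behind an explicit flag because it describes
the precision of the bootstrap average, not the sampling variability of the
estimator.

Aggregate likelihoods are equally convention-dependent; ``nll_mode`` selects
the mean per-replicate NLL (default), the NLL of the averaged coefficients
on the original data (``at_aggregate``), or a ``replication_style`` scaling
``B * mean_nll / N`` whose magnitude grows linearly in B.  In
``replication_style`` mode BIC uses n_effective = B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import DesignMatrix, StudyDataset, encode_design
from .fit_metrics import ModelMetrics, compute_metrics, metrics_from_fits
from .polr_core import (
    CoefficientTable,
    FitResult,
    PolrParams,
    fit_polr,
    intercept_only_nll,
    neg_log_likelihood,
)

__all__ = [
    "BootstrapConfig",
    "ReplicateEstimates",
    "BootstrapSummary",
    "SweepResult",
    "resample_indices",
    "bootstrap_fit",
    "aggregate_replicates",
    "replication_sweep",
]

SE_MODES = ("standard", "replicate_mean")
NLL_MODES = ("mean", "at_aggregate", "scaled")


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 1000
    seed: int = 0
    se_mode: str = "standard"
    nll_mode: str = "mean"
    max_redraws: int = 100
    replicate_maxiter: int = 100
    replicate_bound: float = 15.0
    include_stalled: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.max_redraws < 0:
            raise ValueError("max_redraws must be >= 0")
        if self.replicate_bound <= 0:
            raise ValueError("replicate_bound must be > 0")
        if self.se_mode not in SE_MODES:
            raise ValueError(f"se_mode must be one of {SE_MODES}")
        if self.nll_mode not in NLL_MODES:
            raise ValueError(f"nll_mode must be one of {NLL_MODES}")


@dataclass
class ReplicateEstimates:
    """Per-replicate MLE vectors (thresholds then slopes) and likelihoods."""

    estimates: np.ndarray  # (B, J-1+k)
    nlls: np.ndarray  # (B,)
    null_nlls: np.ndarray  # (B,)
    converged: np.ndarray  # (B,) bool
    redraw_count: int
    term_labels: list[str]
    n_thresholds: int

    @property
    def B(self) -> int:
        return self.estimates.shape[0]

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    def converged_estimates(self) -> np.ndarray:
        return self.estimates[self.converged]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.estimates, columns=self.term_labels)
        df["nll"] = self.nlls
        df["converged"] = self.converged
        return df


@dataclass
class BootstrapSummary:
    config: BootstrapConfig
    table: CoefficientTable
    metrics: ModelMetrics
    replicates: ReplicateEstimates
    n_effective_bic: int
    baseline: FitResult
    warnings: list[str] = field(default_factory=list)


@dataclass
class SweepResult:
    baseline_fit: FitResult
    baseline_null: FitResult
    baseline_metrics: ModelMetrics
    summaries: list[BootstrapSummary]
    comparison: pd.DataFrame


def resample_indices(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform draws with replacement from 0..n-1 (one bootstrap resample)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.integers(0, n, size=n)


def _level_code_matrix(dataset: StudyDataset) -> tuple[np.ndarray, list[int]]:
    """Integer-coded predictor levels (observed ones only) for coverage checks."""
    cols = []
    n_levels = []
    for p in dataset.predictor_specs:
        col = dataset.frame[p.name]
        observed = sorted(set(col))
        code = {lvl: i for i, lvl in enumerate(observed)}
        cols.append(col.map(code).to_numpy(dtype=int))
        n_levels.append(len(observed))
    if not cols:
        return np.empty((dataset.n, 0), dtype=int), []
    return np.column_stack(cols), n_levels


def _covers_all_levels(
    idx: np.ndarray,
    outcome_codes: np.ndarray,
    n_categories: int,
    pred_codes: np.ndarray,
    pred_n_levels: list[int],
) -> bool:
    """True iff the resample re-observes every outcome and predictor level."""
    oc = np.bincount(outcome_codes[idx], minlength=n_categories + 1)[1:]
    if np.any(oc == 0):
        return False
    for c in range(pred_codes.shape[1]):
        counts = np.bincount(pred_codes[idx, c], minlength=pred_n_levels[c])
        if np.any(counts == 0):
            return False
    return True


def bootstrap_fit(dataset: StudyDataset, config: BootstrapConfig) -> BootstrapSummary:
    """Run the full bootstrap: resample, refit per replicate, aggregate.

    The design matrix (columns and coding) is fixed from the full data; a
    resample that fails to re-observe some level is redrawn (up to
    ``max_redraws`` fresh draws from the replicate's own RNG substream) so
    coefficients stay comparable across replicates.  Replicate substreams
    are spawned from the seed, so results do not depend on evaluation order.
    """
    design = encode_design(dataset, drop_unobserved=True)
    baseline = fit_polr(design)
    messages: list[str] = []
    if not baseline.converged:
        msg = "full-data fit did not reach an interior optimum (separation?)"
        messages.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    # replicates warm-start from a box-constrained full-data fit so the
    # starting point is always finite and inside the replicate box
    warm = fit_polr(
        design,
        init=baseline.params if baseline.converged else None,
        bound=config.replicate_bound,
        maxiter=config.replicate_maxiter,
        compute_covariance=False,
    ).params
    n = design.n_obs
    J = design.n_categories
    pred_codes, pred_n_levels = _level_code_matrix(dataset)

    children = np.random.SeedSequence(config.seed).spawn(config.B)
    p = baseline.n_params
    estimates = np.full((config.B, p), np.nan)
    nlls = np.full(config.B, np.nan)
    null_nlls = np.full(config.B, np.nan)
    converged = np.zeros(config.B, dtype=bool)
    redraws = 0

    for b in range(config.B):
        rng = np.random.default_rng(children[b])
        idx = resample_indices(n, rng)
        attempt = 0
        while not _covers_all_levels(
            idx, design.outcome_codes, J, pred_codes, pred_n_levels
        ):
            attempt += 1
            if attempt > config.max_redraws:
                raise RuntimeError(
                    f"replicate {b}: exceeded {config.max_redraws} redraws "
                    f"without covering all observed levels"
                )
            redraws += 1
            idx = resample_indices(n, rng)
        sub = design.take_rows(idx)
        fit = fit_polr(
            sub,
            init=warm,
            bound=config.replicate_bound,
            maxiter=config.replicate_maxiter,
            compute_covariance=False,
        )
        estimates[b] = fit.params.as_vector()
        nlls[b] = fit.neg_log_likelihood
        null_nlls[b] = intercept_only_nll(sub.outcome_codes, J)
        # a replicate is usable if it reached an interior optimum, or — with
        # include_stalled (how fixed-budget ordinal-regression software
        # behaves on separated resamples) — if it stopped at the box or the
        # iteration budget with finite values
        usable = bool(
            np.all(np.isfinite(estimates[b])) and np.isfinite(nlls[b])
        )
        if not config.include_stalled:
            usable = usable and fit.converged
        converged[b] = usable

    reps = ReplicateEstimates(
        estimates=estimates,
        nlls=nlls,
        null_nlls=null_nlls,
        converged=converged,
        redraw_count=redraws,
        term_labels=baseline.term_labels,
        n_thresholds=J - 1,
    )

    frac_failed = 1.0 - reps.n_converged / config.B
    if frac_failed > 0.20:
        msg = (
            f"{frac_failed:.0%} of replicates were separated or failed to "
            f"converge; aggregation uses the remaining {reps.n_converged}"
        )
        messages.append(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)

    table = aggregate_replicates(reps, config.se_mode, allow_insufficient=True)
    if reps.n_converged < 2:
        messages.append("fewer than 2 converged replicates: SE not available")

    # aggregate likelihood per nll_mode
    ok = reps.converged
    mean_nll = float(np.mean(reps.nlls[ok]))
    mean_null = float(np.mean(reps.null_nlls[ok]))
    if config.nll_mode == "mean":
        nll_final, nll_null = mean_nll, mean_null
        n_bic, n_r2 = n, n
    elif config.nll_mode == "at_aggregate":
        mean_vec = reps.converged_estimates().mean(axis=0)
        agg_params = PolrParams(mean_vec[: J - 1], mean_vec[J - 1 :])
        nll_final = neg_log_likelihood(agg_params, design)
        nll_null = intercept_only_nll(design.outcome_codes, J)
        n_bic, n_r2 = n, n
    else:  # replication_style: magnitudes grow linearly in B; BIC uses n = B
        scale = config.B / n
        nll_final, nll_null = mean_nll * scale, mean_null * scale
        n_bic, n_r2 = config.B, config.B
    metrics = compute_metrics(
        nll_final=nll_final,
        nll_null=nll_null,
        df=design.k,
        n_params=p,
        n_effective_bic=n_bic,
        n_for_r2=n_r2,
    )
    return BootstrapSummary(
        config=config,
        table=table,
        metrics=metrics,
        replicates=reps,
        n_effective_bic=n_bic,
        baseline=baseline,
        warnings=messages,
    )


def aggregate_replicates(
    reps: ReplicateEstimates,
    se_mode: str = "standard",
    *,
    allow_insufficient: bool = False,
) -> CoefficientTable:
    """Collapse per-replicate MLEs into a Wald-style coefficient table.

    Estimate = mean across converged replicates.  ``standard`` SE is the
    across-replicate standard deviation (ddof=1); ``replicate_mean`` divides it by
    sqrt(#replicates used).  Percentile 95% intervals are attached as extra
    columns.
    """
    if se_mode not in SE_MODES:
        raise ValueError(f"se_mode must be one of {SE_MODES}")
    est = reps.converged_estimates()
    m = est.shape[0]
    if m < 2 and not allow_insufficient:
        raise ValueError(
            f"need >= 2 converged replicates to aggregate, got {m}"
        )
    if m == 0:
        raise ValueError("no converged replicates at all")
    mean = est.mean(axis=0)
    if m >= 2:
        sd = est.std(axis=0, ddof=1)
        se = sd if se_mode == "standard" else sd / np.sqrt(m)
        lo = np.percentile(est, 2.5, axis=0)
        hi = np.percentile(est, 97.5, axis=0)
    else:
        se = np.full_like(mean, np.nan)
        lo = hi = np.full_like(mean, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, mean / se, np.nan)
    p = 2 * norm.sf(np.abs(z))
    n_th = reps.n_thresholds
    frame = pd.DataFrame(
        {
            "term": reps.term_labels,
            "estimate": mean,
            "std_error": se,
            "z_value": z,
            "p_value": p,
            "odds_ratio": np.exp(mean),
            "ci_low_2.5": lo,
            "ci_high_97.5": hi,
            "is_threshold": [i < n_th for i in range(mean.size)],
        }
    )
    frame = pd.concat(
        [frame[~frame["is_threshold"]], frame[frame["is_threshold"]]],
        ignore_index=True,
    ).drop(columns="is_threshold")
    return CoefficientTable(frame)


_INDICATORS = [
    "Model fitting information (log-likelihood final model)",
    "Standard error",
    "Akaike information criterion (AIC)",
    "Bayesian information criterion (BIC)",
    "McFadden's pseudo R-squared",
    "Cox and Snell (ML)",
    "Nagelkerke (Cragg and Uhler)",
]


def _indicator_column(nll: float, mean_se: float, metrics: ModelMetrics) -> list:
    return [
        nll,
        mean_se,
        metrics.aic,
        metrics.bic,
        metrics.mcfadden,
        metrics.cox_snell,
        metrics.nagelkerke,
    ]


def replication_sweep(
    dataset: StudyDataset,
    B_list: list[int],
    base_config: BootstrapConfig,
) -> SweepResult:
    """Bootstrap summaries for each B next to the single-fit baseline.

    The comparison table has one indicator per row (NLL, mean coefficient
    SE, AIC, BIC, three pseudo-R²) and one column per model: the plain
    ordinal-regression fit first, then each replicate count.
    """
    if not B_list:
        raise ValueError("B_list must be non-empty")
    design = encode_design(dataset, drop_unobserved=True)
    fit_final = fit_polr(design)
    null_design = DesignMatrix(
        columns=[],
        values=np.empty((design.n_obs, 0)),
        outcome_codes=design.outcome_codes,
        outcome_levels=design.outcome_levels,
    )
    fit_null = fit_polr(null_design)
    base_metrics = metrics_from_fits(fit_final, fit_null)

    from .polr_core import wald_table

    base_table = wald_table(fit_final)
    data = {
        "Ordinal regression method": _indicator_column(
            fit_final.neg_log_likelihood,
            float(base_table.frame["std_error"].mean()),
            base_metrics,
        )
    }
    summaries = []
    for B in B_list:
        cfg = replace(base_config, B=B)
        summary = bootstrap_fit(dataset, cfg)
        summaries.append(summary)
        ses = summary.table.frame["std_error"]
        mean_se = float(ses.mean()) if ses.notna().any() else float("nan")
        data[str(B)] = _indicator_column(summary.metrics.nll_final, mean_se, summary.metrics)
    comparison = pd.DataFrame(data, index=_INDICATORS)
    comparison.index.name = "Indicator"
    return SweepResult(
        baseline_fit=fit_final,
        baseline_null=fit_null,
        baseline_metrics=base_metrics,
        summaries=summaries,
        comparison=comparison,
    )
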