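"""Model-fit battery: likelihood-ratio test, AIC/BIC and pseudo-R² measures.

Conventions: all likelihood quantities are NEGATIVE log-likelihoods (nats),
so smaller is better and the likelihood-ratio statistic is
``2 * (nll_null - nll_final)``.  Information criteria count every free
parameter, cut-points included: ``n_params = (J - 1) + k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log

from scipy.stats import chi2

from .polr_core import FitResult

__all__ = [
    "ModelMetrics",
    "likelihood_ratio_test",
    "information_criteria",
    "pseudo_r_squared",
    "compute_metrics",
]


@dataclass
class ModelMetrics:
    """One model's fit summary against its intercept-only null."""

    nll_final: float
    nll_null: float
    chi_square: float
    df: int
    p_value: float
    aic: float
    bic: float
    mcfadden: float
    cox_snell: float
    nagelkerke: float
    n_used_for_bic: int
    n_used_for_r2: int


def likelihood_ratio_test(
    nll_final: float, nll_null: float, df: int
) -> tuple[float, int, float]:
    """LR chi-square of a fitted model against its nested intercept-only null.

    Returns ``(chi_square, df, p_value)`` with
    ``chi_square = 2 * (nll_null - nll_final)`` and the p-value from the
    upper tail of chi-square with ``df`` = slope count.
    """
    if nll_final > nll_null + 1e-9:
        raise ValueError(
            f"final model NLL ({nll_final:.6f}) exceeds null NLL "
            f"({nll_null:.6f}): models not nested or optimisation failed"
        )
    stat = max(0.0, 2.0 * (nll_null - nll_final))
    p = float(chi2.sf(stat, df)) if df > 0 else (1.0 if stat == 0 else 0.0)
    return stat, df, p


def likelihood_ratio_test_fits(
    fit_final: FitResult, fit_null: FitResult
) -> tuple[float, int, float]:
    """LR test from two fits on the same data (null = intercept-only)."""
    if fit_final.n_obs != fit_null.n_obs:
        raise ValueError("fits are not on the same data (n differs)")
    df = fit_final.n_params - fit_null.n_params
    return likelihood_ratio_test(
        fit_final.neg_log_likelihood, fit_null.neg_log_likelihood, df
    )


def information_criteria(
    nll: float, n_params: int, n_effective: int
) -> tuple[float, float]:
    """AIC = 2·nll + 2·p and BIC = 2·nll + p·ln(n)."""
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    if n_effective < 1 and n_params > 0:
        raise ValueError("n_effective must be >= 1")
    aic = 2.0 * nll + 2.0 * n_params
    bic = 2.0 * nll + n_params * (log(n_effective) if n_params > 0 else 0.0)
    return aic, bic


def pseudo_r_squared(
    nll_final: float, nll_null: float, n: int
) -> tuple[float, float, float]:
    """McFadden, Cox–Snell (ML) and Nagelkerke (Cragg–Uhler) pseudo-R².

    McFadden = 1 - nll_final/nll_null; Cox–Snell = 1 - exp(-2·ΔLL/n);
    Nagelkerke rescales Cox–Snell by its attainable maximum
    ``1 - exp(-2·nll_null/n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if nll_final < 0 or nll_null < 0:
        raise ValueError("negative log-likelihoods must be >= 0")
    if nll_final > nll_null + 1e-9:
        raise ValueError("nll_final must not exceed nll_null")
    if nll_null == 0:
        raise ValueError("null model has zero NLL: degenerate outcome")
    delta = nll_null - nll_final
    mcfadden = 1.0 - nll_final / nll_null
    cox_snell = 1.0 - exp(-2.0 * delta / n)
    max_cs = 1.0 - exp(-2.0 * nll_null / n)
    nagelkerke = cox_snell / max_cs
    return mcfadden, cox_snell, nagelkerke


def compute_metrics(
    nll_final: float,
    nll_null: float,
    df: int,
    n_params: int,
    n_effective_bic: int,
    n_for_r2: int,
) -> ModelMetrics:
    """Assemble the full battery from likelihood summaries."""
    chi_sq, df_, p = likelihood_ratio_test(nll_final, nll_null, df)
    aic, bic = information_criteria(nll_final, n_params, n_effective_bic)
    mcf, cs, nag = pseudo_r_squared(nll_final, nll_null, n_for_r2)
    return ModelMetrics(
        nll_final=nll_final,
        nll_null=nll_null,
        chi_square=chi_sq,
        df=df_,
        p_value=p,
        aic=aic,
        bic=bic,
        mcfadden=mcf,
        cox_snell=cs,
        nagelkerke=nag,
        n_used_for_bic=n_effective_bic,
        n_used_for_r2=n_for_r2,
    )


def metrics_from_fits(fit_final: FitResult, fit_null: FitResult) -> ModelMetrics:
    """Battery for a single (non-bootstrap) fit; BIC and R² use n = N."""
    df = fit_final.n_params - fit_null.n_params
    return compute_metrics(
        nll_final=fit_final.neg_log_likelihood,
        nll_null=fit_null.neg_log_likelihood,
        df=df,
        n_params=fit_final.n_params,
        n_effective_bic=fit_final.n_obs,
        n_for_r2=fit_final.n_obs,
    )
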