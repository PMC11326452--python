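"""Maximum-likelihood fitting of the proportional-odds (cumulative logit) model.

Model: for an ordered outcome with categories j = 1..J and design row x,

    logit P(Y <= j | x) = theta_j - x . beta,        j = 1..J-1,

with strictly increasing cut-points theta and one shared slope vector beta.
Under this sign convention a positive slope raises the odds of a MORE severe
category, so exp(beta) reads directly as the odds ratio of worse outcome per
level versus its reference.

Fitting is quasi-Newton (BFGS) with an analytic gradient on an unconstrained
reparameterisation of the cut-points (first cut-point plus log-increments),
which enforces monotonicity.  Standard errors come from the inverse of the
numerically differentiated observed information at the optimum, evaluated in
the natural (theta, beta) parameterisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

from .data_model import DesignMatrix

__all__ = [
    "PolrParams",
    "FitResult",
    "CoefficientTable",
    "category_probabilities",
    "neg_log_likelihood",
    "fit_polr",
    "wald_table",
    "empirical_cumulative_logits",
    "intercept_only_nll",
]

_SE_BLOWUP = 50.0  # SE beyond this flags likely separation


@dataclass
class PolrParams:
    """Cut-points (strictly increasing, length J-1) plus slopes (length k)."""

    thresholds: np.ndarray
    slopes: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        if self.thresholds.ndim != 1 or self.thresholds.size < 1:
            raise ValueError("thresholds must be a non-empty 1-d array")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.thresholds, self.slopes])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_thresholds: int) -> "PolrParams":
        vec = np.asarray(vec, dtype=float)
        return cls(vec[:n_thresholds], vec[n_thresholds:])


@dataclass
class FitResult:
    """A converged (or diagnosed) maximum-likelihood fit."""

    params: PolrParams
    neg_log_likelihood: float
    covariance: np.ndarray  # (J-1+k, J-1+k), natural parameterisation
    converged: bool
    n_obs: int
    n_params: int
    term_labels: list[str]  # threshold labels then slope labels
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CoefficientTable:
    """Per-term Wald rows: estimate, SE, z, p and odds ratio.

    Column names internally are snake_case; :meth:`to_frame` relabels them to
    the presentation header ``Variable, Estimate, Standard error, z-value,
    Significance, Exp (B)``.
    """

    frame: pd.DataFrame  # term, estimate, std_error, z_value, p_value, odds_ratio

    _PRESENTATION = {
        "term": "Variable",
        "estimate": "Estimate",
        "std_error": "Standard error",
        "z_value": "z-value",
        "p_value": "Significance",
        "odds_ratio": "Exp (B)",
    }

    def to_frame(self) -> pd.DataFrame:
        return self.frame.rename(columns=self._PRESENTATION)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def row(self, term: str) -> pd.Series:
        match = self.frame[self.frame["term"] == term]
        if match.empty:
            raise KeyError(term)
        return match.iloc[0]


# --------------------------------------------------------------------------
# Probabilities and likelihood
# --------------------------------------------------------------------------

def _category_prob_matrix(
    thresholds: np.ndarray, eta: np.ndarray
) -> np.ndarray:
    """(n, J) matrix of P(Y = j | eta_i) with eta = x . beta."""
    cum = expit(thresholds[None, :] - eta[:, None])  # (n, J-1)
    ones = np.ones((eta.size, 1))
    zeros = np.zeros((eta.size, 1))
    upper = np.hstack([cum, ones])
    lower = np.hstack([zeros, cum])
    return upper - lower


def category_probabilities(params: PolrParams, x: Sequence[float]) -> np.ndarray:
    """P(Y = j | x) for j = 1..J; entries >= 0 and sum to 1."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size != params.slopes.size:
        raise ValueError(
            f"x has {x.size} entries, model has {params.slopes.size} slopes"
        )
    eta = np.array([float(x @ params.slopes)])
    return _category_prob_matrix(params.thresholds, eta)[0]


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    """log sigma(x), stable for large |x|."""
    return -np.logaddexp(0.0, -x)


def _log_cell_probs(
    theta: np.ndarray, eta: np.ndarray, y: np.ndarray, J: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stable log P(Y=y_i) with the upper/lower cut arguments.

    Returns (logp, a_up, a_lo) where a_up = theta_y - eta (+inf for y = J)
    and a_lo = theta_{y-1} - eta (-inf for y = 1).  Works in log space so
    observations far into a distribution tail keep a finite log-probability
    instead of underflowing to zero.
    """
    th_ext = np.concatenate([[-np.inf], theta, [np.inf]])
    a_up = th_ext[y] - eta
    a_lo = th_ext[y - 1] - eta
    logp = np.empty(y.size)
    first = y == 1
    last = y == J
    mid = ~(first | last)
    logp[first] = _log_sigmoid(a_up[first])
    logp[last] = _log_sigmoid(-a_lo[last])
    if np.any(mid):
        au, al = a_up[mid], a_lo[mid]
        d = au - al  # > 0 by threshold monotonicity
        # P = sigma(au) - sigma(al) = e^{-al} (1 - e^{-d}) sigma(au) sigma(al)
        logp[mid] = (
            -al
            + np.log(-np.expm1(-d))
            + _log_sigmoid(au)
            + _log_sigmoid(al)
        )
    return logp, a_up, a_lo


def neg_log_likelihood(params: PolrParams, design: DesignMatrix) -> float:
    """-sum_i log P(Y = y_i | x_i); +inf if any observation has probability 0."""
    if params.slopes.size != design.k:
        raise ValueError("slope count does not match design matrix")
    if params.n_categories != design.n_categories:
        raise ValueError("threshold count does not match outcome categories")
    eta = design.values @ params.slopes
    logp, _, _ = _log_cell_probs(
        params.thresholds, eta, design.outcome_codes, design.n_categories
    )
    if np.any(np.isneginf(logp)) or np.any(np.isnan(logp)):
        return float("inf")
    return float(-np.sum(logp))


def empirical_cumulative_logits(
    outcome_codes: np.ndarray, n_categories: int
) -> np.ndarray:
    """logit of the empirical cumulative proportions; the intercept-only MLE.

    Proportions are clipped away from 0/1 so unobserved leading/trailing
    categories give large finite starting values rather than infinities.
    """
    codes = np.asarray(outcome_codes, dtype=int)
    n = codes.size
    counts = np.bincount(codes, minlength=n_categories + 1)[1:]
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
    return np.log(cum / (1 - cum))


def intercept_only_nll(outcome_codes: np.ndarray, n_categories: int) -> float:
    """Closed-form NLL of the saturated-margins intercept-only model."""
    codes = np.asarray(outcome_codes, dtype=int)
    counts = np.bincount(codes, minlength=n_categories + 1)[1:]
    n = codes.size
    nz = counts[counts > 0]
    return float(-np.sum(nz * np.log(nz / n)))


# --------------------------------------------------------------------------
# Reparameterised objective (unconstrained) and its analytic gradient
# --------------------------------------------------------------------------

def _theta_from_z(z: np.ndarray) -> np.ndarray:
    # z = (theta_1, log(theta_2 - theta_1), ..., log(theta_{J-1} - theta_{J-2}))
    if z.size == 1:
        return z.copy()
    return z[0] + np.concatenate([[0.0], np.cumsum(np.exp(z[1:]))])


def _z_from_theta(theta: np.ndarray) -> np.ndarray:
    if theta.size == 1:
        return theta.copy()
    return np.concatenate([[theta[0]], np.log(np.diff(theta))])


def _nll_grad_natural(
    theta: np.ndarray, beta: np.ndarray, design: DesignMatrix
) -> tuple[float, np.ndarray, np.ndarray]:
    """NLL plus gradients w.r.t. theta and beta (vectorised over rows).

    The density-to-probability ratios f(a)/P are formed in log space so the
    gradient stays finite deep in the tails, where both f and P underflow.
    """
    y = design.outcome_codes
    X = design.values
    J = design.n_categories
    eta = X @ beta
    logp, a_up, a_lo = _log_cell_probs(theta, eta, y, J)
    if np.any(np.isneginf(logp)) or np.any(np.isnan(logp)):
        return float("inf"), np.zeros(theta.size), np.zeros_like(beta)
    nll = float(-np.sum(logp))
    # log f(a) = log sigma(a) + log sigma(-a); ratios r = f(a)/P
    with np.errstate(over="ignore"):
        log_fu = _log_sigmoid(a_up) + _log_sigmoid(-a_up)
        log_fl = _log_sigmoid(a_lo) + _log_sigmoid(-a_lo)
    r_u = np.where(y == J, 0.0, np.exp(log_fu - logp))
    r_l = np.where(y == 1, 0.0, np.exp(log_fl - logp))
    # d(-log p)/d theta_m: -f(a_up)/P when m = y, +f(a_lo)/P when m = y-1
    g_theta = np.zeros(theta.size)
    np.add.at(g_theta, np.clip(y - 1, 0, theta.size - 1), -r_u)
    np.add.at(g_theta, np.clip(y - 2, 0, theta.size - 1), r_l)
    g_beta = X.T @ (r_u - r_l)
    return nll, g_theta, g_beta


def _objective(z_beta: np.ndarray, design: DesignMatrix, n_th: int):
    z = z_beta[:n_th]
    beta = z_beta[n_th:]
    theta = _theta_from_z(z)
    nll, g_theta, g_beta = _nll_grad_natural(theta, beta, design)
    if not np.isfinite(nll):
        return nll, np.zeros_like(z_beta)
    # chain rule to z: d theta_m / d z_1 = 1; d theta_m / d z_l = e^{z_l} [l <= m]
    g_z = np.empty_like(z)
    g_z[0] = g_theta.sum()
    if n_th > 1:
        # reverse cumulative sums: sum_{m >= l} g_theta[m]
        tail = np.cumsum(g_theta[::-1])[::-1]
        g_z[1:] = np.exp(z[1:]) * tail[1:]
    return nll, np.concatenate([g_z, g_beta])


def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian with per-coordinate scaled steps."""
    p = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    return H


def fit_polr(
    design: DesignMatrix,
    *,
    init: PolrParams | None = None,
    gtol: float = 1e-8,
    ftol: float = 1e-14,
    maxiter: int = 500,
    bound: float | None = None,
    compute_covariance: bool = True,
) -> FitResult:
    """Fit the cumulative-logit model by maximum likelihood.

    Deterministic given the design and options.  Initialisation is the
    empirical cumulative logits with zero slopes unless ``init`` is given
    (e.g. warm-starting bootstrap refits from the full-data optimum).
    """
    J = design.n_categories
    n_th = J - 1
    k = design.k
    observed = set(np.unique(design.outcome_codes).tolist())
    if observed != set(range(1, J + 1)):
        raise ValueError(
            f"every outcome category must be observed; got codes {sorted(observed)}"
        )
    n_params = n_th + k
    if design.n_obs <= n_params:
        warnings.warn(
            f"n = {design.n_obs} observations for {n_params} parameters; "
            f"estimates will be unstable",
            UserWarning,
            stacklevel=2,
        )
    if init is not None:
        theta0 = init.thresholds.copy()
        beta0 = init.slopes.copy()
    else:
        theta0 = empirical_cumulative_logits(design.outcome_codes, J)
        beta0 = np.zeros(k)
    x0 = np.concatenate([_z_from_theta(theta0), beta0])

    # On separated data the likelihood flattens along diverging directions
    # and the unconstrained optimum sits at infinity.  An optional box
    # (|parameter| <= bound, in the unconstrained coordinates) keeps such
    # fits finite: a separated coefficient simply pegs at the bound.  Used
    # by the bootstrap so replicate refits always return finite values.
    bounds = None
    if bound is not None:
        x0 = np.clip(x0, -bound + 1e-9, bound - 1e-9)
        bounds = [(-bound, bound)] * x0.size
    res = optimize.minimize(
        _objective,
        x0,
        args=(design, n_th),
        method="L-BFGS-B",
        jac=True,
        bounds=bounds,
        options={"gtol": gtol, "ftol": ftol, "maxiter": maxiter},
    )
    z_hat = res.x[:n_th]
    theta_hat = _theta_from_z(z_hat)
    beta_hat = res.x[n_th:]
    params = PolrParams(theta_hat, beta_hat)
    nll_hat = float(res.fun)
    grad_norm = float(np.max(np.abs(res.jac)))
    # "converged" means a genuine interior optimum (small gradient), not
    # merely that iteration stopped; separated likelihoods stall with the
    # gradient still large, and are flagged accordingly
    converged = grad_norm < 1e-4

    diagnostics = {
        "n_iterations": int(res.nit),
        "grad_norm": grad_norm,
        "optimizer_message": str(res.message),
    }
    if bound is not None and np.any(np.abs(res.x) >= bound - 1e-6):
        diagnostics["at_bound"] = True

    cov = np.full((n_params, n_params), np.nan)
    if compute_covariance and converged:
        vec_hat = params.as_vector()

        def nll_vec(v: np.ndarray) -> float:
            th = v[:n_th]
            if np.any(np.diff(th) <= 0):
                return float("inf")
            return neg_log_likelihood(PolrParams(th, v[n_th:]), design)

        H = _numerical_hessian(nll_vec, vec_hat)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            diagnostics["singular_information"] = True
        cov = 0.5 * (cov + cov.T)
        diag = np.diag(cov)
        if np.any(diag < 0):
            diagnostics["negative_variance"] = True
        se = np.sqrt(np.clip(diag, 0, None))
        if np.any(se > _SE_BLOWUP):
            diagnostics["possible_separation"] = True
            warnings.warn(
                "very large standard errors; possible separation",
                UserWarning,
                stacklevel=2,
            )

    labels = [
        f"{design.outcome_levels[j]}|{design.outcome_levels[j + 1].lower()}"
        for j in range(n_th)
    ] + list(design.columns)

    return FitResult(
        params=params,
        neg_log_likelihood=nll_hat,
        covariance=cov,
        converged=converged,
        n_obs=design.n_obs,
        n_params=n_params,
        term_labels=labels,
        diagnostics=diagnostics,
    )


def wald_table(fit: FitResult) -> CoefficientTable:
    """Wald coefficient table: estimate, SE, z, two-sided normal p, OR.

    Threshold rows carry ``"low|mid"``-style labels and appear after the
    slope rows, mirroring how ordinal-regression software prints them.
    """
    if not fit.converged:
        raise RuntimeError(
            "fit did not converge; inspect FitResult.diagnostics before "
            "interpreting Wald statistics"
        )
    n_th = fit.params.thresholds.size
    estimates = fit.params.as_vector()
    ses = np.sqrt(np.clip(np.diag(fit.covariance), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, estimates / ses, np.nan)
    p = 2 * norm.sf(np.abs(z))
    frame = pd.DataFrame(
        {
            "term": fit.term_labels,
            "estimate": estimates,
            "std_error": ses,
            "z_value": z,
            "p_value": p,
            "odds_ratio": np.exp(estimates),
            "is_threshold": [i < n_th for i in range(len(estimates))],
        }
    )
    # slopes first, thresholds last (presentation order)
    frame = pd.concat(
        [frame[~frame["is_threshold"]], frame[frame["is_threshold"]]],
        ignore_index=True,
    ).drop(columns="is_threshold")
    return CoefficientTable(frame)
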