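"""Maximum-likelihood logistic regression with survey weighting modes.

Three modes are supported:

``unweighted``
    Ordinary Bernoulli maximum likelihood.
``pseudo_likelihood``
    Each record's log-likelihood contribution is multiplied by its
    sampling weight ``w_ic`` (design-consistent survey weighting).
``eq7_literal``
    The linear predictor itself is multiplied by ``w_ic`` while the
    likelihood stays unweighted, i.e. the model is
    ``logit(pi) = (beta' x) * w``, with the intercept column left
    unscaled so the model stays identified.  This form is NOT standard
    survey weighting and is not design-consistent; it is provided only
    for fidelity to the weighted-predictor parameterization some
    applied analyses print, behind this explicit mode name.

All modes are fitted by iteratively reweighted least squares (IRLS)
starting from ``beta = 0``, with step-halving on deviance increases,
convergence when the deviance changes by less than ``tol`` (default
1e-8), and a cap of 100 iterations.  The model-based covariance is the
inverse observed information at the optimum.  Cluster-robust standard
errors come from a stratified delete-one-cluster jackknife.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "LogitFit",
    "FitSummary",
    "SingularDesignError",
    "NotConvergedError",
    "fit_logit",
    "jackknife_cluster_covariance",
    "summarize_fit",
    "compare_aic",
]

MODES = ("unweighted", "pseudo_likelihood", "eq7_literal")
_PROB_EPS = 1e-10
_SEPARATION_BOUND = 15.0


class SingularDesignError(np.linalg.LinAlgError):
    """The information matrix is singular; the message names the columns."""


class NotConvergedError(RuntimeError):
    """An operation that requires a converged fit received one that is not."""


@dataclass(frozen=True)
class ModelSpec:
    """Outcome and ordered categorical covariates of a logit model.

    ``covariates`` maps each covariate name to its declared level
    order; the first level is the reference and is absorbed into the
    intercept (dummy coding).
    """

    outcome: str = "y"
    covariates: dict[str, tuple[str, ...]] = field(default_factory=dict)
    weighting: str = "unweighted"

    def __post_init__(self) -> None:
        if self.weighting not in MODES:
            raise ValueError(f"weighting must be one of {MODES}")
        for name, levels in self.covariates.items():
            if len(levels) < 2:
                raise ValueError(f"covariate {name!r} needs >= 2 declared levels")


@dataclass
class LogitFit:
    """A fitted logistic model.

    ``params`` holds the coefficients (intercept first, then dummy
    columns in declared order), ``cov_params`` the model-based
    covariance, and — after :func:`jackknife_cluster_covariance` —
    ``jackknife_cov`` the replication covariance with its degrees of
    freedom ``jackknife_df = clusters - strata``.
    """

    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    fitted: np.ndarray
    loglik: float
    aic: float
    deviance: float
    n_iter: int
    converged: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)
    jackknife_cov: pd.DataFrame | None = None
    jackknife_df: int | None = None

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Fitted probabilities for new records under this model."""
        X = build_design(data, self.spec)
        eta = X @ self.params.to_numpy()
        return np.clip(expit(eta), _PROB_EPS, 1.0 - _PROB_EPS)


def build_design(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Design matrix: intercept plus first-reference dummy columns.

    In ``eq7_literal`` mode every non-intercept column is additionally
    multiplied by the record's sampling weight (the intercept keeps
    weight 1, the only reading that keeps the model identified).
    """
    cols = [np.ones(len(data))]
    for name, levels in spec.covariates.items():
        observed = set(pd.unique(data[name].dropna()))
        unknown = observed - set(levels)
        if unknown:
            raise ValueError(
                f"covariate {name!r}: undeclared levels {sorted(unknown)}"
            )
        for level in levels[1:]:
            if level not in observed:
                raise ValueError(
                    f"covariate {name!r}: level {level!r} absent from the data"
                )
            cols.append((data[name].to_numpy() == level).astype(float))
    X = np.column_stack(cols)
    if spec.weighting == "eq7_literal":
        w = _sampling_weights(data, spec)
        X = X.copy()
        X[:, 1:] *= w[:, None]
    return X


def design_columns(spec: ModelSpec) -> list[str]:
    names = ["intercept"]
    for name, levels in spec.covariates.items():
        names += [f"{name}={level}" for level in levels[1:]]
    return names


def _sampling_weights(data: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    if "weight" not in data.columns:
        raise ValueError(f"weighting mode {spec.weighting!r} requires a weight column")
    w = data["weight"].to_numpy(dtype=float)
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise ValueError("sampling weights must be positive and finite")
    return w


def _deviance(y: np.ndarray, mu: np.ndarray, omega: np.ndarray) -> float:
    mu = np.clip(mu, _PROB_EPS, 1.0 - _PROB_EPS)
    return float(-2.0 * np.sum(omega * (y * np.log(mu) + (1 - y) * np.log1p(-mu))))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    omega: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, int, float]:
    """Weighted-likelihood IRLS; returns (beta, info, converged, iters, dev)."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    mu = np.clip(expit(X @ beta), _PROB_EPS, 1.0 - _PROB_EPS)
    dev = _deviance(y, mu, omega)
    info = np.empty((p, p))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = omega * mu * (1.0 - mu)
        info = X.T @ (W[:, None] * X)
        score = X.T @ (omega * (y - mu))
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            raise _singular_error(X, W) from None
        # step-halving: never accept a deviance increase
        new_beta, new_dev = beta, dev
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            cand_dev = _deviance(y, np.clip(expit(X @ cand), _PROB_EPS, 1 - _PROB_EPS), omega)
            if cand_dev <= dev + 1e-12:
                new_beta, new_dev = cand, cand_dev
                break
            factor /= 2.0
        if new_beta is beta:  # no improving step found: treat as converged
            converged = True
            break
        delta = dev - new_dev
        beta, dev = new_beta, new_dev
        mu = np.clip(expit(X @ beta), _PROB_EPS, 1.0 - _PROB_EPS)
        if delta < tol:
            converged = True
            break
    # information at the optimum
    W = omega * mu * (1.0 - mu)
    info = X.T @ (W[:, None] * X)
    return beta, info, converged, it, dev


def _singular_error(X: np.ndarray, W: np.ndarray) -> SingularDesignError:
    A = np.sqrt(W)[:, None] * X
    _, s, vt = np.linalg.svd(A, full_matrices=False)
    null = np.abs(s) < max(s.max(), 1.0) * 1e-10
    involved = sorted(set(np.nonzero(np.abs(vt[null]) > 1e-6)[1]))
    return SingularDesignError(
        f"singular information matrix; collinear design columns at positions {involved}"
    )


def fit_logit(
    data: pd.DataFrame,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogitFit:
    """Fit the logit model by (pseudo-)maximum likelihood via IRLS.

    The objective is ``sum_i omega_i [y_i log pi_i + (1-y_i) log(1-pi_i)]``
    with ``omega_i = 1`` (``unweighted`` and ``eq7_literal``) or
    ``omega_i = w_ic`` (``pseudo_likelihood``).  A non-converged fit is
    returned with ``converged=False`` and a warning rather than raised,
    so callers can inspect it; prediction operations refuse such fits.
    """
    y = data[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1")
    X = build_design(data, spec)
    omega = (
        _sampling_weights(data, spec)
        if spec.weighting == "pseudo_likelihood"
        else np.ones(len(data))
    )
    beta, info, converged, n_iter, dev = _irls(X, y, omega, tol=tol, max_iter=max_iter)
    names = design_columns(spec)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise _singular_error(X, omega) from None
    mu = np.clip(expit(X @ beta), _PROB_EPS, 1.0 - _PROB_EPS)
    loglik = -dev / 2.0
    diagnostics: dict = {}
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        diagnostics["separation_suspected"] = True
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations", RuntimeWarning
        )
    return LogitFit(
        spec=spec,
        params=pd.Series(beta, index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        fitted=mu,
        loglik=loglik,
        aic=2.0 * len(beta) - 2.0 * loglik,
        deviance=dev,
        n_iter=n_iter,
        converged=converged,
        n_obs=len(data),
        diagnostics=diagnostics,
    )


def jackknife_cluster_covariance(
    data: pd.DataFrame, spec: ModelSpec, fit: LogitFit
) -> pd.DataFrame:
    """Stratified delete-one-cluster jackknife covariance of the coefficients.

    For each stratum *h* with ``K_h`` clusters the model is refitted
    with each cluster deleted in turn, the likelihood weights of the
    remaining records of that stratum rescaled by ``K_h / (K_h - 1)``;
    the covariance is ``sum_h ((K_h - 1)/K_h) sum_c (b_hc - b)(b_hc - b)'``.
    The result is stored on ``fit`` (``jackknife_cov``) together with
    the degrees of freedom ``clusters - strata``.
    """
    if not fit.converged:
        raise NotConvergedError("jackknife requires a converged fit")
    y = data[spec.outcome].to_numpy(dtype=float)
    X = build_design(data, spec)
    base_omega = (
        _sampling_weights(data, spec)
        if spec.weighting == "pseudo_likelihood"
        else np.ones(len(data))
    )
    cluster = data["cluster_id"].to_numpy()
    stratum = data["stratum"].to_numpy()
    beta_hat = fit.params.to_numpy()
    p = len(beta_hat)
    cov = np.zeros((p, p))
    n_clusters = 0
    strata = pd.unique(stratum)
    for h in strata:
        in_h = stratum == h
        clusters_h = pd.unique(cluster[in_h])
        K_h = len(clusters_h)
        if K_h < 2:
            raise ValueError(
                f"stratum {h!r} has a single cluster; collapse strata before "
                "the jackknife"
            )
        n_clusters += K_h
        inner = np.zeros((p, p))
        for c in clusters_h:
            keep = cluster != c
            omega = base_omega.copy()
            omega[in_h] *= K_h / (K_h - 1.0)
            beta_c, _, conv, _, _ = _irls(
                X[keep], y[keep], omega[keep], beta0=beta_hat
            )
            if not conv:
                warnings.warn(
                    f"jackknife refit without cluster {c!r} did not converge",
                    RuntimeWarning,
                )
            d = beta_c - beta_hat
            inner += np.outer(d, d)
        cov += (K_h - 1.0) / K_h * inner
    names = fit.columns
    fit.jackknife_cov = pd.DataFrame(cov, index=names, columns=names)
    fit.jackknife_df = n_clusters - len(strata)
    return fit.jackknife_cov


def summarize_fit(fit: LogitFit) -> "FitSummary":
    """Wald summary table: aOR, SE, statistic, two-sided p per coefficient.

    Uses the jackknife covariance when attached (p-values then refer to
    a t distribution with ``clusters - strata`` degrees of freedom,
    standard survey practice), otherwise the model-based covariance
    with a normal reference.  AIC is reported for the unweighted mode
    only; weighted pseudo-likelihoods have no likelihood interpretation
    for information criteria.
    """
    if not fit.converged:
        raise NotConvergedError("cannot summarize a non-converged fit")
    if fit.jackknife_cov is not None:
        se = np.sqrt(np.diag(fit.jackknife_cov.to_numpy()))
        df = fit.jackknife_df
    else:
        se = np.sqrt(np.diag(fit.cov_params.to_numpy()))
        df = None
    beta = fit.params.to_numpy()
    z = beta / se
    if df is not None:
        pvals = 2.0 * stats.t.sf(np.abs(z), df)
        reference = f"t({df})"
    else:
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        reference = "normal"
    table = pd.DataFrame(
        {
            "term": fit.columns,
            "estimate": beta,
            "aOR": np.exp(beta),
            "se": se,
            "statistic": z,
            "p_value": pvals,
        }
    )
    aic = fit.aic if fit.spec.weighting == "unweighted" else None
    return FitSummary(
        table=table,
        aic=aic,
        loglik=fit.loglik,
        weighting=fit.spec.weighting,
        reference=reference,
    )


@dataclass(frozen=True)
class FitSummary:
    table: pd.DataFrame
    aic: float | None
    loglik: float
    weighting: str
    reference: str


def compare_aic(**fits: LogitFit) -> pd.DataFrame:
    """AIC comparison of unweighted fits; flags the smallest."""
    rows = []
    for label, fit in fits.items():
        if fit.spec.weighting != "unweighted":
            raise ValueError("AIC comparison applies to unweighted fits only")
        rows.append({"model": label, "aic": fit.aic, "loglik": fit.loglik})
    out = pd.DataFrame(rows)
    out["preferred"] = out["aic"] == out["aic"].min()
    return out
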