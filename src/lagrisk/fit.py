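"""Stratum-conditioned quasi-Poisson fitting, dispersion, and Q-AIC.

The first-stage model is a Poisson log-linear regression with one nuisance
intercept per case-crossover stratum and quasi-likelihood variance
``var(Y) = phi * mu``.  Stratum intercepts are profiled out in closed form at
each IRLS step (for a log link, ``exp(alpha_s) = sum_s y / sum_s exp(x'beta)``)
and the working least-squares problem is solved on within-stratum
weighted-centered covariates — the Frisch-Waugh projection — which is exactly
equivalent to carrying explicit stratum dummies but scales with the number of
covariates, not the number of strata.  A dummy-variable reference
implementation is kept for testing the equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.special import gammaln

from .design import DesignMatrix

__all__ = [
    "FitResult",
    "fit_quasipoisson_cc",
    "fit_quasipoisson_dummy",
    "estimate_dispersion",
    "qaic",
    "RankDeficientError",
]


class RankDeficientError(np.linalg.LinAlgError):
    """Design is rank deficient after stratum absorption."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns after stratum absorption: {self.columns}")


@dataclass
class FitResult:
    """One district-level fit: coefficients and covariance for the
    non-stratum terms, dispersion, deviance and Q-AIC."""

    coef: np.ndarray
    vcov: np.ndarray
    dispersion: float
    deviance: float
    loglik_poisson: float
    qaic: float
    n_rows: int
    n_strata: int
    n_params: int  # covariates + absorbed stratum intercepts
    converged: bool
    column_map: Dict[str, slice]
    fitted: np.ndarray
    y: np.ndarray
    pearson_chi2: float

    def coef_for(self, term: str) -> np.ndarray:
        return self.coef[self.column_map[term]]

    def vcov_for(self, term: str) -> np.ndarray:
        s = self.column_map[term]
        return self.vcov[s, s]


def _group_codes(strata: np.ndarray):
    uniq, codes = np.unique(strata, return_inverse=True)
    return uniq, codes


def _center_within(M: np.ndarray, codes: np.ndarray, w: np.ndarray, n_groups: int) -> np.ndarray:
    """Subtract the weighted within-group mean from each column of M."""
    wsum = np.bincount(codes, weights=w, minlength=n_groups)
    if M.ndim == 1:
        num = np.bincount(codes, weights=w * M, minlength=n_groups)
        return M - (num / wsum)[codes]
    out = np.empty_like(M)
    for j in range(M.shape[1]):
        num = np.bincount(codes, weights=w * M[:, j], minlength=n_groups)
        out[:, j] = M[:, j] - (num / wsum)[codes]
    return out


def _named_collinear(X: np.ndarray, column_map: Dict[str, slice]):
    """Map pivoted-out column indices to term names for the error message."""
    from numpy.linalg import qr

    q, r = qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.where(diag <= tol)[0]
    names = []
    for b in bad:
        for name, sl in column_map.items():
            if sl.start <= b < sl.stop:
                names.append(f"{name}[{b - sl.start}]")
                break
        else:
            names.append(f"col{b}")
    return names


def fit_quasipoisson_cc(
    design: DesignMatrix,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> FitResult:
    """Fit the stratum-conditioned quasi-Poisson model by absorbed IRLS.

    Equivalent to a Poisson GLM with one intercept dummy per stratum; the
    covariance of the covariate coefficients is scaled by the Pearson
    dispersion ``phi = chi2 / (n - p)`` with ``p`` counting the absorbed
    stratum intercepts.
    """
    y, X, strata = design.y, design.X, design.strata
    uniq, codes = _group_codes(strata)
    n_strata = len(uniq)
    n, k = X.shape

    group_y = np.bincount(codes, weights=y, minlength=n_strata)
    live = group_y[codes] > 0  # degenerate strata: fitted mean -> 0 exactly

    yl, Xl, cl = y[live], X[live], codes[live]
    # re-code live strata densely
    live_uniq, cl = np.unique(cl, return_inverse=True)
    m = len(live_uniq)
    gy = np.bincount(cl, weights=yl, minlength=m)

    beta = np.zeros(k)
    converged = False
    Xc_w = None
    w = None
    for _ in range(max_iter):
        xb = Xl @ beta
        # profile the stratum intercepts in closed form
        log_denom = np.log(np.bincount(cl, weights=np.exp(xb), minlength=m))
        alpha = np.log(gy) - log_denom
        eta = xb + alpha[cl]
        mu = np.exp(eta)
        w = mu
        z = eta + (yl - mu) / mu
        Xc = _center_within(Xl, cl, w, m)
        zc = _center_within(z, cl, w, m)
        sw = np.sqrt(w)
        Xc_w = Xc * sw[:, None]
        rank = np.linalg.matrix_rank(Xc_w)
        if rank < k:
            raise RankDeficientError(_named_collinear(Xc_w, design.column_map))
        beta_new, *_ = np.linalg.lstsq(Xc_w, zc * sw, rcond=None)
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta_new)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    xb = Xl @ beta
    alpha = np.log(gy) - np.log(np.bincount(cl, weights=np.exp(xb), minlength=m))
    mu_l = np.exp(xb + alpha[cl])
    fitted = np.zeros(n)
    fitted[live] = mu_l

    p = k + n_strata  # absorbed intercepts count as parameters
    pearson = float(np.sum((yl - mu_l) ** 2 / mu_l))
    phi = estimate_dispersion(y, fitted, p)

    XtWX = Xc_w.T @ Xc_w
    vcov = phi * np.linalg.inv(XtWX)

    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(yl > 0, yl * np.log(yl / mu_l), 0.0) - (yl - mu_l)
    deviance = float(2.0 * dev_terms.sum())
    ll = float(np.sum(yl * np.log(mu_l) - mu_l - gammaln(yl + 1)))
    # zero-count rows in degenerate strata contribute 0 to both

    fr = FitResult(
        coef=beta,
        vcov=vcov,
        dispersion=phi,
        deviance=deviance,
        loglik_poisson=ll,
        qaic=np.nan,
        n_rows=n,
        n_strata=n_strata,
        n_params=p,
        converged=converged,
        column_map=dict(design.column_map),
        fitted=fitted,
        y=y,
        pearson_chi2=pearson,
    )
    fr.qaic = qaic(fr)
    return fr


def fit_quasipoisson_dummy(design: DesignMatrix) -> FitResult:
    """Reference fit with explicit stratum dummy columns (statsmodels GLM).

    Exists as the exactness oracle for the absorbed implementation; use on
    small problems only.
    """
    import statsmodels.api as sm

    y, X, strata = design.y, design.X, design.strata
    uniq, codes = _group_codes(strata)
    group_y = np.bincount(codes, weights=y, minlength=len(uniq))
    live = group_y[codes] > 0
    yl, Xl, cl = y[live], X[live], codes[live]
    live_uniq, cl = np.unique(cl, return_inverse=True)
    D = np.zeros((len(yl), len(live_uniq)))
    D[np.arange(len(yl)), cl] = 1.0
    full = np.hstack([Xl, D])
    res = sm.GLM(yl, full, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-12)
    k = X.shape[1]
    p = k + len(uniq)
    mu = res.fittedvalues
    fitted = np.zeros(len(y))
    fitted[live] = mu
    phi = estimate_dispersion(y, fitted, p)
    vcov = phi * np.asarray(res.normalized_cov_params)[:k, :k]
    ll = float(np.sum(yl * np.log(mu) - mu - gammaln(yl + 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        dev_terms = np.where(yl > 0, yl * np.log(yl / mu), 0.0) - (yl - mu)
    fr = FitResult(
        coef=np.asarray(res.params)[:k],
        vcov=vcov,
        dispersion=phi,
        deviance=float(2 * dev_terms.sum()),
        loglik_poisson=ll,
        qaic=np.nan,
        n_rows=len(y),
        n_strata=len(uniq),
        n_params=p,
        converged=bool(res.converged),
        column_map=dict(design.column_map),
        fitted=fitted,
        y=y,
        pearson_chi2=float(np.sum((yl - mu) ** 2 / mu)),
    )
    fr.qaic = qaic(fr)
    return fr


def estimate_dispersion(y: np.ndarray, fitted: np.ndarray, n_params: int) -> float:
    """Pearson dispersion ``phi = sum (y-mu)^2/mu / (n - p)``.

    Rows with fitted mean exactly zero (degenerate strata) have zero observed
    counts and contribute nothing to the numerator.
    """
    y = np.asarray(y, float)
    mu = np.asarray(fitted, float)
    n = len(y)
    if n <= n_params:
        raise ValueError(f"cannot estimate dispersion with n={n} <= p={n_params}")
    pos = mu > 0
    chi2 = float(np.sum((y[pos] - mu[pos]) ** 2 / mu[pos]))
    if chi2 == 0.0:
        import warnings

        warnings.warn("saturated fit: Pearson chi-square is exactly zero", stacklevel=2)
    return chi2 / (n - n_params)


def qaic(fit: FitResult, dispersion: Optional[float] = None) -> float:
    """Quasi-AIC: ``-2 * loglik_Poisson(beta) + 2 * p * phi``.

    ``dispersion`` overrides the fit's own estimate — used when ranking a
    sensitivity grid with the dispersion of the largest candidate model.
    Comparable only across models on identical rows.
    """
    phi = fit.dispersion if dispersion is None else float(dispersion)
    return -2.0 * fit.loglik_poisson + 2.0 * fit.n_params * phi
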