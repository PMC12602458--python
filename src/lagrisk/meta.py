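"""Multivariate random-effects meta-analysis of district-level summaries.

Second stage of the two-stage design: district estimates ``y_i`` with
within-district covariances ``S_i`` are modelled as

    y_i ~ N(mu, S_i + Psi)

with the between-district covariance ``Psi`` estimated by REML on a
log-Cholesky parameterisation (quasi-Newton), falling back to a
method-of-moments estimate when the optimiser fails.  The pooled mean is the
generalised-least-squares estimate ``mu = (sum W_i)^-1 sum W_i y_i`` with
``W_i = (S_i + Psi)^-1``.  Cochran's Q and I^2 quantify residual
heterogeneity relative to the fixed-effect (Psi = 0) fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist

from .predict import ReducedCoef, RRTable, ERCurve, predict_from_reduced

__all__ = ["MetaResult", "meta_fit", "heterogeneity", "pool_predict"]

log = logging.getLogger(__name__)


@dataclass
class MetaResult:
    pooled: np.ndarray
    vcov: np.ndarray
    between_cov: np.ndarray
    q_stat: float
    q_df: int
    q_pvalue: float
    i2: float
    n_units: int
    method: str
    converged: bool
    basis_meta: dict
    kind: Optional[str] = None


def _as_arrays(estimates: Sequence) -> Tuple[List[np.ndarray], List[np.ndarray]]:
    ys, Ss = [], []
    for est in estimates:
        if isinstance(est, ReducedCoef):
            ys.append(np.atleast_1d(np.asarray(est.coef, float)))
            Ss.append(np.atleast_2d(np.asarray(est.vcov, float)))
        else:
            y, S = est
            ys.append(np.atleast_1d(np.asarray(y, float)))
            Ss.append(np.atleast_2d(np.asarray(S, float)))
    k = len(ys[0])
    if any(len(y) != k for y in ys) or any(S.shape != (k, k) for S in Ss):
        raise ValueError("estimates have non-conformable dimensions")
    return ys, Ss


def _gls(ys, Ss, Psi):
    """GLS pooled mean and its covariance for a given Psi."""
    k = len(ys[0])
    Wsum = np.zeros((k, k))
    Wy = np.zeros(k)
    Ws = []
    for y, S in zip(ys, Ss):
        W = np.linalg.inv(S + Psi)
        Ws.append(W)
        Wsum += W
        Wy += W @ y
    try:
        vcov = np.linalg.inv(Wsum)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular weight sum across units: {e}") from e
    return vcov @ Wy, vcov, Ws


def _psi_from_theta(theta: np.ndarray, k: int) -> np.ndarray:
    """log-Cholesky: diag entries exponentiated, lower triangle free."""
    Lm = np.zeros((k, k))
    idx = np.tril_indices(k)
    Lm[idx] = theta
    Lm[np.diag_indices(k)] = np.exp(np.diag(Lm))
    return Lm @ Lm.T


def _theta_from_psi(Psi: np.ndarray) -> np.ndarray:
    k = Psi.shape[0]
    # nearest-PSD then Cholesky with jitter for a safe start
    w, V = np.linalg.eigh((Psi + Psi.T) / 2)
    w = np.clip(w, 1e-10, None)
    Lm = np.linalg.cholesky(V @ np.diag(w) @ V.T + 1e-12 * np.eye(k))
    Lm = Lm.copy()
    Lm[np.diag_indices(k)] = np.log(np.diag(Lm))
    return Lm[np.tril_indices(k)]


def _neg_reml(theta, ys, Ss):
    k = len(ys[0])
    Psi = _psi_from_theta(np.asarray(theta), k)
    Wsum = np.zeros((k, k))
    Wy = np.zeros(k)
    logdet = 0.0
    Ws = []
    for y, S in zip(ys, Ss):
        V = S + Psi
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return 1e12
        logdet += ld
        W = np.linalg.inv(V)
        Ws.append(W)
        Wsum += W
        Wy += W @ y
    sign, ld_w = np.linalg.slogdet(Wsum)
    if sign <= 0:
        return 1e12
    mu = np.linalg.solve(Wsum, Wy)
    quad = sum(float((y - mu) @ W @ (y - mu)) for y, W in zip(ys, Ws))
    return 0.5 * (logdet + ld_w + quad)


def _psi_mom(ys, Ss) -> np.ndarray:
    """Moment estimate: covariance of estimates minus mean within-unit
    covariance, projected onto the PSD cone."""
    Y = np.vstack(ys)
    n = len(ys)
    if n < 2:
        return np.zeros((Y.shape[1],) * 2)
    emp = np.cov(Y, rowvar=False, ddof=1)
    emp = np.atleast_2d(emp)
    Psi = emp - sum(Ss) / n
    w, V = np.linalg.eigh((Psi + Psi.T) / 2)
    return V @ np.diag(np.clip(w, 0.0, None)) @ V.T


def meta_fit(estimates: Sequence, method: str = "reml") -> MetaResult:
    """Pool unit-level (coef, vcov) estimates under a random-effects model.

    ``method``: ``"reml"`` (default), ``"mom"`` or ``"fixed"`` (Psi forced to
    zero — the inverse-variance-weighted limit).
    """
    ys, Ss = _as_arrays(estimates)
    n = len(ys)
    if n < 2:
        raise ValueError("meta-analysis needs at least 2 units")
    k = len(ys[0])

    basis_meta, kind = {}, None
    for est in estimates:
        if isinstance(est, ReducedCoef):
            basis_meta, kind = est.basis_meta, est.kind
            break

    converged = True
    if method == "fixed":
        Psi = np.zeros((k, k))
        used = "fixed"
    elif method == "mom":
        Psi = _psi_mom(ys, Ss)
        used = "mom"
    elif method == "reml":
        theta0 = _theta_from_psi(_psi_mom(ys, Ss) + 1e-8 * np.eye(k))
        res = minimize(
            _neg_reml,
            theta0,
            args=(ys, Ss),
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if res.success or res.fun < _neg_reml(theta0, ys, Ss):
            Psi = _psi_from_theta(res.x, k)
            used = "reml"
            converged = bool(res.success)
        else:
            log.warning("REML optimisation failed (%s); method-of-moments fallback", res.message)
            Psi = _psi_mom(ys, Ss)
            used = "mom"
            converged = False
    else:
        raise ValueError(f"unknown meta method {method!r}")

    pooled, vcov, _ = _gls(ys, Ss, Psi)
    q, qdf, qp, i2 = _q_stats(ys, Ss)
    return MetaResult(
        pooled=pooled,
        vcov=vcov,
        between_cov=Psi,
        q_stat=q,
        q_df=qdf,
        q_pvalue=qp,
        i2=i2,
        n_units=n,
        method=used,
        converged=converged,
        basis_meta=basis_meta,
        kind=kind,
    )


def _q_stats(ys, Ss):
    mu_fe, _, Ws = _gls(ys, Ss, np.zeros((len(ys[0]),) * 2))
    q = sum(float((y - mu_fe) @ np.linalg.inv(S) @ (y - mu_fe)) for y, S in zip(ys, Ss))
    qdf = (len(ys) - 1) * len(ys[0])
    i2 = max(0.0, (q - qdf) / q) * 100.0 if q > 0 else 0.0
    qp = float(chi2_dist.sf(q, qdf)) if qdf > 0 else float("nan")
    return float(q), int(qdf), qp, i2


def heterogeneity(estimates: Sequence, meta: Optional[MetaResult] = None):
    """Cochran's Q (from the fixed-effect fit), its df, and I^2 in percent."""
    ys, Ss = _as_arrays(estimates)
    q, qdf, _, i2 = _q_stats(ys, Ss)
    return q, qdf, i2


def pool_predict(meta: MetaResult, basis_meta: Optional[dict] = None, grid=None):
    """Region-level RR table / exposure-response curve from pooled coefficients."""
    red = ReducedCoef(
        kind=meta.kind,
        coef=meta.pooled,
        vcov=meta.vcov,
        basis_meta=basis_meta or meta.basis_meta,
    )
    if red.kind is None:
        raise ValueError("meta result carries no reduction metadata")
    return predict_from_reduced(red, grid=grid)
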