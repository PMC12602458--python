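"""Relative-risk summaries from a fitted crossbasis.

Given the coefficient block B (exposure dimension x lag dimension) of a
fitted crossbasis, the lag-specific log relative risk at an exposure contrast
``x1 vs x0`` is ``[R(x1) - R(x0)]' B C(l)`` and the cumulative (overall)
log RR at exposure ``x`` is the sum of that quantity over lags.  Standard
errors follow by the delta method: every summary is a linear contrast
``m' beta`` of the crossbasis coefficients, so ``se = sqrt(m' V m)``.
Reductions project the full coefficient vector and covariance onto the lag
dimension (lag-wise curve at a stated increment) or the exposure dimension
(cumulative exposure-response), the per-district summaries pooled in the
second stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .basis import Crossbasis

__all__ = [
    "Z95",
    "RRTable",
    "ERCurve",
    "ReducedCoef",
    "predict_lag_rr",
    "predict_overall_curve",
    "reduce_fit",
]

# normal 97.5% quantile; significance = 95% CI excluding RR 1
Z95 = 1.959964


@dataclass
class RRTable:
    """Lag-specific relative risks at a stated exposure increment."""

    lag: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    increment: float
    reference: float

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + Z95 * self.se)

    @property
    def significant(self) -> np.ndarray:
        return (self.rr_low > 1.0) | (self.rr_high < 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lag,
                "rr": self.rr,
                "lo": self.rr_low,
                "hi": self.rr_high,
                "log_rr": self.log_rr,
                "se": self.se,
            }
        )


@dataclass
class ERCurve:
    """Cumulative exposure-response curve from a reference level."""

    exposure_grid: np.ndarray
    log_rr: np.ndarray
    se: np.ndarray
    reference: float
    cumulative: bool = True

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    @property
    def rr_low(self) -> np.ndarray:
        return np.exp(self.log_rr - Z95 * self.se)

    @property
    def rr_high(self) -> np.ndarray:
        return np.exp(self.log_rr + Z95 * self.se)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposure_grid,
                "rr": self.rr,
                "lo": self.rr_low,
                "hi": self.rr_high,
                "log_rr": self.log_rr,
                "se": self.se,
            }
        )


@dataclass
class ReducedCoef:
    """Projected coefficient vector and covariance for second-stage pooling.

    ``kind``:
      - ``lag_specific_at_increment``: dimension = lag-basis columns; the
        lag-wise log-RR curve at the stated increment is ``C @ coef``.
      - ``exposure_response``: dimension = exposure-basis columns; the
        cumulative log RR at exposure x is ``[R(x)-R(ref)] @ coef``.
      - ``overall_cumulative``: scalar cumulative log RR at the increment.
    """

    kind: str
    coef: np.ndarray
    vcov: np.ndarray
    basis_meta: Dict = field(default_factory=dict)
    unit: Optional[str] = None


def _coef_block(fit, term: str):
    sl = fit.column_map[term]
    return fit.coef[sl], fit.vcov[sl, sl]


def _check_support(cb: Crossbasis, value: float):
    lo, hi = cb.exposure_basis.boundary
    if value < lo or value > hi:
        import warnings

        warnings.warn(
            f"prediction value {value} outside basis support [{lo}, {hi}]; extrapolating",
            stacklevel=3,
        )


def predict_lag_rr(
    fit,
    cb: Crossbasis,
    increment: float,
    reference: float = 0.0,
    term: str = "pollutant",
) -> RRTable:
    """Lag-specific RR per ``increment`` units above ``reference``."""
    if increment <= 0:
        raise ValueError("increment must be positive")
    _check_support(cb, reference + increment)
    beta, V = _coef_block(fit, term)
    vx, vk = cb.vx, cb.vk
    dR = cb.exposure_contrast(reference + increment, reference)[0]  # (vx,)
    C = cb.lag_values  # (L+1, vk)
    M = np.array([np.kron(dR, C[l]) for l in range(C.shape[0])])  # (L+1, vx*vk)
    log_rr = M @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", M, V, M))
    assert M.shape[1] == vx * vk
    return RRTable(
        lag=np.arange(C.shape[0]),
        log_rr=log_rr,
        se=se,
        increment=float(increment),
        reference=float(reference),
    )


def predict_overall_curve(
    fit,
    cb: Crossbasis,
    grid=None,
    reference: float = 0.0,
    term: str = "pollutant",
) -> ERCurve:
    """Cumulative exposure-response curve on ``grid`` (default: 0..observed max)."""
    beta, V = _coef_block(fit, term)
    if grid is None:
        grid = np.linspace(0.0, cb.exposure_basis.boundary[1], 50)
    grid = np.asarray(grid, float)
    dR = cb.exposure_contrast(grid, reference)  # (g, vx)
    csum = cb.lag_values.sum(axis=0)  # (vk,)
    M = np.array([np.kron(dR[i], csum) for i in range(len(grid))])
    log_rr = M @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", M, V, M))
    return ERCurve(
        exposure_grid=grid, log_rr=log_rr, se=se, reference=float(reference)
    )


def reduce_fit(
    fit,
    cb: Crossbasis,
    kind: str,
    at: Optional[float] = None,
    reference: float = 0.0,
    term: str = "pollutant",
    unit: Optional[str] = None,
) -> ReducedCoef:
    """Project the crossbasis coefficients to a one-dimensional summary.

    The reduction is a linear map ``M``: reduced coef = ``M beta`` and reduced
    vcov = ``M V M'``, so predicting from the reduced object reproduces the
    prediction from the full fit on the defining grid exactly.
    """
    beta, V = _coef_block(fit, term)
    vx, vk = cb.vx, cb.vk
    C = cb.lag_values
    if kind == "lag_specific_at_increment":
        if at is None:
            raise ValueError("lag_specific_at_increment needs `at` (the increment)")
        dR = cb.exposure_contrast(reference + at, reference)[0]
        # beta is laid out exposure-outer: coef_k = sum_j dR_j beta[j*vk+k]
        M = np.kron(dR[None, :], np.eye(vk)).reshape(vk, vx * vk)
        meta = {"lag_values": C, "increment": at, "reference": reference}
    elif kind == "exposure_response":
        csum = C.sum(axis=0)
        M = np.kron(np.eye(vx), csum[None, :]).reshape(vx, vx * vk)
        meta = {
            "exposure_basis": cb.exposure_basis,
            "reference": reference,
            "max_exposure": cb.exposure_basis.boundary[1],
        }
    elif kind == "overall_cumulative":
        if at is None:
            raise ValueError("overall_cumulative needs `at` (the increment)")
        dR = cb.exposure_contrast(reference + at, reference)[0]
        M = np.kron(dR, C.sum(axis=0))[None, :]
        meta = {"increment": at, "reference": reference}
    else:
        raise ValueError(f"unknown reduction kind {kind!r}")
    coef = M @ beta
    vcov = M @ V @ M.T
    return ReducedCoef(kind=kind, coef=coef, vcov=np.atleast_2d(vcov), basis_meta=meta, unit=unit)


def predict_from_reduced(red: ReducedCoef, grid=None) -> "RRTable | ERCurve":
    """Evaluate a reduced summary: lag curve or cumulative exposure-response."""
    if red.kind == "lag_specific_at_increment":
        C = red.basis_meta["lag_values"]
        log_rr = C @ red.coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", C, red.vcov, C))
        return RRTable(
            lag=np.arange(C.shape[0]),
            log_rr=log_rr,
            se=se,
            increment=float(red.basis_meta["increment"]),
            reference=float(red.basis_meta["reference"]),
        )
    if red.kind == "exposure_response":
        ob = red.basis_meta["exposure_basis"]
        ref = red.basis_meta["reference"]
        if grid is None:
            grid = np.linspace(0.0, red.basis_meta["max_exposure"], 50)
        grid = np.asarray(grid, float)
        dR = ob.transform(grid) - ob.transform(np.full_like(grid, ref))
        log_rr = dR @ red.coef
        se = np.sqrt(np.einsum("ij,jk,ik->i", dR, red.vcov, dR))
        return ERCurve(exposure_grid=grid, log_rr=log_rr, se=se, reference=float(ref))
    if red.kind == "overall_cumulative":
        return RRTable(
            lag=np.array([0]),
            log_rr=red.coef.copy(),
            se=np.sqrt(np.diag(red.vcov)),
            increment=float(red.basis_meta["increment"]),
            reference=float(red.basis_meta["reference"]),
        )
    raise ValueError(f"unknown reduction kind {red.kind!r}")
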