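"""One-dimensional basis functions and the bi-dimensional crossbasis.

A distributed-lag non-linear model represents the effect of an exposure
series ``x`` on an outcome as a surface ``f(x, lag)`` that is smooth both in
exposure intensity and in lag time.  The surface is parameterised through a
*crossbasis*: the tensor product of an exposure-dimension basis ``R`` (linear,
natural cubic spline or step function) evaluated on lagged exposures, and a
lag-dimension basis ``C`` evaluated on the integer lag grid ``0..L``.  Column
``(j, k)`` of the crossbasis at day ``t`` is

    sum_{l=0}^{L} R_j(x[t-l]) * C_k(l)

so that a coefficient vector on the crossbasis columns encodes the full
exposure-lag-response surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

__all__ = [
    "BasisSpec",
    "CrossbasisSpec",
    "OneBasis",
    "Crossbasis",
    "logknots",
    "build_onebasis",
    "build_lag_matrix",
    "build_crossbasis",
]

_VALID_FUNS = ("linear", "ns", "strata")


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional basis.

    Parameters
    ----------
    fun:
        ``"linear"`` (identity, one column), ``"ns"`` (natural cubic spline,
        linear beyond the boundary knots) or ``"strata"`` (disjoint interval
        indicators).
    df:
        Number of basis columns (excluding the intercept column unless
        ``intercept`` is set).  For ``ns`` without explicit knots, ``df - 1``
        internal knots are placed at equally spaced quantiles of the data.
    knots:
        Internal knots (``ns``) or interval cut points (``strata``).  When
        given for ``ns``, ``df`` is implied as ``len(knots) + 1 + intercept``.
    boundary:
        Boundary knot pair for ``ns``; defaults to the data range.
    intercept:
        Whether the basis spans the constant function explicitly.
    """

    fun: str
    df: Optional[int] = None
    knots: Optional[tuple] = None
    boundary: Optional[tuple] = None
    intercept: bool = False

    def __post_init__(self):
        if self.fun not in _VALID_FUNS:
            raise ValueError(f"unknown basis fun {self.fun!r}; expected one of {_VALID_FUNS}")
        if self.knots is not None:
            object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
            if any(b >= a for a, b in zip(self.knots[1:], self.knots[:-1])):
                raise ValueError("knots must be strictly increasing")
        if self.boundary is not None:
            b = tuple(float(v) for v in self.boundary)
            if len(b) != 2 or b[0] >= b[1]:
                raise ValueError("boundary must be an increasing pair")
            object.__setattr__(self, "boundary", b)
        if self.fun == "linear":
            if self.df not in (None, 1):
                raise ValueError("linear basis has df=1")
            if self.knots:
                raise ValueError("linear basis takes no knots")
        if self.fun == "ns" and self.knots is not None and self.boundary is not None:
            if not (self.boundary[0] < self.knots[0] and self.knots[-1] < self.boundary[1]):
                raise ValueError("internal knots must lie strictly inside the boundary")

    @property
    def ncol(self) -> Optional[int]:
        """Number of basis columns, if determined by the spec alone."""
        if self.fun == "linear":
            return 1 + int(self.intercept)
        if self.fun == "ns":
            if self.knots is not None:
                return len(self.knots) + 1 + int(self.intercept)
            return self.df
        if self.knots is not None:  # strata
            return len(self.knots) + int(self.intercept)
        return self.df


def logknots(max_lag: int, n_knots: int) -> np.ndarray:
    """Knot locations equally spaced on the log-lag scale.

    Places ``n_knots`` values strictly inside ``(0, max_lag]`` at
    ``exp(log(max_lag) * i / (n_knots + 1))`` for ``i = 1..n_knots``, i.e.
    equally spaced between lag 1 (log 0) and lag ``max_lag`` on the log scale.
    """
    max_lag = int(max_lag)
    n_knots = int(n_knots)
    if max_lag < 2:
        raise ValueError("max_lag must be at least 2")
    if n_knots < 1 or n_knots >= max_lag:
        raise ValueError("need 1 <= n_knots < max_lag")
    i = np.arange(1, n_knots + 1)
    return np.exp(np.log(max_lag) * i / (n_knots + 1))


class OneBasis:
    """A basis resolved against data: knots fixed, reusable on new grids.

    Use :meth:`fit` on the training values; :meth:`transform` then evaluates
    the identical basis functions anywhere (prediction grids, lag grids).
    """

    def __init__(self, spec: BasisSpec, knots: np.ndarray, boundary: tuple):
        self.spec = spec
        self.knots = np.asarray(knots, dtype=float)
        self.boundary = boundary
        self._Z = None  # ns constraint null-space, built lazily
        if spec.fun == "ns":
            self._Z = self._ns_nullspace()

    # -- construction -----------------------------------------------------

    @classmethod
    def fit(cls, x: Sequence[float], spec: BasisSpec) -> "OneBasis":
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("basis input contains non-finite values")
        if spec.fun == "linear":
            return cls(spec, np.empty(0), (float(x.min()), float(x.max())))
        if spec.fun == "strata":
            if spec.knots is not None:
                knots = np.asarray(spec.knots, float)
            else:
                # df intervals -> df-1+intercept... equally spaced quantile cuts
                ncut = (spec.df or 1) + (0 if spec.intercept else 1) - 1
                qs = np.linspace(0, 1, ncut + 2)[1:-1]
                knots = np.unique(np.quantile(x, qs))
            return cls(spec, knots, (float(x.min()), float(x.max())))
        # ns
        boundary = spec.boundary or (float(x.min()), float(x.max()))
        if spec.knots is not None:
            knots = np.asarray(spec.knots, float)
        else:
            if spec.df is None:
                raise ValueError("ns basis needs df or knots")
            n_int = spec.df - 1 - int(spec.intercept)
            if n_int < 0:
                raise ValueError("ns df too small for requested intercept")
            qs = np.linspace(0, 1, n_int + 2)[1:-1]
            knots = np.unique(np.quantile(x, qs))
        inside = (knots > boundary[0]) & (knots < boundary[1])
        if not inside.all():
            import warnings

            warnings.warn("ns knots outside the data/boundary range", stacklevel=2)
            knots = knots[inside]
        return cls(spec, knots, boundary)

    # -- ns internals ------------------------------------------------------

    def _bspline_knot_vector(self) -> np.ndarray:
        b0, b1 = self.boundary
        return np.r_[[b0] * 4, self.knots, [b1] * 4]

    def _ns_nullspace(self) -> np.ndarray:
        """Null space of the natural constraints on B-spline coefficients.

        Constraints: zero second derivative at both boundary knots; without an
        intercept, additionally orthogonality of the coefficient vector to the
        constant function's coefficients (all ones, by partition of unity),
        which complements the constant in the natural-spline space.
        """
        t = self._bspline_knot_vector()
        nb = len(self.knots) + 4
        eye = np.eye(nb)
        d2 = BSpline(t, eye, 3).derivative(2)
        cons = np.vstack([d2(self.boundary[0]), d2(self.boundary[1])])
        if not self.spec.intercept:
            cons = np.vstack([cons, np.ones(nb)])
        Z = null_space(cons)
        if Z.shape[1] != self.ncol:
            raise RuntimeError("ns constraint null space has unexpected dimension")
        return Z

    # -- evaluation --------------------------------------------------------

    @property
    def ncol(self) -> int:
        fun = self.spec.fun
        if fun == "linear":
            return 1 + int(self.spec.intercept)
        if fun == "ns":
            return len(self.knots) + 1 + int(self.spec.intercept)
        return len(self.knots) + int(self.spec.intercept)

    def transform(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        x = np.atleast_1d(x)
        if not np.all(np.isfinite(x)):
            raise ValueError("basis input contains non-finite values")
        fun = self.spec.fun
        if fun == "linear":
            cols = [x]
            if self.spec.intercept:
                cols = [np.ones_like(x)] + cols
            out = np.column_stack(cols)
        elif fun == "strata":
            out = self._strata(x)
        else:
            out = self._ns(x)
        return out[0] if scalar else out

    def _strata(self, x: np.ndarray) -> np.ndarray:
        # left-closed right-open intervals; lowest interval is the reference
        # (dropped) unless an intercept is requested
        edges = np.r_[-np.inf, self.knots, np.inf]
        idx = np.searchsorted(self.knots, x, side="right")  # interval index 0..m
        n_int = len(self.knots) + 1
        full = np.zeros((len(x), n_int))
        full[np.arange(len(x)), idx] = 1.0
        del edges
        return full if self.spec.intercept else full[:, 1:]

    def _ns(self, x: np.ndarray) -> np.ndarray:
        b0, b1 = self.boundary
        t = self._bspline_knot_vector()
        nb = len(self.knots) + 4
        eye = np.eye(nb)
        spl = BSpline(t, eye, 3)
        d1 = spl.derivative(1)
        xc = np.clip(x, b0, b1)
        B = spl(xc)
        # natural splines are linear beyond the boundary knots
        lo, hi = x < b0, x > b1
        if lo.any():
            B[lo] = spl(b0) + np.outer(x[lo] - b0, d1(b0))
        if hi.any():
            B[hi] = spl(b1) + np.outer(x[hi] - b1, d1(b1))
        return B @ self._Z


def build_onebasis(x: Sequence[float], spec: BasisSpec) -> np.ndarray:
    """Evaluate the basis defined by ``spec`` on ``x`` (knots from ``x``)."""
    return OneBasis.fit(x, spec).transform(x)


def build_lag_matrix(x: Sequence[float], max_lag: int) -> np.ndarray:
    """Matrix ``Q`` with ``Q[t, l] = x[t - l]``; NaN where history is missing.

    Assumes a single unit's series at regular daily spacing in time order.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    L = int(max_lag)
    if L < 0:
        raise ValueError("max_lag must be non-negative")
    n = len(x)
    Q = np.full((n, L + 1), np.nan)
    for lag in range(L + 1):
        Q[lag:, lag] = x[: n - lag]
    return Q


@dataclass(frozen=True)
class CrossbasisSpec:
    """Exposure basis x lag basis over lags ``0..max_lag``."""

    exposure: BasisSpec
    lag: BasisSpec
    max_lag: int

    def __post_init__(self):
        if self.max_lag < 0:
            raise ValueError("max_lag must be non-negative")


@dataclass
class Crossbasis:
    """Evaluated crossbasis for one unit's series.

    ``values[t, j*vk + k] = sum_l R_j(x[t-l]) C_k(l)`` — exposure index outer,
    lag index inner.  The first ``max_lag`` rows lack full lag history and are
    flagged via ``first_valid_row``; downstream design assembly drops them.
    """

    values: np.ndarray
    spec: CrossbasisSpec
    exposure_basis: OneBasis
    lag_basis: OneBasis
    lag_values: np.ndarray = field(repr=False)  # (L+1, vk) lag basis on 0..L
    first_valid_row: int = 0

    @property
    def vx(self) -> int:
        return self.exposure_basis.ncol

    @property
    def vk(self) -> int:
        return self.lag_basis.ncol

    def exposure_contrast(self, value, reference: float) -> np.ndarray:
        """Row(s) of ``R(value) - R(reference)``."""
        v = np.atleast_1d(np.asarray(value, float))
        return self.exposure_basis.transform(v) - self.exposure_basis.transform(
            np.full_like(v, reference)
        )


def build_crossbasis(x: Sequence[float], spec: CrossbasisSpec) -> Crossbasis:
    """Construct the crossbasis of a single ordered daily series."""
    x = np.asarray(x, dtype=float)
    L = spec.max_lag
    if len(x) < L + 1:
        raise ValueError(f"series of length {len(x)} shorter than max_lag+1={L + 1}")
    exposure = OneBasis.fit(x, spec.exposure)
    lag_grid = np.arange(L + 1, dtype=float)
    # default lag-spline boundary spans the full lag range
    lag_spec = spec.lag
    if lag_spec.fun == "ns" and lag_spec.boundary is None:
        lag_spec = BasisSpec(
            fun="ns",
            df=lag_spec.df,
            knots=lag_spec.knots,
            boundary=(0.0, float(L)) if L > 0 else None,
            intercept=lag_spec.intercept,
        )
    lag_basis = OneBasis.fit(lag_grid, lag_spec)
    C = lag_basis.transform(lag_grid)  # (L+1, vk)
    Q = build_lag_matrix(x, L)  # (n, L+1) with NaN in the head rows
    Qf = np.nan_to_num(Q, nan=0.0)
    R = exposure.transform(Qf.ravel()).reshape(len(x), L + 1, exposure.ncol)
    values = np.einsum("nlj,lk->njk", R, C).reshape(len(x), exposure.ncol * lag_basis.ncol)
    values[:L] = np.nan  # incomplete history
    return Crossbasis(
        values=values,
        spec=spec,
        exposure_basis=exposure,
        lag_basis=lag_basis,
        lag_values=C,
        first_valid_row=L,
    )
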