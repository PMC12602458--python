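"""Basis construction: splines, lag matrices and the crossbasis tensor."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lagrisk.basis import (
    BasisSpec,
    CrossbasisSpec,
    OneBasis,
    build_crossbasis,
    build_lag_matrix,
    build_onebasis,
    logknots,
)


class TestLogknots:
    def test_two_knots_over_14_lags_follow_log_spacing(self):
        # equally spaced on log scale: exp(log(14) * i/3)
        expected = [14 ** (1 / 3), 14 ** (2 / 3)]
        np.testing.assert_allclose(logknots(14, 2), expected, rtol=1e-12)

    @pytest.mark.parametrize("L", [2, 5, 7, 14, 30])
    def test_single_knot_is_geometric_midpoint(self, L):
        np.testing.assert_allclose(logknots(L, 1), [np.sqrt(L)], rtol=1e-12)

    @given(L=st.integers(3, 40), nk=st.integers(1, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_strictly_increasing_and_inside_range(self, L, nk):
        if nk >= L:
            return
        k = logknots(L, nk)
        assert np.all(np.diff(k) > 0)
        assert np.all((k > 0) & (k <= L))

    @pytest.mark.parametrize("args", [(1, 1), (0, 1), (5, 5), (5, 9), (3, 0)])
    def test_invalid_arguments_rejected(self, args):
        with pytest.raises(ValueError):
            logknots(*args)


class TestOneBasis:
    def test_linear_returns_single_column(self):
        out = build_onebasis([0.0, 1.0, 2.0], BasisSpec("linear"))
        np.testing.assert_array_equal(out, [[0.0], [1.0], [2.0]])

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            build_onebasis([0.0, np.nan], BasisSpec("linear"))

    def test_ns_is_linear_at_and_beyond_boundary(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 100)
        ob = OneBasis.fit(x, BasisSpec("ns", df=4))
        grid = np.linspace(x.max(), x.max() + 5, 9)
        vals = ob.transform(grid)
        # second differences of a linear function vanish
        assert np.abs(np.diff(vals, n=2, axis=0)).max() < 1e-10
        lo = ob.transform(np.linspace(x.min() - 5, x.min(), 9))
        assert np.abs(np.diff(lo, n=2, axis=0)).max() < 1e-10

    def test_ns_span_matches_truncated_power_oracle(self):
        """Natural-spline column span equals the classic truncated-power
        construction (regression of each oracle column gives R^2 = 1)."""
        rng = np.random.default_rng(1)
        x = np.sort(rng.uniform(0, 10, 200))
        knots = (2.5, 5.0, 7.5)
        ob = OneBasis.fit(x, BasisSpec("ns", knots=knots))
        N = ob.transform(x)

        # oracle: truncated-power natural cubic spline basis (ESL form)
        b0, b1 = x.min(), x.max()
        ks = np.r_[b0, knots, b1]

        def d(j, xx):
            return (np.maximum(xx - ks[j], 0) ** 3 - np.maximum(xx - ks[-1], 0) ** 3) / (
                ks[-1] - ks[j]
            )

        oracle = np.column_stack([x] + [d(j, x) - d(len(ks) - 2, x) for j in range(len(ks) - 2)])
        design = np.column_stack([np.ones_like(x), N])
        for col in oracle.T:
            beta, *_ = np.linalg.lstsq(design, col, rcond=None)
            resid = col - design @ beta
            r2 = 1 - resid @ resid / np.sum((col - col.mean()) ** 2)
            assert r2 > 1 - 1e-10

    def test_ns_df_gives_requested_column_count(self):
        x = np.linspace(0, 1, 50)
        for df in (2, 3, 4):
            assert build_onebasis(x, BasisSpec("ns", df=df)).shape[1] == df

    def test_strata_columns_are_disjoint_indicators(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        out = build_onebasis(x, BasisSpec("strata", knots=(1.5, 3.5)))
        # reference interval (lowest) absorbed: two indicator columns
        assert out.shape == (5, 2)
        np.testing.assert_array_equal(out.sum(axis=1) <= 1, True)
        np.testing.assert_array_equal(out[:, 0], [0, 0, 1, 1, 0])
        np.testing.assert_array_equal(out[:, 1], [0, 0, 0, 0, 1])

    def test_strata_with_intercept_partitions_unity(self):
        x = np.linspace(0, 10, 40)
        out = build_onebasis(x, BasisSpec("strata", knots=(3.0, 7.0), intercept=True))
        np.testing.assert_array_equal(out.sum(axis=1), np.ones(40))

    def test_unknown_fun_rejected(self):
        with pytest.raises(ValueError):
            BasisSpec("cubic")

    def test_decreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            BasisSpec("ns", knots=(3.0, 1.0))


class TestLagMatrix:
    def test_basic_shift_example(self):
        Q = build_lag_matrix([5.0, 6.0, 7.0], 1)
        assert np.isnan(Q[0, 1])
        np.testing.assert_array_equal(Q[:, 0], [5, 6, 7])
        np.testing.assert_array_equal(Q[1:, 1], [5, 6])

    def test_zero_lag_is_identity(self):
        x = np.arange(5.0)
        np.testing.assert_array_equal(build_lag_matrix(x, 0), x[:, None])

    @given(st.integers(0, 6))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_columns_are_shifts(self, L):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(50)
        Q = build_lag_matrix(x, L)
        for lag in range(L + 1):
            np.testing.assert_array_equal(Q[lag:, lag], x[: 50 - lag])
            assert np.isnan(Q[:lag, lag]).all()


class TestCrossbasis:
    def test_linear_exposure_single_stratum_is_moving_sum(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(3, 5, 60)
        spec = CrossbasisSpec(
            BasisSpec("linear"), BasisSpec("strata", intercept=True, df=1), 3
        )
        cb = build_crossbasis(x, spec)
        ms = np.convolve(x, np.ones(4), "full")[:60]
        np.testing.assert_allclose(cb.values[3:, 0], ms[3:], rtol=1e-12)
        assert np.isnan(cb.values[:3]).all()

    def test_zero_max_lag_linear_is_identity(self):
        x = np.array([1.0, 4.0, 2.0])
        cb = build_crossbasis(
            x, CrossbasisSpec(BasisSpec("linear"), BasisSpec("strata", intercept=True, df=1), 0)
        )
        np.testing.assert_allclose(cb.values[:, 0], x)

    def test_matches_bruteforce_quadruple_loop(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(3, 6, 200)
        spec = CrossbasisSpec(
            BasisSpec("ns", df=3),
            BasisSpec("ns", knots=tuple(logknots(7, 2)), intercept=True),
            7,
        )
        cb = build_crossbasis(x, spec)
        R = cb.exposure_basis.transform(x)
        C = cb.lag_values
        for t in range(7, 200, 13):
            for j in range(cb.vx):
                for k in range(cb.vk):
                    want = sum(R[t - l, j] * C[l, k] for l in range(8))
                    assert abs(cb.values[t, j * cb.vk + k] - want) < 1e-10

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_crossbasis(
                np.ones(3), CrossbasisSpec(BasisSpec("linear"), BasisSpec("linear"), 5)
            )

    @pytest.mark.parametrize(
        "exp_spec,lag_spec,L",
        [
            (BasisSpec("linear"), BasisSpec("ns", df=3, intercept=True), 7),
            (BasisSpec("ns", df=2), BasisSpec("ns", df=3, intercept=True), 3),
            (BasisSpec("ns", df=4), BasisSpec("ns", knots=tuple(logknots(14, 2)), intercept=True), 14),
            (BasisSpec("ns", df=3), BasisSpec("strata", knots=(3.0, 10.0), intercept=True), 10),
        ],
    )
    def test_column_count_is_product_of_dimensions(self, exp_spec, lag_spec, L):
        rng = np.random.default_rng(4)
        x = rng.gamma(3, 6, 120)
        cb = build_crossbasis(x, CrossbasisSpec(exp_spec, lag_spec, L))
        assert cb.values.shape[1] == cb.vx * cb.vk

    def test_unconstrained_lag_basis_reduces_to_classical_dlm(self):
        """Per-lag indicator lag basis makes the crossbasis columns exactly
        the lagged exposure-basis columns."""
        rng = np.random.default_rng(5)
        x = rng.gamma(3, 6, 80)
        L = 4
        spec = CrossbasisSpec(
            BasisSpec("linear"),
            BasisSpec("strata", knots=tuple(range(1, L + 1)), intercept=True),
            L,
        )
        cb = build_crossbasis(x, spec)
        Q = build_lag_matrix(x, L)
        np.testing.assert_allclose(cb.values[L:], Q[L:], rtol=1e-12)

    def test_linearity_in_exposure_basis(self):
        """Crossbasis equals exposure basis evaluated on lags then weighted
        by the lag basis: doubling the exposure-basis output doubles the
        crossbasis (tensor construction is linear in R)."""
        rng = np.random.default_rng(6)
        x = rng.gamma(3, 6, 100)
        spec = CrossbasisSpec(BasisSpec("linear"), BasisSpec("ns", df=3, intercept=True), 5)
        cb1 = build_crossbasis(x, spec)
        cb2 = build_crossbasis(2 * x, spec)
        np.testing.assert_allclose(cb2.values[5:], 2 * cb1.values[5:], rtol=1e-10)
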