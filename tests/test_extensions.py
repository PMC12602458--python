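"""Stratified runs, bi-pollutant models, nested heterogeneity, Q-AIC grid."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lagrisk import (
    AnalysisConfig,
    BasisSpec,
    BiPollutantSpec,
    ScenarioConfig,
    TrueSurface,
    gen_environment,
    gen_outcomes,
    merge_panels,
    two_stage,
)
from lagrisk.extensions import (
    default_grid,
    fit_bipollutant,
    heterogeneity_test,
    run_stratified,
    sensitivity_grid,
)
from lagrisk.fit import fit_quasipoisson_cc
from lagrisk.pipeline import build_district_design
from lagrisk.predict import RRTable, predict_lag_rr
from lagrisk.design import season_of


class TestZTest:
    def test_equal_estimates_give_null(self):
        from lagrisk import ztest_effect_modification

        z, p = ztest_effect_modification(0.05, 0.01, 0.05, 0.02)
        assert z == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        from lagrisk import ztest_effect_modification

        z, p = ztest_effect_modification(0.1, 0.05, 0.0, 0.05)
        assert z == pytest.approx(0.1 / np.sqrt(0.005), rel=1e-6)
        assert z == pytest.approx(1.4142, abs=1e-4)
        assert p == pytest.approx(0.1573, abs=1e-4)

    def test_antisymmetric_in_group_order(self):
        from lagrisk import ztest_effect_modification

        z1, p1 = ztest_effect_modification(0.2, 0.1, -0.1, 0.2)
        z2, p2 = ztest_effect_modification(-0.1, 0.2, 0.2, 0.1)
        assert z1 == -z2 and p1 == p2

    def test_nonpositive_se_rejected(self):
        from lagrisk import ztest_effect_modification

        with pytest.raises(ValueError):
            ztest_effect_modification(0.1, 0.0, 0.0, 0.1)


class TestStratified:
    def test_all_inclusive_level_reproduces_main_model(self, small_panel, fast_config):
        panel, _ = small_panel
        main = two_stage(panel, fast_config)
        srun = run_stratified(panel, fast_config, "all")
        np.testing.assert_allclose(
            srun.results["all"].rr.log_rr, main.rr.log_rr, atol=1e-12
        )

    def test_season_levels_partition_rows(self, small_panel, fast_config):
        panel, _ = small_panel
        seas = season_of(panel["date"])
        counts = seas.value_counts()
        assert set(counts.index) == {"winter", "spring", "summer", "autumn"}
        assert counts.sum() == len(panel)
        srun = run_stratified(panel, fast_config, "season")
        assert sum(counts[level] for level in srun.results) == len(panel)

    def test_all_urban_districts_skip_rural_level(self, small_panel, fast_config):
        panel, districts = small_panel
        d = districts.copy()
        d["urban"] = True
        srun = run_stratified(panel, fast_config, "urbanicity", districts=d)
        assert "rural" in srun.skipped
        assert "urban" in srun.results

    def test_sex_stratification_runs_both_levels_with_ztests(self, small_panel, fast_config):
        panel, _ = small_panel
        srun = run_stratified(panel, fast_config, "sex")
        assert set(srun.results) == {"male", "female"}
        zt = srun.ztests["female"]
        assert list(zt.columns) == ["lag", "z", "p"]
        assert len(zt) == 8
        # identical generative effect in both sexes: no extreme z expected
        assert np.abs(zt["z"]).max() < 4.0


class TestBiPollutant:
    def test_pm_pair_disallowed_by_default(self):
        with pytest.raises(ValueError, match="PM2.5/PM10"):
            BiPollutantSpec(primary="pm25", co="pm10")

    def test_same_pollutant_rejected(self):
        with pytest.raises(ValueError):
            BiPollutantSpec(primary="no2", co="no2")

    def test_zero_co_series_reduces_to_single_pollutant(self, small_panel, fast_config):
        panel, _ = small_panel
        sub = panel[panel.district == "D000"].reset_index(drop=True).copy()
        sub["so2"] = 0.0
        design, cb = build_district_design(sub, fast_config)
        fr = fit_quasipoisson_cc(design)
        rr_single = predict_lag_rr(fr, cb, 10.0)
        fr_bi, rr_bi = fit_bipollutant(
            sub, fast_config, BiPollutantSpec(primary="pm25", co="so2")
        )
        np.testing.assert_allclose(rr_bi.log_rr, rr_single.log_rr, atol=1e-10)

    def test_independent_co_pollutant_leaves_primary_unshifted(self, fast_config):
        """Co-pollutant unrelated to outcome and primary: adjustment moves
        the primary log RR only within Monte-Carlo noise."""
        shifts = []
        for rep in range(8):
            cfg = ScenarioConfig(seed=300 + rep, n_districts=1, n_days=1461)
            env, _ = gen_environment(cfg)
            rng = np.random.default_rng(rep)
            env = env.copy()
            env["so2"] = rng.gamma(4.0, 0.5, len(env))  # independent series
            out = gen_outcomes(env, TrueSurface.linear({"pm25": 0.003}, (0.6, 0.4)), cfg)
            sub = merge_panels(env, out)
            design, cb = build_district_design(sub, fast_config)
            fr = fit_quasipoisson_cc(design)
            rr_single = predict_lag_rr(fr, cb, 10.0)
            _, rr_bi = fit_bipollutant(
                sub, fast_config, BiPollutantSpec(primary="pm25", co="so2")
            )
            shifts.append(rr_bi.log_rr.sum() - rr_single.log_rr.sum())
        # mean shift consistent with zero
        assert abs(np.mean(shifts)) < 3 * np.std(shifts, ddof=1) / np.sqrt(len(shifts)) + 1e-3

    def test_interaction_recovers_synergy_sign(self, fast_config):
        """Generative synergy between PM2.5 and O3: the interaction model's
        primary RR evaluated at high co-exposure exceeds low co-exposure."""
        from lagrisk import PollutantEffect

        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = ScenarioConfig(seed=400 + rep, n_districts=1, n_days=1461,
                                 regional_daily_mean=5.0, frailty_shape=5.0)
            env, _ = gen_environment(cfg)
            truth = TrueSurface(
                effects={"pm25": PollutantEffect(shape="linear", scale=0.001,
                                                 lag_weights=(1.0,))},
                synergy={("pm25", "o3"): 5e-5},
            )
            out = gen_outcomes(env, truth, cfg)
            sub = merge_panels(env, out)
            bspec = BiPollutantSpec(primary="pm25", co="o3", mode="interaction")
            fr_b, _ = fit_bipollutant(sub, fast_config, bspec)
            inter = fr_b.coef_for("co_interaction")
            _, cb = build_district_design(sub, fast_config)
            # effective same-day modification per unit primary x unit co
            lag0 = cb.lag_values[0] @ inter
            hits += float(lag0 > 0)
        assert hits >= 0.8 * n_rep


class TestHeterogeneityTest:
    def _mk_fit(self, deviance, n_params, n_rows=1000, dispersion=1.0):
        from lagrisk.fit import FitResult

        return FitResult(
            coef=np.zeros(2), vcov=np.eye(2), dispersion=dispersion,
            deviance=deviance, loglik_poisson=-500.0, qaic=0.0, n_rows=n_rows,
            n_strata=10, n_params=n_params, converged=True,
            column_map={"pollutant": slice(0, 2)}, fitted=np.ones(n_rows),
            y=np.ones(n_rows), pearson_chi2=float(n_rows),
        )

    def _mk_rr(self, log_rr):
        log_rr = np.asarray(log_rr, float)
        return RRTable(lag=np.arange(len(log_rr)), log_rr=log_rr,
                       se=np.full(len(log_rr), 0.01), increment=10.0, reference=0.0)

    def test_identical_models_give_unit_pvalues(self):
        rr = self._mk_rr([0.01, 0.02, 0.0])
        single = (self._mk_fit(500.0, 20), rr)
        bi = (self._mk_fit(500.0, 25), rr)
        p_overall, per_lag = heterogeneity_test(single, bi)
        assert p_overall == 1.0
        np.testing.assert_array_equal(per_lag, 1.0)

    def test_row_mismatch_rejected(self):
        rr = self._mk_rr([0.0])
        with pytest.raises(ValueError, match="identical rows"):
            heterogeneity_test(
                (self._mk_fit(500.0, 20, n_rows=900), rr),
                (self._mk_fit(480.0, 25, n_rows=1000), rr),
            )

    def test_true_confounding_detected(self, fast_config):
        """Co-pollutant that drives the outcome and correlates with the
        primary: the nested quasi-F flags the added block."""
        detected = 0
        n_rep = 8
        for rep in range(n_rep):
            cfg = ScenarioConfig(seed=500 + rep, n_districts=1, n_days=3000,
                                 regional_daily_mean=5.0, frailty_shape=5.0)
            env, _ = gen_environment(cfg)
            # outcome driven by NO2 (correlated with CO, rho ~0.85)
            truth = TrueSurface.linear({"no2": 0.008}, lag_weights=(0.7, 0.3))
            out = gen_outcomes(env, truth, cfg)
            sub = merge_panels(env, out)
            acfg = fast_config.with_(pollutant="co", increment=100.0)
            design, cb = build_district_design(sub, acfg)
            fr_s = fit_quasipoisson_cc(design)
            rr_s = predict_lag_rr(fr_s, cb, 100.0)
            fr_b, rr_b = fit_bipollutant(
                sub, acfg, BiPollutantSpec(primary="co", co="no2")
            )
            p_overall, _ = heterogeneity_test((fr_s, rr_s), (fr_b, rr_b))
            detected += float(p_overall < 0.05)
        assert detected >= 0.8 * n_rep


class TestSensitivityGrid:
    def test_single_config_trivially_ranked(self, small_panel, fast_config):
        panel, _ = small_panel
        sub = panel[panel.district == "D000"].reset_index(drop=True)
        table = sensitivity_grid(sub, [fast_config])
        assert len(table) == 1
        assert table["rank"].iloc[0] == 1
        assert table["converged"].iloc[0]

    def test_all_configs_share_row_set(self, small_panel, fast_config):
        panel, _ = small_panel
        sub = panel[panel.district == "D000"].reset_index(drop=True)
        configs = [
            fast_config.with_(max_lag=3),
            fast_config.with_(max_lag=7),
            fast_config.with_(max_lag=14),
            fast_config.with_(exposure_spec=BasisSpec("ns", df=3), max_lag=7),
        ]
        table = sensitivity_grid(sub, configs)
        ok = table[table.converged]
        assert ok["n_rows"].nunique() == 1
        assert ok["n_rows"].iloc[0] == len(sub) - 14

    def test_default_grid_enumerates_lattice(self):
        grid = default_grid("no2")
        assert all(c.pollutant == "no2" for c in grid)
        max_lags = {c.max_lag for c in grid}
        assert max_lags == {3, 7, 10, 14}
        funs = {c.exposure_spec.fun for c in grid}
        assert funs == {"linear", "ns"}

    def test_failed_config_recorded_not_fatal(self, small_panel, fast_config):
        panel, _ = small_panel
        sub = panel[panel.district == "D000"].reset_index(drop=True).copy()
        sub["broken"] = 0.0
        configs = [fast_config, fast_config.with_(pollutant="broken")]
        table = sensitivity_grid(sub, configs)
        assert table["converged"].sum() == 1
        failed = table[~table.converged.astype(bool)]
        assert failed["error"].iloc[0] != ""
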