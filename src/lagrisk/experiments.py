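"""Replicated simulation studies over the full pipeline.

Each study generates synthetic panels with a known ground truth, runs the
two-stage analysis, and summarises an operating characteristic: coverage of
the true pooled effect, false-positive calibration under a null surface,
uniformity of effect-modification z-tests, or the Q-AIC grid's ability to
identify the true lag length.  All randomness descends from a single integer
seed through ``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
from scipy import stats

from .basis import BasisSpec, CrossbasisSpec, build_crossbasis
from .design import assign_strata, build_design
from .extensions import sensitivity_grid, ztest_effect_modification
from .fit import fit_quasipoisson_cc
from .pipeline import AnalysisConfig, merge_panels, two_stage
from .predict import Z95, predict_lag_rr
from .synthetic import POLLUTANTS, ScenarioConfig, TrueSurface, gen_environment, gen_outcomes

__all__ = [
    "recovery_study",
    "null_calibration_study",
    "ztest_null_uniformity",
    "qaic_lag_selection_study",
]


def _child_seeds(seed: int, n: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def recovery_study(
    n_replicates: int = 40,
    n_districts: int = 20,
    n_days: int = 1461,
    effect: float = 0.0029,
    lag_weights: Sequence[float] = (0.5, 0.5),
    seed: int = 1,
    config: AnalysisConfig | None = None,
) -> Dict:
    """Coverage of the true cumulative per-10 RR by the pooled 95% CI.

    Simulates districts sharing a linear PM2.5 effect of ``effect`` log-RR
    per ug/m3 distributed over ``lag_weights``, runs the two-stage pipeline,
    and checks whether the pooled cumulative (sum over lags) log RR per 10
    ug/m3 confidence interval contains the truth.
    """
    config = config or AnalysisConfig(pollutant="pm25")
    truth_cum = 10.0 * effect * float(np.sum(lag_weights))
    covered, estimates = [], []
    for s in _child_seeds(seed, n_replicates):
        cfg = ScenarioConfig(seed=s, n_districts=n_districts, n_days=n_days)
        env, _ = gen_environment(cfg)
        out = gen_outcomes(env, TrueSurface.linear({"pm25": effect}, tuple(lag_weights)), cfg)
        res = two_stage(merge_panels(env, out), config)
        csum = res.meta_lag.basis_meta["lag_values"].sum(axis=0)
        cum = float(csum @ res.meta_lag.pooled)
        se = float(np.sqrt(csum @ res.meta_lag.vcov @ csum))
        covered.append(cum - Z95 * se <= truth_cum <= cum + Z95 * se)
        estimates.append(cum)
    return {
        "coverage": float(np.mean(covered)),
        "truth_cumulative_log_rr": truth_cum,
        "mean_estimate": float(np.mean(estimates)),
        "estimates": estimates,
        "n_replicates": n_replicates,
    }


def null_calibration_study(
    n_replicates: int = 40,
    n_districts: int = 10,
    n_days: int = 1461,
    seed: int = 2,
    pollutants: Sequence[str] = POLLUTANTS,
    alpha: float = 0.05,
) -> Dict:
    """False-positive rate of pooled lag-wise RRs when the true surface is null.

    Every (pollutant x lag) cell whose pooled 95% CI excludes RR 1 counts as
    a false positive; with a calibrated pipeline the share sits near alpha.
    """
    n_sig, n_cells, pvals = 0, 0, []
    for s in _child_seeds(seed, n_replicates):
        cfg = ScenarioConfig(seed=s, n_districts=n_districts, n_days=n_days)
        env, _ = gen_environment(cfg)
        out = gen_outcomes(env, TrueSurface.null(), cfg)
        panel = merge_panels(env, out)
        for pol in pollutants:
            res = two_stage(panel, AnalysisConfig(pollutant=pol))
            z = res.rr.log_rr / res.rr.se
            p = 2.0 * stats.norm.sf(np.abs(z))
            pvals.extend(p.tolist())
            n_sig += int(np.sum(p < alpha))
            n_cells += len(p)
    return {
        "significant_share": n_sig / n_cells,
        "n_cells": n_cells,
        "pvalues": pvals,
    }


def ztest_null_uniformity(n_tests: int = 500, n_days: int = 500, seed: int = 3) -> Dict:
    """p-values of effect-modification z-tests between independent null fits.

    Each test compares the lag-0 log RR of two independently simulated
    districts with identical (null) generative effects; under the null the
    z-test p-values should be standard-uniform.  Independence across tests
    makes a Kolmogorov-Smirnov check valid at face value.
    """
    seeds = _child_seeds(seed, 2 * n_tests)
    config = AnalysisConfig(
        pollutant="pm25", include_temperature=False, include_humidity=False
    )
    estimates = []
    for s in seeds:
        cfg = ScenarioConfig(
            seed=s, n_districts=1, n_days=n_days,
            regional_daily_mean=3.0, frailty_shape=5.0,
        )
        env, _ = gen_environment(cfg)
        out = gen_outcomes(env, TrueSurface.null(), cfg)
        sub = merge_panels(env, out)
        from .pipeline import build_district_design

        design, cb = build_district_design(sub, config)
        fr = fit_quasipoisson_cc(design)
        rr = predict_lag_rr(fr, cb, 10.0)
        estimates.append((float(rr.log_rr[0]), float(rr.se[0])))
    pvals = [
        ztest_effect_modification(b1, s1, b2, s2)[1]
        for (b1, s1), (b2, s2) in zip(estimates[::2], estimates[1::2])
    ]
    ks = stats.kstest(pvals, "uniform")
    return {"pvalues": pvals, "ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


def qaic_lag_selection_study(
    n_replicates: int = 50,
    n_days: int = 1461,
    true_max_lag: int = 3,
    wrong_max_lag: int = 14,
    seed: int = 4,
) -> Dict:
    """How often Q-AIC ranks the true lag length above a much longer one.

    The generative effect acts over lags 0..2; candidate models truncate the
    lag dimension at ``true_max_lag`` or extend it to ``wrong_max_lag``.
    Both candidates use unconstrained (per-lag indicator) lag bases, so the
    longer model spends one parameter per extra lag and Q-AIC's dimension
    penalty is the deciding term.
    """
    base = AnalysisConfig(
        pollutant="pm25", include_temperature=False, include_humidity=False
    )

    def unconstrained(L: int) -> BasisSpec:
        return BasisSpec("strata", knots=tuple(range(1, L + 1)), intercept=True)

    configs = [
        base.with_(max_lag=true_max_lag, lag_spec=unconstrained(true_max_lag)),
        base.with_(max_lag=wrong_max_lag, lag_spec=unconstrained(wrong_max_lag)),
    ]
    correct = 0
    for s in _child_seeds(seed, n_replicates):
        cfg = ScenarioConfig(
            seed=s, n_districts=1, n_days=n_days,
            regional_daily_mean=5.0, frailty_shape=5.0,
        )
        env, _ = gen_environment(cfg)
        truth = TrueSurface.linear({"pm25": 0.003}, lag_weights=(0.4, 0.35, 0.25))
        out = gen_outcomes(env, truth, cfg)
        sub = merge_panels(env, out)
        table = sensitivity_grid(sub, configs)
        if table.loc[table["rank"] == 1, "max_lag"].iloc[0] == true_max_lag:
            correct += 1
    return {"correct_rate": correct / n_replicates, "n_replicates": n_replicates}
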