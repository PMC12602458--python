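"""Stratified analyses, bi-pollutant models, and the Q-AIC sensitivity grid.

Effect modification is assessed by re-running the identical two-stage
pipeline per stratum level (separate subgroup count series for age and sex;
row subsets for season; district subsets for urbanicity) and comparing
lag-wise log relative risks to the reference level with two-sample z-tests.
Bi-pollutant models extend the single-pollutant design with the co-pollutant
crossbasis (confounder mode) or with products of the primary crossbasis and
the co-pollutant's same-day exposure (interaction mode); single and
bi-pollutant fits are compared through nested-model quasi-F tests plus
per-lag contrasts.  The sensitivity grid refits the model over a lattice of
basis and lag choices on a common row set and ranks configurations by Q-AIC.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisSpec, CrossbasisSpec, build_crossbasis, logknots
from .design import season_of
from .fit import FitResult, fit_quasipoisson_cc, qaic
from .pipeline import (
    AnalysisConfig,
    RegionResult,
    build_district_design,
    two_stage,
)
from .predict import RRTable, predict_lag_rr

__all__ = [
    "ztest_effect_modification",
    "StratifiedRun",
    "run_stratified",
    "BiPollutantSpec",
    "fit_bipollutant",
    "heterogeneity_test",
    "sensitivity_grid",
]

log = logging.getLogger(__name__)

STRATIFIER_LEVELS = {
    "all": ("all",),
    "age": ("senior", "adult"),  # reference first: >=65 years
    "sex": ("male", "female"),
    "urbanicity": ("urban", "rural"),
    "season": ("winter", "spring", "summer", "autumn"),
}


def ztest_effect_modification(b1: float, se1: float, b2: float, se2: float):
    """Two-sample z-test for a difference in log-RR between strata.

    Returns ``(z, p)`` with ``z = (b1 - b2) / sqrt(se1^2 + se2^2)`` and a
    two-sided normal p-value.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class StratifiedRun:
    stratifier: str
    reference_level: str
    results: Dict[str, RegionResult]
    skipped: Dict[str, str]
    # per non-reference level: DataFrame with lag, z, p columns
    ztests: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _level_panel(
    panel: pd.DataFrame,
    districts: Optional[pd.DataFrame],
    stratifier: str,
    level: str,
    config: AnalysisConfig,
) -> Tuple[pd.DataFrame, AnalysisConfig]:
    if stratifier == "all":
        # single all-inclusive level: the stratified code path must reproduce
        # the main model exactly
        return panel, config
    if stratifier in ("age", "sex"):
        col = {"senior": "ohca_senior", "adult": "ohca_adult",
               "male": "ohca_male", "female": "ohca_female"}[level]
        if col not in panel:
            raise KeyError(f"subgroup column {col!r} missing from panel")
        return panel, config.with_(outcome=col)
    if stratifier == "season":
        seas = season_of(panel["date"]).to_numpy()
        return panel[seas == level].reset_index(drop=True), config
    if stratifier == "urbanicity":
        if districts is None or "urban" not in districts:
            raise ValueError("urbanicity stratification needs a district table with an urban flag")
        wanted = districts.loc[districts["urban"] == (level == "urban"), "district"]
        return panel[panel["district"].isin(set(wanted.astype(str)))].reset_index(drop=True), config
    raise ValueError(f"unknown stratifier {stratifier!r}")


def run_stratified(
    panel: pd.DataFrame,
    config: AnalysisConfig,
    stratifier: str,
    districts: Optional[pd.DataFrame] = None,
    levels: Optional[Sequence[str]] = None,
) -> StratifiedRun:
    """Full two-stage pipeline per stratum level, with z-tests vs reference.

    Season subsets are taken after stratum assignment; because strata are
    year x month x weekday and seasons are whole-month blocks, no stratum
    straddles two seasons.  Levels with no events (or too few districts) are
    skipped with a log entry.
    """
    levels = tuple(levels) if levels is not None else STRATIFIER_LEVELS[stratifier]
    reference = levels[0]
    results: Dict[str, RegionResult] = {}
    skipped: Dict[str, str] = {}
    for level in levels:
        try:
            sub_panel, sub_config = _level_panel(panel, districts, stratifier, level, config)
            if sub_panel.empty or sub_panel[sub_config.outcome].sum() == 0:
                raise RuntimeError("no rows or no events at this level")
            results[level] = two_stage(sub_panel, sub_config)
        except Exception as e:  # noqa: BLE001 - level isolation is the contract
            skipped[level] = str(e)
            log.warning("stratifier %s level %s skipped: %s", stratifier, level, e)

    ztests: Dict[str, pd.DataFrame] = {}
    if reference in results:
        ref_rr = results[reference].rr
        for level, res in results.items():
            if level == reference:
                continue
            rows = []
            for lag in range(len(ref_rr.lag)):
                z, p = ztest_effect_modification(
                    res.rr.log_rr[lag], res.rr.se[lag], ref_rr.log_rr[lag], ref_rr.se[lag]
                )
                rows.append({"lag": lag, "z": z, "p": p})
            ztests[level] = pd.DataFrame(rows)
    return StratifiedRun(
        stratifier=stratifier,
        reference_level=reference,
        results=results,
        skipped=skipped,
        ztests=ztests,
    )


@dataclass(frozen=True)
class BiPollutantSpec:
    """Co-pollutant adjustment: confounder or interaction mode.

    PM2.5 with PM10 is disallowed by default: the two are nearly collinear
    (Spearman ~0.98) and a joint model is not identifiable in practice.
    """

    primary: str
    co: str
    mode: str = "confounder"  # confounder | interaction
    co_exposure_spec: BasisSpec = field(default_factory=lambda: BasisSpec("linear"))
    co_lag_spec: BasisSpec = field(default_factory=lambda: BasisSpec("ns", df=3, intercept=True))
    co_max_lag: int = 7
    allow_pm_pair: bool = False

    def __post_init__(self):
        if self.primary == self.co:
            raise ValueError("primary and co-pollutant must differ")
        if self.mode not in ("confounder", "interaction"):
            raise ValueError(f"unknown bi-pollutant mode {self.mode!r}")
        pair = {self.primary, self.co}
        if pair == {"pm25", "pm10"} and not self.allow_pm_pair:
            raise ValueError("PM2.5/PM10 pairing disallowed (near-collinear); set allow_pm_pair")


def _bipollutant_terms(
    sub: pd.DataFrame, config: AnalysisConfig, bispec: BiPollutantSpec
) -> Dict[str, np.ndarray]:
    xco = sub[bispec.co].to_numpy(float)
    if bispec.mode == "confounder":
        co_cb = build_crossbasis(
            xco, CrossbasisSpec(bispec.co_exposure_spec, bispec.co_lag_spec, bispec.co_max_lag)
        )
        vals = co_cb.values
        # a degenerate (identically zero) co-pollutant series produces all-zero
        # columns; drop them so the model reduces to the single-pollutant fit
        nonzero = ~np.all(np.nan_to_num(vals) == 0.0, axis=0)
        if not nonzero.all():
            log.warning("dropping %d all-zero co-pollutant columns", int((~nonzero).sum()))
            vals = vals[:, nonzero]
        if vals.shape[1] == 0:
            return {}
        return {"co_pollutant": vals}
    # interaction: products of the primary crossbasis columns with the
    # co-pollutant's same-day exposure basis (default linear, centered so the
    # primary block keeps its main-effect interpretation at mean co-exposure)
    primary_cb = build_crossbasis(
        sub[config.pollutant].to_numpy(float),
        CrossbasisSpec(config.exposure_spec, config.lag_spec, config.max_lag),
    )
    co_centered = xco - xco.mean()
    inter = primary_cb.values * co_centered[:, None]
    return {"co_interaction": inter}


def fit_bipollutant(
    sub: pd.DataFrame, config: AnalysisConfig, bispec: BiPollutantSpec
) -> Tuple[FitResult, RRTable]:
    """Fit one district's bi-pollutant model; returns the fit and the
    primary pollutant's lag-wise RR table recomputed under adjustment."""
    if config.pollutant != bispec.primary:
        config = config.with_(pollutant=bispec.primary)
    extra = _bipollutant_terms(sub, config, bispec)
    design, cb = build_district_design(sub, config, extra_terms=extra)
    fr = fit_quasipoisson_cc(design)
    rr = predict_lag_rr(fr, cb, config.resolved_increment(), config.reference)
    return fr, rr


def heterogeneity_test(
    single: Tuple[FitResult, RRTable], bi: Tuple[FitResult, RRTable]
) -> Tuple[float, np.ndarray]:
    """Nested-model comparison of single vs bi-pollutant fits.

    Overall: quasi-likelihood F-test on the added block,
    ``F = (dev_single - dev_bi) / (dp * phi_bi)`` on ``(dp, n - p_bi)``
    degrees of freedom.  Per lag: z-contrast on the lag-wise log-RR
    difference with the conservative sum of variances (the two fits share
    data, so their estimates are correlated; ignoring the covariance widens
    the implied interval).
    """
    fit_s, rr_s = single
    fit_b, rr_b = bi
    if fit_s.n_rows != fit_b.n_rows:
        raise ValueError("single and bi-pollutant fits must use identical rows")
    dp = fit_b.n_params - fit_s.n_params
    if dp <= 0:
        raise ValueError("bi-pollutant model must nest the single-pollutant model")
    ddev = max(0.0, fit_s.deviance - fit_b.deviance)
    phi = fit_b.dispersion
    df2 = fit_b.n_rows - fit_b.n_params
    if ddev == 0.0:
        p_overall = 1.0
    else:
        f = ddev / (dp * phi)
        p_overall = float(stats.f.sf(f, dp, df2))
    per_lag = np.empty(len(rr_s.lag))
    for i in range(len(rr_s.lag)):
        d = rr_b.log_rr[i] - rr_s.log_rr[i]
        se = np.hypot(rr_b.se[i], rr_s.se[i])
        per_lag[i] = 1.0 if d == 0 else 2.0 * stats.norm.sf(abs(d) / se)
    return p_overall, per_lag


# ---------------------------------------------------------------------------
# sensitivity grid


def default_grid(pollutant: str = "pm25") -> List[AnalysisConfig]:
    """The model-choice lattice explored in sensitivity analysis.

    Pollutant transform: linear and natural splines with 2-4 df; lags 3, 7,
    10, 14 days with either a 3-df natural-spline lag basis or two log-spaced
    knots; temperature knots at combinations of the 10th/75th/90th
    percentiles with a 14-day lag as strata or log-spaced spline; humidity as
    a 3- or 4-df spline of same-day values or 3-day running means.
    """
    configs: List[AnalysisConfig] = []
    exposure_specs = [BasisSpec("linear")] + [BasisSpec("ns", df=d) for d in (2, 3, 4)]
    for exp_spec, L in itertools.product(exposure_specs, (3, 7, 10, 14)):
        lag_specs = [BasisSpec("ns", df=3, intercept=True)]
        if L >= 3:
            lag_specs.append(
                BasisSpec("ns", knots=tuple(logknots(L, 2)), intercept=True)
            )
        for lag_spec in lag_specs:
            configs.append(
                AnalysisConfig(
                    pollutant=pollutant, exposure_spec=exp_spec, lag_spec=lag_spec, max_lag=L
                )
            )
    return configs


def sensitivity_grid(
    sub: pd.DataFrame,
    configs: Sequence[AnalysisConfig],
    shared_dispersion: bool = True,
) -> pd.DataFrame:
    """Fit every configuration on one district's panel and rank by Q-AIC.

    All configurations are fit on the identical row set — the rows valid at
    the largest lag in the grid — so their Q-AIC values are comparable.  With
    ``shared_dispersion`` the dispersion of the largest (most parameters)
    converged model penalises every candidate.  Non-converging configurations
    are recorded, not fatal.  Ties rank the smaller model first, then stable
    input order.
    """
    if not configs:
        raise ValueError("empty sensitivity grid")
    max_L = max(max(c.max_lag, c.temp_max_lag if c.include_temperature else 0) for c in configs)
    records = []
    fits: List[Optional[FitResult]] = []
    for i, cfg in enumerate(configs):
        try:
            # pad max lag via design trimming: build with the config, then
            # drop rows so every model sees the same sample
            design, cb = build_district_design(sub, cfg)
            this_first = max(cfg.max_lag, cfg.temp_max_lag if cfg.include_temperature else 0)
            extra_drop = max_L - this_first
            if extra_drop > 0:
                design.y = design.y[extra_drop:]
                design.X = design.X[extra_drop:]
                design.strata = design.strata[extra_drop:]
                design.index = design.index[extra_drop:]
            fr = fit_quasipoisson_cc(design)
            rr = predict_lag_rr(fr, cb, cfg.resolved_increment(), cfg.reference)
            fits.append(fr)
            records.append(
                {
                    "config_id": i,
                    "n_rows": fr.n_rows,
                    "n_params": fr.n_params,
                    "converged": fr.converged,
                    "dispersion": fr.dispersion,
                    "qaic": fr.qaic,
                    "exposure": _spec_label(cfg.exposure_spec),
                    "lag_basis": _spec_label(cfg.lag_spec),
                    "max_lag": cfg.max_lag,
                    "rr_lag0": float(rr.rr[0]),
                    "error": "",
                }
            )
        except Exception as e:  # noqa: BLE001
            fits.append(None)
            records.append(
                {
                    "config_id": i, "n_rows": np.nan, "n_params": np.nan,
                    "converged": False, "dispersion": np.nan, "qaic": np.nan,
                    "exposure": _spec_label(cfg.exposure_spec),
                    "lag_basis": _spec_label(cfg.lag_spec),
                    "max_lag": cfg.max_lag, "rr_lag0": np.nan, "error": str(e),
                }
            )
    table = pd.DataFrame(records)
    ok = table["converged"].fillna(False).astype(bool)
    if ok.any():
        row_sets = table.loc[ok, "n_rows"].unique()
        if len(row_sets) > 1:
            raise AssertionError(f"grid configurations fit on differing row sets: {row_sets}")
        if shared_dispersion:
            largest = table.loc[ok, "n_params"].idxmax()
            phi = table.loc[largest, "dispersion"]
            for i in table.index[ok]:
                table.loc[i, "qaic"] = qaic(fits[table.loc[i, "config_id"]], dispersion=phi)
    table = table.sort_values(
        ["qaic", "n_params", "config_id"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def _spec_label(spec: BasisSpec) -> str:
    if spec.fun == "linear":
        return "linear"
    if spec.knots is not None:
        return f"{spec.fun}(knots={','.join(f'{k:.3g}' for k in spec.knots)})"
    return f"{spec.fun}(df={spec.df})"
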