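"""Two-stage analysis orchestration.

Stage one fits, per district, a stratum-conditioned quasi-Poisson model with
a pollutant crossbasis, a temperature crossbasis, a humidity spline and a
holiday indicator; stage two pools the districts' reduced coefficient
summaries by multivariate random-effects meta-analysis and turns the pooled
coefficients into region-level lag-wise relative risks and cumulative
exposure-response curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .basis import BasisSpec, CrossbasisSpec, Crossbasis, build_crossbasis, OneBasis, logknots
from .design import DesignMatrix, assign_strata, build_design, holiday_indicator
from .fit import FitResult, fit_quasipoisson_cc
from .meta import MetaResult, meta_fit, pool_predict
from .predict import ERCurve, RRTable, ReducedCoef, reduce_fit

__all__ = [
    "DEFAULT_INCREMENTS",
    "AnalysisConfig",
    "DistrictFit",
    "RegionResult",
    "running_mean",
    "fit_district",
    "two_stage",
]

log = logging.getLogger(__name__)

# reporting increments, ug/m3: particulates/NO2/O3 per 10, SO2 per 1 (its
# daily levels stay in single digits), CO per 100 (its range spans hundreds)
DEFAULT_INCREMENTS = {"pm25": 10.0, "pm10": 10.0, "no2": 10.0, "o3": 10.0, "so2": 1.0, "co": 100.0}


@dataclass(frozen=True)
class AnalysisConfig:
    """First-stage model configuration for one pollutant."""

    pollutant: str = "pm25"
    increment: Optional[float] = None  # default per DEFAULT_INCREMENTS
    reference: float = 0.0
    exposure_spec: BasisSpec = field(default_factory=lambda: BasisSpec("linear"))
    lag_spec: BasisSpec = field(
        default_factory=lambda: BasisSpec("ns", df=3, intercept=True)
    )
    max_lag: int = 7
    # temperature confounder: spline knots towards the distribution tails,
    # 14-day lag on a log-spaced spline
    temp_knot_quantiles: Tuple[float, ...] = (0.10, 0.75, 0.90)
    temp_lag_spec: BasisSpec = field(
        default_factory=lambda: BasisSpec("ns", knots=tuple(logknots(14, 2)), intercept=True)
    )
    temp_max_lag: int = 14
    rh_df: int = 3
    rh_running_mean: int = 3  # days; 1 = same-day values
    outcome: str = "ohca"
    meta_method: str = "reml"
    include_temperature: bool = True
    include_humidity: bool = True
    include_holiday: bool = True

    def resolved_increment(self) -> float:
        if self.increment is not None:
            return float(self.increment)
        return DEFAULT_INCREMENTS.get(self.pollutant, 10.0)

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass
class DistrictFit:
    district: str
    fit: FitResult
    crossbasis: Crossbasis
    reduced_lag: ReducedCoef
    reduced_er: ReducedCoef


@dataclass
class RegionResult:
    """Pooled second-stage result for one pollutant."""

    config: AnalysisConfig
    district_fits: List[DistrictFit]
    failures: Dict[str, str]
    meta_lag: MetaResult
    meta_er: MetaResult
    rr: RRTable
    curve: ERCurve


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing running mean over `window` days (window=1 returns x)."""
    x = np.asarray(x, float)
    if window <= 1:
        return x.copy()
    c = np.convolve(x, np.ones(window) / window, mode="full")[: len(x)]
    c[: window - 1] = np.nan
    # partial windows at the series head are averaged over available days
    for i in range(min(window - 1, len(x))):
        c[i] = x[: i + 1].mean()
    return c


def _district_frames(panel: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    out = {}
    for d, sub in panel.groupby("district", sort=True):
        out[str(d)] = sub.sort_values("date").reset_index(drop=True)
    return out


def build_district_design(
    sub: pd.DataFrame,
    config: AnalysisConfig,
    extra_terms: Optional[Dict[str, np.ndarray]] = None,
) -> Tuple[DesignMatrix, Crossbasis]:
    """Assemble the first-stage design for one district's merged panel."""
    dates = pd.DatetimeIndex(sub["date"])
    x = sub[config.pollutant].to_numpy(float)
    cb_spec = CrossbasisSpec(config.exposure_spec, config.lag_spec, config.max_lag)
    cb = build_crossbasis(x, cb_spec)

    temp_cb = None
    if config.include_temperature and "temp" in sub:
        t = sub["temp"].to_numpy(float)
        tknots = tuple(np.quantile(t, config.temp_knot_quantiles))
        temp_spec = CrossbasisSpec(
            BasisSpec("ns", knots=tknots), config.temp_lag_spec, config.temp_max_lag
        )
        temp_cb = build_crossbasis(t, temp_spec)

    rh_basis = None
    if config.include_humidity and "rh" in sub:
        rh = running_mean(sub["rh"].to_numpy(float), config.rh_running_mean)
        rh_basis = OneBasis.fit(rh, BasisSpec("ns", df=config.rh_df)).transform(rh)

    hol = holiday_indicator(dates) if config.include_holiday else None
    strata = assign_strata(dates, sub["district"].iloc[0])
    design = build_design(
        cb,
        temp_cb,
        rh_basis,
        hol,
        counts=sub[config.outcome].to_numpy(float),
        strata=strata,
        dates=dates,
        extra_terms=extra_terms,
    )
    return design, cb


def fit_district(sub: pd.DataFrame, config: AnalysisConfig) -> DistrictFit:
    design, cb = build_district_design(sub, config)
    fr = fit_quasipoisson_cc(design)
    inc, ref = config.resolved_increment(), config.reference
    red_lag = reduce_fit(fr, cb, "lag_specific_at_increment", at=inc, reference=ref)
    red_er = reduce_fit(fr, cb, "exposure_response", reference=ref)
    return DistrictFit(
        district=str(sub["district"].iloc[0]),
        fit=fr,
        crossbasis=cb,
        reduced_lag=red_lag,
        reduced_er=red_er,
    )


def resolve_exposure_spec(panel: pd.DataFrame, config: AnalysisConfig) -> AnalysisConfig:
    """Pin spline exposure knots to region-wide quantiles so that district
    bases coincide and their reduced coefficients are poolable."""
    spec = config.exposure_spec
    if spec.fun != "ns" or spec.knots is not None:
        return config
    x = panel[config.pollutant].to_numpy(float)
    n_int = (spec.df or 2) - 1 - int(spec.intercept)
    qs = np.linspace(0, 1, n_int + 2)[1:-1]
    knots = tuple(np.quantile(x, qs))
    boundary = spec.boundary or (min(0.0, float(x.min())), float(x.max()))
    return config.with_(
        exposure_spec=BasisSpec("ns", knots=knots, boundary=boundary, intercept=spec.intercept)
    )


def two_stage(panel: pd.DataFrame, config: AnalysisConfig) -> RegionResult:
    """Run the full two-stage analysis on a merged district-day panel.

    ``panel`` holds one row per district-day with exposure, covariate and
    outcome columns.  Districts whose first-stage fit fails (rank deficiency,
    non-convergence) are excluded from pooling and listed in ``failures``.
    """
    config = resolve_exposure_spec(panel, config)
    fits: List[DistrictFit] = []
    failures: Dict[str, str] = {}
    for d, sub in _district_frames(panel).items():
        try:
            df_ = fit_district(sub, config)
            if not df_.fit.converged:
                raise RuntimeError("IRLS did not converge")
            fits.append(df_)
        except Exception as e:  # noqa: BLE001 - per-district isolation is the contract
            failures[d] = str(e)
            log.warning("district %s excluded from pooling: %s", d, e)
    if len(fits) < 2:
        raise RuntimeError(
            f"fewer than 2 districts fit successfully ({len(failures)} failures): {failures}"
        )
    meta_lag = meta_fit([f.reduced_lag for f in fits], method=config.meta_method)
    meta_er = meta_fit([f.reduced_er for f in fits], method=config.meta_method)
    # pooled exposure-response evaluated over the region-wide observed range
    max_exp = float(panel[config.pollutant].max())
    grid = np.linspace(0.0, max_exp, 50)
    er_meta = dict(meta_er.basis_meta)
    er_meta["max_exposure"] = max_exp
    rr = pool_predict(meta_lag)
    curve = pool_predict(meta_er, basis_meta=er_meta, grid=grid)
    return RegionResult(
        config=config,
        district_fits=fits,
        failures=failures,
        meta_lag=meta_lag,
        meta_er=meta_er,
        rr=rr,
        curve=curve,
    )


def merge_panels(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Inner-join exposure and outcome panels on district-day."""
    merged = exposure.merge(outcome, on=["district", "date"], how="inner", validate="1:1")
    return merged.sort_values(["district", "date"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration-driven runner


def _spec_from_dict(d: Optional[dict], default: BasisSpec) -> BasisSpec:
    if not d:
        return default
    return BasisSpec(
        fun=d.get("fun", "linear"),
        df=d.get("df"),
        knots=tuple(d["knots"]) if d.get("knots") else None,
        boundary=tuple(d["boundary"]) if d.get("boundary") else None,
        intercept=bool(d.get("intercept", False)),
    )


def load_pipeline_config(path):
    """Parse and validate a YAML pipeline configuration (unknown keys rejected)."""
    import yaml

    from .schema import PipelineConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def read_panel(path) -> pd.DataFrame:
    """Read a delimited-text district-day panel; parse dates, check numerics."""
    df = pd.read_csv(path)
    if "district" not in df or "date" not in df:
        raise ValueError(f"{path}: panel needs 'district' and 'date' columns")
    df["date"] = pd.to_datetime(df["date"])
    df["district"] = df["district"].astype(str)
    for c in df.columns.drop(["district", "date"]):
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            i = int(np.where(bad)[0][0])
            raise ValueError(
                f"{path}: non-numeric value {df[c].iloc[i]!r} in column {c!r} at row {i + 2}"
            )
        df[c] = coerced
    return df


def validate_panel(path) -> pd.DataFrame:
    """Schema/continuity/range audit; returns a violations table (empty = clean)."""
    df = read_panel(path)
    issues = []
    dup = df.duplicated(subset=["district", "date"])
    for i in np.where(dup)[0]:
        issues.append(
            {"district": df["district"].iloc[i], "date": str(df["date"].iloc[i].date()),
             "issue": "duplicated district-day"}
        )
    from .synthetic import POLLUTANTS

    for d, sub in df.groupby("district"):
        dates = pd.DatetimeIndex(sub["date"]).sort_values()
        gaps = np.where(np.diff(dates.values).astype("timedelta64[D]") > np.timedelta64(1, "D"))[0]
        for g in gaps:
            issues.append(
                {"district": d, "date": str(dates[g].date()),
                 "issue": f"date gap before {dates[g + 1].date()}"}
            )
    for pol in POLLUTANTS:
        if pol in df:
            neg = df[pol] < 0
            for i in np.where(neg)[0]:
                issues.append(
                    {"district": df["district"].iloc[i], "date": str(df["date"].iloc[i].date()),
                     "issue": f"negative {pol}"}
                )
    return pd.DataFrame(issues, columns=["district", "date", "issue"])


_FLOAT_FMT = "%.12g"


def _write_csv(df: pd.DataFrame, path):
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def run_pipeline(config_path, log_stream=None) -> Dict:
    """Run the configured two-stage analysis end to end.

    Writes, under the configured output directory: pooled lag-wise RR tables
    and cumulative exposure-response curves per pollutant, per-district
    reduced coefficients, district fit summaries, stratified and bi-pollutant
    reports where requested, the sensitivity ranking, and a run manifest.
    Per-district failures are isolated and reported in the manifest.
    """
    import hashlib
    import json
    from pathlib import Path

    from .extensions import (
        BiPollutantSpec,
        default_grid,
        fit_bipollutant,
        heterogeneity_test,
        run_stratified,
        sensitivity_grid,
    )
    from .predict import predict_lag_rr

    cfg = load_pipeline_config(config_path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    exposure = read_panel(cfg.exposure_panel)
    outcome = read_panel(cfg.outcome_panel)
    districts = None
    if cfg.district_table:
        districts = pd.read_csv(cfg.district_table)
        districts["district"] = districts["district"].astype(str)
        if "urban" in districts:
            districts["urban"] = districts["urban"].astype(bool)
    panel = merge_panels(exposure, outcome)

    manifest: Dict = {
        "config_sha256": hashlib.sha256(Path(config_path).read_bytes()).hexdigest(),
        "seed": cfg.seed,
        "versions": _versions(),
        "pollutants": {},
        "failures": {},
    }

    base = AnalysisConfig(
        max_lag=cfg.max_lag,
        meta_method=cfg.meta_method,
        outcome=cfg.outcome,
    )
    for pol in cfg.pollutants:
        acfg = base.with_(
            pollutant=pol,
            increment=cfg.increments.get(pol),
            exposure_spec=_spec_from_dict(cfg.exposure_basis.get(pol), base.exposure_spec),
            lag_spec=_spec_from_dict(cfg.lag_basis.get(pol), base.lag_spec),
        )
        res = two_stage(panel, acfg)
        _write_csv(res.rr.to_frame(), out / f"rr_{pol}.csv")
        _write_csv(res.curve.to_frame(), out / f"curve_{pol}.csv")
        rows = []
        for dfit in res.district_fits:
            for j, c in enumerate(dfit.reduced_lag.coef):
                rows.append(
                    {"district": dfit.district, "coef_index": j, "coef": c,
                     "variance": dfit.reduced_lag.vcov[j, j],
                     "dispersion": dfit.fit.dispersion, "qaic": dfit.fit.qaic}
                )
        _write_csv(pd.DataFrame(rows), out / f"district_coefs_{pol}.csv")
        manifest["pollutants"][pol] = {
            "n_districts_pooled": len(res.district_fits),
            "i2_lag": res.meta_lag.i2,
            "q_lag": res.meta_lag.q_stat,
            "meta_method": res.meta_lag.method,
        }
        manifest["failures"][pol] = res.failures

        for strat in cfg.stratifiers:
            srun = run_stratified(panel, acfg, strat, districts=districts)
            rows = []
            for level, r in srun.results.items():
                fr = r.rr.to_frame()
                fr.insert(0, "level", level)
                rows.append(fr)
            if rows:
                _write_csv(pd.concat(rows, ignore_index=True), out / f"strat_{strat}_{pol}.csv")
            zrows = []
            for level, zt in srun.ztests.items():
                zt = zt.copy()
                zt.insert(0, "level", level)
                zrows.append(zt)
            if zrows:
                _write_csv(pd.concat(zrows, ignore_index=True), out / f"ztest_{strat}_{pol}.csv")

    for pair in cfg.bipollutant_pairs:
        primary, co, mode = pair["primary"], pair["co"], pair.get("mode", "confounder")
        acfg = base.with_(pollutant=primary, increment=cfg.increments.get(primary))
        acfg = resolve_exposure_spec(panel, acfg)
        bspec = BiPollutantSpec(primary=primary, co=co, mode=mode)
        rows = []
        for d, sub in _district_frames(panel).items():
            try:
                design_s, cb = build_district_design(sub, acfg)
                fr_s = fit_quasipoisson_cc(design_s)
                rr_s = predict_lag_rr(fr_s, cb, acfg.resolved_increment(), acfg.reference)
                fr_b, rr_b = fit_bipollutant(sub, acfg, bspec)
                p_overall, per_lag = heterogeneity_test((fr_s, rr_s), (fr_b, rr_b))
                for lag in range(len(rr_b.lag)):
                    rows.append(
                        {"district": d, "lag": lag, "rr_single": rr_s.rr[lag],
                         "rr_bi": rr_b.rr[lag], "p_overall": p_overall,
                         "p_lag": per_lag[lag]}
                    )
            except Exception as e:  # noqa: BLE001
                manifest["failures"].setdefault(f"bi_{primary}_{co}_{mode}", {})[d] = str(e)
        if rows:
            _write_csv(pd.DataFrame(rows), out / f"bipollutant_{primary}_{co}_{mode}.csv")

    if cfg.run_sensitivity:
        first = next(iter(_district_frames(panel).values()))
        table = sensitivity_grid(first, default_grid(cfg.pollutants[0]))
        _write_csv(table, out / "sensitivity_ranking.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _versions() -> Dict[str, str]:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "lagrisk": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
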