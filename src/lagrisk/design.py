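"""Time-stratified case-crossover strata and regression design assembly.

The time-stratified case-crossover design compares each day with the other
days in the same stratum — here district x year x month x day-of-week — so
that slow confounders (long-term trends, seasonality, intra-week patterns)
are absorbed by design rather than modelled.  Each stratum contributes one
nuisance intercept to the first-stage quasi-Poisson fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .basis import Crossbasis

__all__ = [
    "assign_strata",
    "season_of",
    "holiday_indicator",
    "italian_holidays",
    "load_holiday_file",
    "DesignMatrix",
    "build_design",
]


def assign_strata(dates: Sequence, district) -> pd.Series:
    """Stratum key (district, year, month, weekday) for each date.

    Days sharing a key are mutual controls; keys never span districts.
    """
    d = pd.to_datetime(pd.Series(list(dates)))
    keys = (
        str(district)
        + ":"
        + d.dt.year.astype(str)
        + "-"
        + d.dt.month.astype(str).str.zfill(2)
        + "-dow"
        + d.dt.dayofweek.astype(str)
    )
    keys.index = range(len(keys))
    return keys


_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(dates: Sequence) -> pd.Series:
    """Meteorological season: Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov autumn."""
    months = pd.to_datetime(pd.Series(list(dates))).dt.month
    out = months.map(_SEASON_BY_MONTH)
    out.index = range(len(out))
    return out


def _easter_sunday(year: int) -> pd.Timestamp:
    """Gregorian computus (anonymous/Meeus algorithm)."""
    a = year % 19
    b, c = divmod(year, 100)
    d, e = divmod(b, 4)
    f = (b + 8) // 25
    g = (b - f + 1) // 3
    h = (19 * a + b - d - g + 15) % 30
    i, k = divmod(c, 4)
    l = (32 + 2 * e + 2 * i - h - k) % 7
    m = (a + 11 * h + 22 * l) // 451
    month = (h + l - 7 * m + 114) // 31
    day = ((h + l - 7 * m + 114) % 31) + 1
    return pd.Timestamp(year=year, month=month, day=day)


# fixed-date Italian national holidays (month, day)
_ITALY_FIXED = [
    (1, 1),   # Capodanno
    (1, 6),   # Epifania
    (4, 25),  # Liberazione
    (5, 1),   # Festa del Lavoro
    (6, 2),   # Festa della Repubblica
    (8, 15),  # Ferragosto
    (11, 1),  # Ognissanti
    (12, 8),  # Immacolata
    (12, 25), # Natale
    (12, 26), # Santo Stefano
]


def italian_holidays(years: Iterable[int]) -> set:
    """Italian national holidays: fixed dates plus Easter Monday by computus."""
    cal = set()
    for y in sorted(set(int(v) for v in years)):
        for m, d in _ITALY_FIXED:
            cal.add(pd.Timestamp(year=y, month=m, day=d))
        cal.add(_easter_sunday(y) + pd.Timedelta(days=1))  # Pasquetta
    return cal


def load_holiday_file(path) -> set:
    """Holiday calendar file: one ISO-8601 date per line, '#' comments allowed."""
    cal = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            cal.add(pd.Timestamp(line))
    return cal


def holiday_indicator(dates: Sequence, calendar: Optional[set] = None) -> np.ndarray:
    """0/1 vector: 1 iff the date is in the holiday calendar.

    With ``calendar=None`` the built-in Italian national list is used.
    """
    d = pd.to_datetime(pd.Series(list(dates))).dt.normalize()
    if calendar is None:
        calendar = italian_holidays(d.dt.year.unique())
    cal = {pd.Timestamp(c).normalize() for c in calendar}
    return d.isin(cal).to_numpy(dtype=float)


@dataclass
class DesignMatrix:
    """Assembled first-stage design for one district.

    ``column_map`` maps term names ("pollutant", "temperature", "humidity",
    "holiday", optional co-pollutant terms) to column slices of ``X``; it is
    what lets prediction and reduction find the crossbasis block afterwards.
    """

    y: np.ndarray
    X: np.ndarray
    strata: np.ndarray  # stratum key per retained row
    column_map: Dict[str, slice]
    index: pd.Index  # dates of retained rows
    n_dropped_incomplete: int = 0
    n_dropped_missing: int = 0
    degenerate_strata: tuple = field(default_factory=tuple)

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def term_slice(self, name: str) -> slice:
        return self.column_map[name]


def build_design(
    exposure_cb: Crossbasis,
    temp_cb: Optional[Crossbasis],
    rh_basis: Optional[np.ndarray],
    holiday: Optional[np.ndarray],
    counts: Sequence[float],
    strata: Sequence,
    dates: Optional[Sequence] = None,
    extra_terms: Optional[Dict[str, np.ndarray]] = None,
) -> DesignMatrix:
    """Assemble response, design matrix and strata with consistent row filtering.

    Rows lacking full lag history (the first ``max_lag`` of each series) or
    containing missing values are dropped from response, design and strata
    alike.  Strata left with zero events are flagged as degenerate: they
    contribute nothing to the conditional likelihood (their implied intercept
    diverges) but are kept in the bookkeeping used for dispersion.
    """
    y = np.asarray(counts, dtype=float)
    n = len(y)
    blocks: Dict[str, np.ndarray] = {"pollutant": exposure_cb.values}
    if temp_cb is not None:
        blocks["temperature"] = temp_cb.values
    if rh_basis is not None:
        blocks["humidity"] = np.asarray(rh_basis, dtype=float)
    if holiday is not None:
        blocks["holiday"] = np.asarray(holiday, dtype=float).reshape(-1, 1)
    for name, mat in (extra_terms or {}).items():
        blocks[name] = np.asarray(mat, dtype=float)
        if blocks[name].ndim == 1:
            blocks[name] = blocks[name].reshape(-1, 1)

    for name, mat in blocks.items():
        if mat.shape[0] != n:
            raise ValueError(f"term {name!r} has {mat.shape[0]} rows, expected {n}")
    strata = np.asarray(pd.Series(list(strata)).astype(str))
    if len(strata) != n:
        raise ValueError("strata not aligned with counts")

    first_valid = exposure_cb.first_valid_row
    for cb in (temp_cb,):
        if cb is not None:
            first_valid = max(first_valid, cb.first_valid_row)

    X = np.hstack(list(blocks.values()))
    keep = np.ones(n, dtype=bool)
    keep[:first_valid] = False
    n_incomplete = int((~keep).sum())
    finite = np.isfinite(X).all(axis=1) & np.isfinite(y)
    n_missing = int((keep & ~finite).sum())
    keep &= finite

    column_map: Dict[str, slice] = {}
    start = 0
    for name, mat in blocks.items():
        column_map[name] = slice(start, start + mat.shape[1])
        start += mat.shape[1]

    y_k, X_k, s_k = y[keep], X[keep], strata[keep]
    totals = pd.Series(y_k).groupby(pd.Series(s_k)).sum()
    degenerate = tuple(totals.index[totals == 0])

    if dates is not None:
        idx = pd.to_datetime(pd.Index(list(dates)))[keep]
    else:
        idx = pd.RangeIndex(n)[keep]

    return DesignMatrix(
        y=y_k,
        X=X_k,
        strata=s_k,
        column_map=column_map,
        index=idx,
        n_dropped_incomplete=n_incomplete,
        n_dropped_missing=n_missing,
        degenerate_strata=degenerate,
    )
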