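"""Geometric-mean annual change of road traffic deaths and 2021/2030 projections.

The average annual change rate is the constant multiplicative rate carrying
the first observed road-traffic death count to the last::

    r = (D_last / D_first) ** (1 / (last_year - first_year)) - 1

(the geometric mean of year-over-year ratios collapses to this endpoint
form; gaps are annualized through the exponent, and a final year with zero
deaths gives r = -1). Deaths are projected as
``D_Y = D_base * (1 + r) ** (Y - base_year)`` for Y in {2021, 2030}; the
projected percent change 2021→2030 is ``100 * ((1 + r)**9 - 1)``, and a
country is *on track* for the UN target of halving road traffic deaths by
2030 when that change is <= -50%.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .taxonomy import CodeSetRegistry, road_traffic_mask


class UndefinedTrendError(ValueError):
    """Trend undefined: fewer than two observed years, or zero first-year deaths."""


@dataclass(frozen=True)
class TrendEstimate:
    """Average annual change rate r (signed fraction/year) and the span used."""

    country: str
    r: float
    first_year: int
    last_year: int
    n_years_used: int
    corrected: bool = False


@dataclass(frozen=True)
class ProjectionResult:
    country: str
    deaths_2021: float
    deaths_2030: float
    pct_change_2021_2030: float
    on_track: bool
    corrected: bool = False


class ShiftClass(enum.Enum):
    """How correction moved a country's annual change rate."""

    SIGN_FLIP_POS = "sign_flip_pos"
    SIGN_FLIP_NEG = "sign_flip_neg"
    SHIFT_GT_10PT = "shift_gt_10pt"
    MINOR = "minor"


def average_annual_change(
    series: Mapping[int, float], country: str = "", corrected: bool = False
) -> TrendEstimate:
    """Geometric-mean average annual change over the observed endpoints.

    Requires >= 2 observed years and positive deaths in the first year;
    zero deaths in the last year give r = -1 (a -100% annual change).
    """
    years = sorted(int(y) for y in series)
    if len(years) < 2:
        raise UndefinedTrendError(f"{country or 'series'}: need >= 2 observed years")
    first, last = years[0], years[-1]
    d0, d1 = float(series[first]), float(series[last])
    if d0 <= 0:
        raise UndefinedTrendError(
            f"{country or 'series'}: first-year deaths must be > 0"
        )
    if d1 == 0:
        r = -1.0
    else:
        r = (d1 / d0) ** (1.0 / (last - first)) - 1.0
    return TrendEstimate(
        country=country, r=r, first_year=first, last_year=last,
        n_years_used=len(years), corrected=corrected,
    )


def project(
    trend: TrendEstimate,
    base_year_deaths: float,
    base_year: int | None = None,
) -> ProjectionResult:
    """Project road traffic deaths to 2021 and 2030 from the last observed year.

    ``pct_change_2021_2030`` is independent of the base and equals
    ``100 * ((1 + r)**9 - 1)``; ``on_track`` iff it is <= -50 (with a 1e-9
    guard so float round-off at the exact halving boundary still counts).
    """
    base_year = trend.last_year if base_year is None else int(base_year)
    r = trend.r
    d2021 = float(base_year_deaths) * (1.0 + r) ** (2021 - base_year)
    d2030 = float(base_year_deaths) * (1.0 + r) ** (2030 - base_year)
    pct = 100.0 * ((1.0 + r) ** 9 - 1.0)
    return ProjectionResult(
        country=trend.country, deaths_2021=d2021, deaths_2030=d2030,
        pct_change_2021_2030=pct, on_track=pct <= -50.0 + 1e-9,
        corrected=trend.corrected,
    )


def classify_shift(
    uncorrected: TrendEstimate, corrected: TrendEstimate
) -> ShiftClass:
    """Classify how correction shifted the annual change rate.

    Zero counts as its own sign, so 0 → positive is a positive sign flip;
    otherwise a move of more than 10 percentage points on the annual rate is
    a large shift, anything else minor.
    """
    s_u, s_c = np.sign(uncorrected.r), np.sign(corrected.r)
    if s_c > s_u:
        return ShiftClass.SIGN_FLIP_POS
    if s_c < s_u:
        return ShiftClass.SIGN_FLIP_NEG
    if abs(100.0 * corrected.r - 100.0 * uncorrected.r) > 10.0:
        return ShiftClass.SHIFT_GT_10PT
    return ShiftClass.MINOR


# -- table-level helpers ------------------------------------------------------


def road_traffic_series(
    table: pd.DataFrame, registry: CodeSetRegistry
) -> pd.Series:
    """Road traffic deaths (V01-V89) per (country, year)."""
    mask = road_traffic_mask(table["cause"], registry)
    return table[mask.to_numpy()].groupby(["country", "year"])["deaths"].sum()


def trends_table(
    table: pd.DataFrame, registry: CodeSetRegistry, corrected: bool = False
) -> pd.DataFrame:
    """Per-country trend estimates; countries with undefined trends are
    skipped with a warning."""
    series = road_traffic_series(table, registry)
    rows = []
    for country in series.index.get_level_values("country").unique():
        s = series.loc[country].to_dict()
        try:
            t = average_annual_change(s, country=country, corrected=corrected)
        except UndefinedTrendError as exc:
            warnings.warn(str(exc))
            continue
        rows.append(t)
    return pd.DataFrame([t.__dict__ for t in rows])


def projections_table(
    table: pd.DataFrame, registry: CodeSetRegistry, corrected: bool = False
) -> pd.DataFrame:
    """Per-country 2021/2030 projections chained from the last observed year."""
    series = road_traffic_series(table, registry)
    rows = []
    for country in series.index.get_level_values("country").unique():
        s = series.loc[country].to_dict()
        try:
            t = average_annual_change(s, country=country, corrected=corrected)
        except UndefinedTrendError as exc:
            warnings.warn(str(exc))
            continue
        p = project(t, base_year_deaths=s[t.last_year])
        rows.append({**p.__dict__, "r": t.r})
    return pd.DataFrame(rows)
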