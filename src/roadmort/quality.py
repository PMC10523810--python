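"""Data-availability and coding-quality indicators.

Two indicators approximate the quality of road traffic mortality data in a
civil-registration panel: (i) *availability* — in how many years of the
study range a country reports any deaths; and (ii) *coding quality* — per
country-year, the percentage of deaths carrying each of the five categories
of nonspecific codes, measured against that category's own hierarchy level
(all causes, injuries, unintentional injuries, transport, road traffic) and
classified into five 20-point bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .taxonomy import (
    CodeSetRegistry,
    GARBAGE_CASCADE,
    NonspecificCategory,
    categorize,
    denominator_mask,
)

#: Bin labels for nonspecific-code percentages (lower bins upper-inclusive:
#: exactly 20% falls in P0_20, 20.5% in P21_40, ...).
BIN_LABELS = ("P0_20", "P21_40", "P41_60", "P61_80", "P81_100")
_BIN_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass
class QualityReport:
    """Availability per country plus per country-year-category proportions."""

    availability: pd.Series  # index country -> years available
    proportions: pd.DataFrame  # country, year, category, garbage_deaths,
    #                            denominator_deaths, proportion, bin


def availability_summary(
    table: pd.DataFrame,
    year_range: tuple[int, int],
    countries: Iterable[str] | None = None,
) -> pd.Series:
    """Years within *year_range* in which each country has >= 1 death row.

    Countries listed in *countries* but absent from the table report 0.
    """
    y0, y1 = year_range
    sub = table[(table["year"] >= y0) & (table["year"] <= y1)]
    counts = sub.groupby("country")["year"].nunique()
    universe = sorted(set(table["country"]) | set(countries or []))
    return counts.reindex(universe, fill_value=0).rename("years_available")


def nonspecific_proportions(
    table: pd.DataFrame,
    registry: CodeSetRegistry,
    include_own_garbage: bool = True,
) -> pd.DataFrame:
    """Percentage of nonspecific deaths per (country, year, category).

    For each category the numerator is the deaths carrying that category's
    garbage codes and the denominator is the deaths in its hierarchy level;
    by default the level's own garbage codes count in the denominator
    (``include_own_garbage=False`` excludes them). A zero denominator yields
    a missing (NaN) proportion, never 0.
    """
    cats = categorize(table["cause"], registry)
    country_years = pd.MultiIndex.from_frame(
        table[["country", "year"]].drop_duplicates()
    )
    frames = []
    for category in GARBAGE_CASCADE:
        gmask = cats == category
        dmask = denominator_mask(table["cause"], category, registry)
        if not include_own_garbage:
            dmask = dmask & ~gmask
        g = table[gmask].groupby(["country", "year"])["deaths"].sum()
        d = table[dmask].groupby(["country", "year"])["deaths"].sum()
        merged = (
            pd.concat(
                [g.rename("garbage_deaths"), d.rename("denominator_deaths")], axis=1
            )
            .reindex(country_years)
            .fillna(0.0)
        )
        merged.index.names = ["country", "year"]
        with np.errstate(invalid="ignore", divide="ignore"):
            merged["proportion"] = np.where(
                merged["denominator_deaths"] > 0,
                100.0 * merged["garbage_deaths"] / merged["denominator_deaths"],
                np.nan,
            )
        merged["category"] = category.name
        frames.append(merged.reset_index())
    out = pd.concat(frames, ignore_index=True)
    out["bin"] = bin_proportions(out["proportion"])
    cols = ["country", "year", "category", "garbage_deaths",
            "denominator_deaths", "proportion", "bin"]
    return out[cols].sort_values(["country", "year", "category"]).reset_index(drop=True)


def bin_proportions(proportions: pd.Series | float) -> pd.Series | str:
    """Classify percentages into the five 20-point bins.

    Boundaries belong to the lower bin ([0,20], (20,40], ...); values outside
    [0, 100] raise. NaN (undefined proportion) stays NaN.
    """
    scalar = np.isscalar(proportions)
    s = pd.Series([proportions]) if scalar else pd.Series(proportions)
    valid = s.dropna()
    if ((valid < 0) | (valid > 100)).any():
        bad = valid[(valid < 0) | (valid > 100)].tolist()[:5]
        raise ValueError(f"proportions outside [0, 100]: {bad}")
    binned = pd.cut(
        s, bins=_BIN_EDGES, labels=BIN_LABELS, include_lowest=True, right=True
    ).astype(object)
    if scalar:
        return binned.iloc[0]
    binned.index = s.index
    return binned


def assess(
    table: pd.DataFrame,
    registry: CodeSetRegistry,
    year_range: tuple[int, int],
    countries: Iterable[str] | None = None,
    include_own_garbage: bool = True,
) -> QualityReport:
    """Full quality report: availability plus binned proportions."""
    return QualityReport(
        availability=availability_summary(table, year_range, countries),
        proportions=nonspecific_proportions(table, registry, include_own_garbage),
    )


def countries_over_threshold(
    proportions: pd.DataFrame, threshold: float = 20.0
) -> pd.Series:
    """Average number of countries per reported year whose nonspecific share
    exceeds *threshold* percent, by category (abstract-style summary)."""
    flagged = proportions[proportions["proportion"] > threshold]
    per_year = flagged.groupby(["category", "year"])["country"].nunique()
    n_years = proportions.groupby("category")["year"].nunique()
    return (
        per_year.groupby("category").sum() / n_years
    ).reindex(n_years.index).fillna(0.0).rename("mean_countries_over_threshold")
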