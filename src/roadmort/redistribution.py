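"""Proportionate redistribution of garbage-coded deaths with adaptive windows.

The proportionate method assumes deaths with nonspecific codes follow the
same cause distribution as deaths with specific codes, and reallocates each
garbage category's mass across its target set in proportion to the observed
specific-cause counts. The reference distribution is pooled over an adaptive
temporal window driven by how bad the coding is in the study year:

====================  =================================
nonspecific share     years pooled
====================  =================================
< 30%                 the study year only
30%-49%               3 years (year ± 1)
50%-69%               5 years (year ± 2)
>= 70%                7 years (year ± 3)
====================  =================================

If any nominal window year is unavailable for the country, *all* available
years are pooled instead. Categories cascade outermost level first
(ill-defined → undetermined intent → unspecified unintentional →
unspecified transport → unspecified road traffic); each step's output feeds
the next step's proportions and pools. A conservation ledger (provenance +
unallocated mass) accounts for every garbage death.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import io as mio
from .taxonomy import (
    CodeSetRegistry,
    GARBAGE_CASCADE,
    NonspecificCategory,
    categorize,
    denominator_mask,
    target_mask,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowRule:
    """Breakpoints on the nonspecific share and the half-widths they select."""

    thresholds: tuple[float, ...] = (0.30, 0.50, 0.70)
    half_widths: tuple[int, ...] = (0, 1, 2, 3)

    def __post_init__(self) -> None:
        if len(self.half_widths) != len(self.thresholds) + 1:
            raise ValueError("need one more half-width than thresholds")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be increasing")
        if list(self.half_widths) != sorted(self.half_widths):
            raise ValueError("half-widths must be non-decreasing (monotone rule)")

    @classmethod
    def same_year(cls) -> "WindowRule":
        """Always use the study year only (no temporal pooling)."""
        return cls(half_widths=(0, 0, 0, 0))


def select_window(
    proportion: float,
    year: int,
    available_years: Iterable[int],
    rule: WindowRule | None = None,
) -> tuple[int, ...]:
    """Years pooled for redistribution in *year* given the nonspecific share.

    *proportion* is a fraction in [0, 1]. Thresholds belong to the wider
    window (0.30 → 3 years). If any nominal window year is missing from
    *available_years*, all available years are returned.
    """
    rule = rule or WindowRule()
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion must be in [0, 1]: {proportion}")
    avail = sorted({int(y) for y in available_years})
    if not avail:
        raise ValueError("available_years is empty")
    i = sum(proportion >= t for t in rule.thresholds)
    hw = rule.half_widths[i]
    nominal = tuple(range(year - hw, year + hw + 1))
    if all(y in set(avail) for y in nominal):
        return nominal
    return tuple(avail)


@dataclass
class RedistributedTable:
    """Mortality table after redistribution, with a conservation ledger.

    ``table`` holds fractional counts; ``provenance`` records, per output
    cell and garbage category, the mass that category contributed;
    ``unallocated`` records garbage mass that found no target pool.
    """

    table: pd.DataFrame
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=mio.KEY_COLUMNS + ["category", "deaths"]
        )
    )
    unallocated: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["country", "year", "category", "deaths"]
        )
    )


def _allocate(
    garbage: pd.DataFrame,
    pool: pd.DataFrame,
    strata: str,
) -> tuple[pd.DataFrame, float]:
    """Allocate each garbage stratum's mass over the pooled target weights.

    Fallback ladder when a (sex, age) stratum has no pooled targets: pool
    sexes within the age band, then pool everything; mass that still finds
    no weights is returned as unallocated.
    """
    p_sex_age = pool.groupby(["sex", "age_group", "cause"], observed=True)[
        "deaths"
    ].sum()
    p_age = pool.groupby(["age_group", "cause"], observed=True)["deaths"].sum()
    p_all = pool.groupby("cause", observed=True)["deaths"].sum()
    p_all = p_all[p_all > 0]
    out_frames: list[pd.DataFrame] = []
    unallocated = 0.0

    if strata == "none":
        g_total = garbage["deaths"].sum()
        w = pool.groupby(["sex", "age_group", "cause"], observed=True)["deaths"].sum()
        w = w[w > 0]
        if w.empty:
            return pd.DataFrame(columns=["sex", "age_group", "cause", "deaths"]), g_total
        alloc = (g_total * w / w.sum()).rename("deaths").reset_index()
        return alloc, 0.0

    g_strata = garbage.groupby(["sex", "age_group"], observed=True)["deaths"].sum()
    for (sex, age), g_mass in g_strata.items():
        if g_mass <= 0:
            continue
        w = None
        try:
            cand = p_sex_age.loc[(sex, age)]
            cand = cand[cand > 0]
            if len(cand):
                w = cand
        except KeyError:
            pass
        if w is None:
            try:
                cand = p_age.loc[age]
                cand = cand[cand > 0]
                if len(cand):
                    w = cand
            except KeyError:
                pass
        if w is None:
            if len(p_all):
                w = p_all
            else:
                unallocated += g_mass
                continue
        alloc = (g_mass * w / w.sum()).rename("deaths").reset_index()
        alloc["sex"] = sex
        alloc["age_group"] = age
        out_frames.append(alloc[["sex", "age_group", "cause", "deaths"]])
    if not out_frames:
        return pd.DataFrame(columns=["sex", "age_group", "cause", "deaths"]), unallocated
    return pd.concat(out_frames, ignore_index=True), unallocated


def redistribute_category(
    table: pd.DataFrame,
    category: NonspecificCategory,
    registry: CodeSetRegistry,
    window_rule: WindowRule | None = None,
    strata: str = "age_sex",
    include_own_garbage_in_denominator: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One cascade step: reallocate *category*'s garbage mass.

    Returns ``(delta, unallocated)``: *delta* rows (canonical key columns +
    fractional deaths) to merge into the table, and per country-year
    unallocated mass. The input table is not modified; garbage-row removal
    is the caller's responsibility.
    """
    if category is NonspecificCategory.NONE:
        raise ValueError("cannot redistribute NONE")
    if strata not in ("age_sex", "none"):
        raise ValueError(f"unknown strata mode: {strata}")
    rule = window_rule or WindowRule()
    table = table.reset_index(drop=True)
    cats = categorize(table["cause"], registry)
    gmask = (cats == category).to_numpy()
    empty_delta = pd.DataFrame(columns=mio.MORTALITY_COLUMNS)
    empty_un = pd.DataFrame(columns=["country", "year", "category", "deaths"])
    if not gmask.any():
        return empty_delta, empty_un
    tmask = target_mask(table["cause"], category, registry).to_numpy()
    dmask = denominator_mask(table["cause"], category, registry).to_numpy()
    if not include_own_garbage_in_denominator:
        dmask = dmask & ~gmask

    deltas: list[pd.DataFrame] = []
    unalloc: list[dict] = []
    for country, cdf in table.groupby("country", observed=True):
        idx = cdf.index.to_numpy()
        available = sorted(cdf["year"].unique())
        c_g = cdf[gmask[idx]]
        if c_g.empty:
            continue
        c_t = cdf[tmask[idx]]
        c_d = cdf[dmask[idx]]
        denom_by_year = c_d.groupby("year")["deaths"].sum()
        garbage_by_year = c_g.groupby("year")["deaths"].sum()
        for year, g_year in c_g.groupby("year"):
            g_total = garbage_by_year.loc[year]
            if g_total <= 0:
                continue
            denom = denom_by_year.get(year, 0.0)
            proportion = float(g_total / denom) if denom > 0 else 1.0
            window = select_window(min(proportion, 1.0), int(year), available, rule)
            pool = c_t[c_t["year"].isin(window)]
            alloc, un = _allocate(g_year, pool, strata)
            if un > 0:
                unalloc.append(
                    dict(country=country, year=int(year),
                         category=category.name, deaths=float(un))
                )
                log.warning(
                    "%s %s: %.6g deaths of %s unallocated (empty target pool)",
                    country, year, un, category.name,
                )
            if len(alloc):
                alloc = alloc.copy()
                alloc.insert(0, "year", int(year))
                alloc.insert(0, "country", country)
                deltas.append(alloc[mio.MORTALITY_COLUMNS])
    delta = (
        pd.concat(deltas, ignore_index=True) if deltas else empty_delta
    )
    un_df = pd.DataFrame(unalloc) if unalloc else empty_un
    return delta, un_df


def redistribute_all(
    table: pd.DataFrame,
    registry: CodeSetRegistry,
    window_rule: WindowRule | None = None,
    include_level5: bool = True,
    strata: str = "age_sex",
    include_own_garbage_in_denominator: bool = True,
) -> RedistributedTable:
    """Run the full cascade and return the corrected table with its ledger.

    The first four categories are always processed (they add mass to road
    traffic from outside); the fifth (road-traffic-unspecified, V87.0-V87.8
    and V89.2) moves mass only within road traffic into occupant and
    motorcyclist codes and is applied iff *include_level5* — user-specific
    rates for occupants and motorcyclists use all five, other scopes the
    first four.
    """
    work = table.copy()
    cats_to_run = GARBAGE_CASCADE[:4] + (
        (NonspecificCategory.UNSPEC_RT,) if include_level5 else ()
    )
    prov_frames: list[pd.DataFrame] = []
    un_frames: list[pd.DataFrame] = []
    for category in cats_to_run:
        delta, un = redistribute_category(
            work, category, registry, window_rule, strata,
            include_own_garbage_in_denominator,
        )
        cats = categorize(work["cause"], registry)
        work = work[cats != category]
        if len(delta):
            work = (
                pd.concat([work, delta], ignore_index=True)
                .groupby(mio.KEY_COLUMNS, as_index=False)["deaths"].sum()
            )
            prov = delta.copy()
            prov["category"] = category.name
            prov_frames.append(prov)
        if len(un):
            un_frames.append(un)
    result = RedistributedTable(table=mio.canonical_sort(work))
    if prov_frames:
        result.provenance = pd.concat(prov_frames, ignore_index=True)
    if un_frames:
        result.unallocated = pd.concat(un_frames, ignore_index=True)
    return result
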