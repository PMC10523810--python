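"""Age-standardized road traffic mortality rates before and after correction.

The age-standardized rate (ASR) weights age-specific death rates by a fixed
standard population::

    ASR = 100000 * sum_a  w_a * D_a / P_a

with ``w_a`` the standard weight of band *a*, ``D_a`` deaths and ``P_a``
person counts. Rates are reported per 100 000 standard population, both
sexes combined. Five scopes are computed: overall road traffic (V01-V89,
user-unspecified codes included) and the four user groups. Corrected rates
for overall/pedestrian/pedal-cyclist scopes come from the four-category
cascade; occupant/motorcyclist scopes from the five-category cascade (the
fifth category moves mass only within road traffic, into those two groups).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .redistribution import RedistributedTable
from .taxonomy import (
    CodeSetRegistry,
    RoadUserGroup,
    group_series,
    road_traffic_mask,
)

SCOPES = ("overall_rt", "pedestrian", "pedal_cyclist", "motorcyclist", "occupant")

_SCOPE_GROUP = {
    "pedestrian": RoadUserGroup.PEDESTRIAN,
    "pedal_cyclist": RoadUserGroup.PEDAL_CYCLIST,
    "motorcyclist": RoadUserGroup.MOTORCYCLIST,
    "occupant": RoadUserGroup.OCCUPANT,
}


class ZeroPopulationError(ValueError):
    """Deaths observed in an age band with no population."""


def age_standardize(
    deaths_by_age: Mapping[str, float] | pd.Series,
    population_by_age: Mapping[str, float] | pd.Series,
    standard: mio.StandardPopulation,
) -> float:
    """Age-standardized rate per 100 000 standard population.

    Bands absent from *deaths_by_age* contribute 0; deaths in a band with
    zero/missing population raise :class:`ZeroPopulationError` naming it.
    """
    d = dict(deaths_by_age)
    p = dict(population_by_age)
    rate = 0.0
    for band, w in standard.weights.items():
        deaths = float(d.get(band, 0.0))
        if deaths == 0.0:
            continue
        pop = float(p.get(band, 0.0))
        if pop <= 0.0:
            raise ZeroPopulationError(f"deaths but no population in band {band}")
        rate += w * deaths / pop
    return 100_000.0 * rate


def _scope_table(
    table: pd.DataFrame, scope: str, registry: CodeSetRegistry
) -> pd.DataFrame:
    causes = table["cause"]
    if scope == "overall_rt":
        mask = road_traffic_mask(causes, registry)
    else:
        mask = (group_series(causes, registry) == _SCOPE_GROUP[scope]).fillna(False)
    return table[mask.to_numpy()]


def _asr_series(
    table: pd.DataFrame,
    scope: str,
    population: pd.DataFrame,
    standard: mio.StandardPopulation,
    registry: CodeSetRegistry,
    country_years: pd.DataFrame,
) -> pd.Series:
    """ASR per (country, year) for one scope; absent deaths give rate 0."""
    tab = mio.allocate_unknown_age(table)
    sub = _scope_table(tab, scope, registry)
    deaths = sub.groupby(["country", "year", "age_group"], observed=True)[
        "deaths"
    ].sum()
    pop = population.groupby(["country", "year", "age_group"], observed=True)[
        "population"
    ].sum()
    out = {}
    for country, year in country_years.itertuples(index=False):
        try:
            p = pop.loc[(country, year)]
        except KeyError:
            warnings.warn(f"no population for {country} {year}; result omitted")
            continue
        try:
            d = deaths.loc[(country, year)]
        except KeyError:
            d = pd.Series(dtype=float)
        out[(country, year)] = age_standardize(d, p, standard)
    s = pd.Series(out, dtype=float)
    if len(s):
        s.index.names = ["country", "year"]
    else:
        s.index = pd.MultiIndex.from_tuples([], names=["country", "year"])
    return s


def user_specific_rates(
    uncorrected: pd.DataFrame,
    corrected_l4: RedistributedTable | pd.DataFrame,
    corrected_l5: RedistributedTable | pd.DataFrame,
    population: pd.DataFrame,
    standard: mio.StandardPopulation,
    registry: CodeSetRegistry,
) -> pd.DataFrame:
    """Rate results per (country, year, scope): uncorrected vs corrected ASR.

    *corrected_l4* must come from the cascade without the fifth category,
    *corrected_l5* with it. Returns columns ``country, year, scope,
    uncorrected_rate, corrected_rate, ratio, pct_change`` where ``ratio`` is
    corrected/uncorrected (1.0 when both rates are 0, NaN when only the
    uncorrected rate is 0).
    """
    l4 = getattr(corrected_l4, "table", corrected_l4)
    l5 = getattr(corrected_l5, "table", corrected_l5)
    cy = uncorrected[["country", "year"]].drop_duplicates()
    rows = []
    for scope in SCOPES:
        corrected = l5 if scope in ("motorcyclist", "occupant") else l4
        unc = _asr_series(uncorrected, scope, population, standard, registry, cy)
        cor = _asr_series(corrected, scope, population, standard, registry, cy)
        merged = pd.concat(
            [unc.rename("uncorrected_rate"), cor.rename("corrected_rate")], axis=1
        ).reset_index()
        merged["scope"] = scope
        rows.append(merged)
    out = pd.concat(rows, ignore_index=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(
            out["uncorrected_rate"] > 0,
            out["corrected_rate"] / out["uncorrected_rate"],
            np.where(out["corrected_rate"] == 0, 1.0, np.nan),
        )
    out["pct_change"] = 100.0 * (out["ratio"] - 1.0)
    cols = ["country", "year", "scope", "uncorrected_rate", "corrected_rate",
            "ratio", "pct_change"]
    return out[cols].sort_values(["country", "year", "scope"]).reset_index(drop=True)
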