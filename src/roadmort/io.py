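"""Readers/writers for mortality panels, population tables and standard populations.

Two mortality dialects are supported:

* the WHO Mortality Database ICD-10 part-file layout (columns ``Country,
  Admin1, SubDiv, Year, List, Cause, Sex, Frmat, IM_Frmat, Deaths1..Deaths26``,
  with per-row age formats), and
* a canonical tidy long CSV with columns
  ``country, year, sex, age_group, cause, deaths``.

All tables are plain :class:`pandas.DataFrame` objects in the canonical long
layout; :func:`validate_mortality` is the single schema gate. Ages use 18
five-year bands 0-4 .. 85+ plus ``UNKNOWN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .taxonomy import validate_code

log = logging.getLogger(__name__)

AGE_BANDS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 85, 5)
) + ("85+",)
UNKNOWN_AGE = "UNKNOWN"
SEXES = ("male", "female", "unknown")
MORTALITY_COLUMNS = ["country", "year", "sex", "age_group", "cause", "deaths"]
KEY_COLUMNS = ["country", "year", "sex", "age_group", "cause"]

_AGE_ORDER = {b: i for i, b in enumerate(AGE_BANDS + (UNKNOWN_AGE,))}


class SchemaError(ValueError):
    """A table violates the canonical mortality/population schema."""


def _band_for(age_lo: int) -> str:
    return "85+" if age_lo >= 85 else f"{(age_lo // 5) * 5}-{(age_lo // 5) * 5 + 4}"


def canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Sort by country, year, sex, age band order, cause."""
    key = df["age_group"].map(_AGE_ORDER)
    return (
        df.assign(_age=key)
        .sort_values(["country", "year", "sex", "_age", "cause"], kind="mergesort")
        .drop(columns="_age")
        .reset_index(drop=True)
    )


def validate_mortality(
    df: pd.DataFrame, *, allow_unknown_age: bool = True
) -> pd.DataFrame:
    """Validate and canonicalize a long mortality table.

    Checks columns, sex/age vocabularies, code syntax, non-negative deaths
    and duplicate keys; returns a sorted copy. Offending rows are listed in
    the raised :class:`SchemaError`.
    """
    missing = [c for c in MORTALITY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = df[MORTALITY_COLUMNS].copy()
    out["country"] = out["country"].astype(str)
    out["year"] = out["year"].astype(int)
    out["sex"] = out["sex"].astype(str)
    bad_sex = sorted(set(out["sex"]) - set(SEXES))
    if bad_sex:
        raise SchemaError(f"unknown sex values: {bad_sex}")
    allowed_ages = set(AGE_BANDS) | ({UNKNOWN_AGE} if allow_unknown_age else set())
    out["age_group"] = out["age_group"].astype(str)
    bad_age = sorted(set(out["age_group"]) - allowed_ages)
    if bad_age:
        raise SchemaError(f"unknown age groups: {bad_age}")
    out["cause"] = out["cause"].map({c: validate_code(c) for c in out["cause"].unique()})
    out["deaths"] = out["deaths"].astype(float)
    neg = out[out["deaths"] < 0]
    if len(neg):
        raise SchemaError(f"negative deaths in rows: {neg.index.tolist()[:10]}")
    dup = out.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        keys = out.loc[dup, KEY_COLUMNS].head(5).to_dict("records")
        raise SchemaError(f"duplicate (country,year,sex,age_group,cause) keys: {keys}")
    return canonical_sort(out)


def read_long_csv(path) -> pd.DataFrame:
    """Read a canonical long mortality CSV and validate it."""
    df = pd.read_csv(path, dtype={"country": str})
    if df.empty and set(MORTALITY_COLUMNS) <= set(df.columns):
        out = pd.DataFrame({
            "country": pd.Series(dtype=str), "year": pd.Series(dtype=int),
            "sex": pd.Series(dtype=str), "age_group": pd.Series(dtype=str),
            "cause": pd.Series(dtype=str), "deaths": pd.Series(dtype=float),
        })
        return out
    return validate_mortality(df)


def write_long_csv(table: pd.DataFrame, path) -> None:
    """Write a mortality table in canonical order (round-trips exactly)."""
    canonical_sort(table[MORTALITY_COLUMNS]).to_csv(path, index=False)


# -- population ---------------------------------------------------------------

POPULATION_COLUMNS = ["country", "year", "sex", "age_group", "population"]


def validate_population(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    out = df[POPULATION_COLUMNS].copy()
    out["country"] = out["country"].astype(str)
    out["year"] = out["year"].astype(int)
    bad_age = sorted(set(out["age_group"]) - set(AGE_BANDS))
    if bad_age:
        raise SchemaError(f"unknown age groups in population: {bad_age}")
    out["population"] = out["population"].astype(float)
    if (out["population"] <= 0).any():
        bad = out[out["population"] <= 0].index.tolist()[:10]
        raise SchemaError(f"non-positive population in rows: {bad}")
    dup = out.duplicated(subset=["country", "year", "sex", "age_group"], keep=False)
    if dup.any():
        raise SchemaError("duplicate population keys")
    return out.reset_index(drop=True)


def read_population_csv(path) -> pd.DataFrame:
    return validate_population(pd.read_csv(path, dtype={"country": str}))


# -- standard population ------------------------------------------------------


@dataclass(frozen=True)
class StandardPopulation:
    """Age weights of a standard population (18 bands summing to 1)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        bands = set(self.weights)
        if bands != set(AGE_BANDS):
            raise SchemaError(
                f"standard population must cover exactly the 18 bands; "
                f"missing={sorted(set(AGE_BANDS) - bands)} extra={sorted(bands - set(AGE_BANDS))}"
            )
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-6:
            raise SchemaError(f"standard population weights sum to {total}, not 1")


def load_standard_population(path=None) -> StandardPopulation:
    """Load age-standardization weights; the bundled default is the 18-band
    WHO world standard population."""
    if path is None:
        ref = resources.files("roadmort.data").joinpath("who_world_standard.csv")
        with ref.open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    if not {"age_group", "weight"} <= set(df.columns):
        raise SchemaError("standard population file needs age_group, weight columns")
    return StandardPopulation(dict(zip(df["age_group"].astype(str), df["weight"].astype(float))))


# -- WHO Mortality Database dialect -------------------------------------------

# Fixed meanings of the fine-format Deaths columns (Deaths2..Deaths25).
_FIVE_YEAR = {i: (5 * (i - 6), 5 * (i - 6) + 4) for i in range(7, 23)}  # 5-9 .. 80-84

#: Per-Frmat mapping Deaths column index -> inclusive age span (years).
FRMAT_AGE_COLUMNS: dict[int, dict[int, tuple[int, int]]] = {
    0: {2: (0, 0), 3: (1, 1), 4: (2, 2), 5: (3, 3), 6: (4, 4),
        **_FIVE_YEAR, 23: (85, 89), 24: (90, 94), 25: (95, 120)},
    1: {2: (0, 0), 3: (1, 1), 4: (2, 2), 5: (3, 3), 6: (4, 4),
        **_FIVE_YEAR, 23: (85, 120)},
    2: {2: (0, 0), 3: (1, 4), **_FIVE_YEAR, 23: (85, 120)},
    3: {2: (0, 0), 3: (1, 4), 7: (5, 14), 9: (15, 24), 11: (25, 34),
        13: (35, 44), 15: (45, 54), 17: (55, 64), 19: (65, 74), 21: (75, 120)},
}

_SEX_CODES = {"1": "male", "2": "female", "9": "unknown"}


def normalize_who_cause(raw: str) -> str:
    """Normalize WHO dialect causes: "V873" -> "V87.3", "X59" unchanged."""
    c = str(raw).strip().upper()
    if len(c) == 4 and c[0].isalpha() and c[1:].isdigit():
        c = f"{c[:3]}.{c[3]}"
    return validate_code(c)


def _split_span(lo: int, hi: int, pop_by_band: Mapping[str, float] | None):
    """Apportion an age span over canonical bands; weights are population
    shares when available, else the span's overlap width in years."""
    bands: list[tuple[str, float]] = []
    for b_lo in range(0, 90, 5):
        b_hi = 120 if b_lo == 85 else b_lo + 4
        ov = min(hi, b_hi) - max(lo, b_lo) + 1
        if ov > 0:
            band = _band_for(b_lo)
            w = ov
            if pop_by_band is not None and band in pop_by_band:
                w = pop_by_band[band] * ov / (b_hi - b_lo + 1 if b_lo < 85 else 36)
            bands.append((band, float(w)))
    total = sum(w for _, w in bands)
    return [(b, w / total) for b, w in bands]


def read_who_icd10(
    path,
    frmat_policy: str = "split",
    population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Read a WHO Mortality Database ICD-10 part file into the canonical layout.

    Per-row ``Frmat`` codes describe which Deaths columns are populated and
    what ages they span; fine formats are aggregated up to the 18 canonical
    bands, and coarse lumped bands are split across bands (proportionally to
    *population* if given, else by width in years) when ``frmat_policy`` is
    ``"split"``, or rejected when ``"strict"``. ``Deaths26`` (age unknown)
    maps to the ``UNKNOWN`` band; ``Deaths1`` serves only as a checksum;
    subnational rows (non-empty Admin1/SubDiv) are excluded.
    """
    if frmat_policy not in ("split", "strict"):
        raise ValueError(f"unknown frmat_policy: {frmat_policy}")
    df = pd.read_csv(path, dtype=str).fillna("")
    required = ["Country", "Admin1", "SubDiv", "Year", "Cause", "Sex", "Frmat"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing WHO columns: {missing}")
    national = df[(df["Admin1"].str.strip() == "") & (df["SubDiv"].str.strip() == "")]
    dup = national.duplicated(subset=["Country", "Year", "Sex", "Cause"], keep=False)
    if dup.any():
        keys = national.loc[dup, ["Country", "Year", "Sex", "Cause"]].head(5)
        raise SchemaError(f"duplicate WHO rows: {keys.to_dict('records')}")

    pop_shares: dict[tuple[str, int, str], dict[str, float]] = {}
    if population is not None:
        p = validate_population(population)
        for (c, y, s), g in p.groupby(["country", "year", "sex"]):
            tot = g["population"].sum()
            pop_shares[(c, y, s)] = dict(
                zip(g["age_group"], g["population"] / tot)
            )

    records: list[dict] = []
    for idx, row in national.iterrows():
        frmat = int(row["Frmat"])
        if frmat not in FRMAT_AGE_COLUMNS:
            raise SchemaError(f"unknown Frmat {frmat} in row {idx}")
        colmap = FRMAT_AGE_COLUMNS[frmat]
        country = row["Country"].strip()
        year = int(row["Year"])
        sex = _SEX_CODES.get(row["Sex"].strip(), "unknown")
        cause = normalize_who_cause(row["Cause"])

        def deaths_in(i: int) -> float:
            v = str(row.get(f"Deaths{i}", "")).strip()
            return float(v) if v else 0.0

        total = 0.0
        for col, (lo, hi) in colmap.items():
            d = deaths_in(col)
            if d == 0:
                continue
            total += d
            spans_bands = _band_for(lo) != _band_for(min(hi, 85))
            if spans_bands and frmat_policy == "strict":
                raise SchemaError(
                    f"row {idx}: Frmat {frmat} lumps ages {lo}-{hi}; "
                    "pass frmat_policy='split' to apportion"
                )
            if spans_bands:
                log.warning(
                    "row %s: splitting lumped age span %s-%s over canonical bands",
                    idx, lo, hi,
                )
                shares = _split_span(lo, hi, pop_shares.get((country, year, sex)))
            else:
                shares = [(_band_for(lo), 1.0)]
            for band, share in shares:
                records.append(
                    dict(country=country, year=year, sex=sex,
                         age_group=band, cause=cause, deaths=d * share)
                )
        d26 = deaths_in(26)
        if d26:
            total += d26
            records.append(
                dict(country=country, year=year, sex=sex,
                     age_group=UNKNOWN_AGE, cause=cause, deaths=d26)
            )
        d1 = deaths_in(1)
        if d1 and abs(d1 - total) > 0.5:
            log.warning(
                "row %s (%s %s %s %s): Deaths1=%s but age columns sum to %s",
                idx, country, year, sex, cause, d1, total,
            )
    if not records:
        return pd.DataFrame(columns=MORTALITY_COLUMNS)
    long = (
        pd.DataFrame.from_records(records)
        .groupby(KEY_COLUMNS, as_index=False)["deaths"].sum()
    )
    return validate_mortality(long)


# -- unknown-age allocation ---------------------------------------------------


def allocate_unknown_age(table: pd.DataFrame) -> pd.DataFrame:
    """Redistribute UNKNOWN-age deaths across age bands.

    Each UNKNOWN row is split proportionally to the known-age distribution of
    the same (country, year, sex, cause); if that cause has no known-age
    deaths, the (country, year, sex) all-cause age distribution is used; if
    nothing is known the row is kept as UNKNOWN with a warning. Totals are
    conserved.
    """
    unk = table[table["age_group"] == UNKNOWN_AGE]
    if unk.empty:
        return table
    known = table[table["age_group"] != UNKNOWN_AGE]
    by_cause = known.groupby(["country", "year", "sex", "cause"])
    by_all = known.groupby(["country", "year", "sex"])
    extra: list[pd.DataFrame] = []
    kept: list[int] = []
    for i, row in unk.iterrows():
        key4 = (row["country"], row["year"], row["sex"], row["cause"])
        try:
            dist = by_cause.get_group(key4)
        except KeyError:
            try:
                dist = by_all.get_group(key4[:3])
            except KeyError:
                kept.append(i)
                log.warning("cannot allocate UNKNOWN-age deaths for %s", key4)
                continue
        w = dist.groupby("age_group", observed=True)["deaths"].sum()
        w = w[w > 0]
        if w.empty:
            kept.append(i)
            continue
        frac = w / w.sum()
        extra.append(
            pd.DataFrame(
                dict(country=row["country"], year=row["year"], sex=row["sex"],
                     age_group=frac.index, cause=row["cause"],
                     deaths=row["deaths"] * frac.values)
            )
        )
    parts = [known, table.loc[kept]] + extra
    out = (
        pd.concat(parts, ignore_index=True)
        .groupby(KEY_COLUMNS, as_index=False)["deaths"].sum()
    )
    return canonical_sort(out)
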