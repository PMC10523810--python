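"""Synthetic civil-registration-style mortality panels with known ground truth.

The generator produces country-year panels of ICD-10-coded death counts with
a configurable true cause distribution, then *injects* garbage coding by
relabelling part of the specific-cause mass into nonspecific codes, category
by category. Because injection only relabels (never creates or destroys
deaths) the pre-injection truth table is a recoverable oracle for every
downstream stage.

Injection applies the five categories from the innermost hierarchy level
outward (road-traffic-unspecified first, ill-defined last), each stealing a
fraction of the *current* specific mass inside its denominator ∩ target set.
The redistribution cascade runs outermost-first and therefore unwinds the
injections in LIFO order: with deterministic fractional injection and
same-year windows it reconstructs the truth exactly.

Two sampling modes exist on both axes: deterministic (expected values,
fractional counts — exact oracles) and stochastic (multinomial truth,
binomial relabelling — realistic integer counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .taxonomy import (
    CodeSetRegistry,
    GARBAGE_CASCADE,
    NonspecificCategory,
    categorize,
    default_registry,
    denominator_mask,
    target_mask,
    road_traffic_mask,
    validate_code,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


#: Default true cause mix: 41 specific ICD-10 codes spanning every level of
#: the cause hierarchy (non-injury; intentional injury; unintentional
#: non-transport; non-road transport; all four road-user groups plus other
#: road vehicles), so every redistribution step has a non-empty target pool.
DEFAULT_CAUSE_MIX: dict[str, float] = {
    # non-injury (0.88)
    "A09": 0.04, "C16": 0.05, "C34": 0.08, "C50": 0.04, "E11": 0.07,
    "I21": 0.20, "I64": 0.14, "J18": 0.09, "J44": 0.07, "K70": 0.05, "N18": 0.05,
    # intentional injury (0.015)
    "X70": 0.007, "X95": 0.005, "Y04": 0.003,
    # unintentional non-transport injury (0.03)
    "W13": 0.005, "W19": 0.008, "W74": 0.004, "X00": 0.005, "X42": 0.008,
    # non-road transport (0.005)
    "V90": 0.002, "V93": 0.001, "V95": 0.001, "V97": 0.001,
    # pedestrians (0.015)
    "V02": 0.003, "V03": 0.006, "V04": 0.004, "V09": 0.002,
    # pedal cyclists (0.005)
    "V12": 0.002, "V13": 0.002, "V18": 0.001,
    # motorcyclists (0.02)
    "V22": 0.006, "V23": 0.006, "V27": 0.005, "V29": 0.003,
    # vehicle occupants (0.025)
    "V43": 0.008, "V47": 0.006, "V49": 0.005, "V58": 0.003, "V69": 0.003,
    # other road vehicles (0.005)
    "V82": 0.002, "V86": 0.003,
}

# death counts skew old; population skews young
_DEATH_AGE_SHAPE = np.array(
    [3, 1, 1, 2, 3, 3, 4, 4, 5, 6, 7, 8, 10, 12, 14, 15, 14, 12], dtype=float
)
_POP_AGE_SHAPE = np.array(
    [9, 9, 9, 8.5, 8, 8, 7.5, 7, 6.5, 6, 5.5, 5, 4, 3, 2, 1.5, 1, 0.5], dtype=float
)

#: Canonical garbage code emitted per category during injection.
CANONICAL_GARBAGE: dict[NonspecificCategory, str] = {
    NonspecificCategory.ILL_DEFINED: "R99",
    NonspecificCategory.UNDETERMINED_INTENT: "Y34",
    NonspecificCategory.UNSPEC_UNINTENTIONAL: "X59",
    NonspecificCategory.UNSPEC_TRANSPORT: "V99",
    NonspecificCategory.UNSPEC_RT: "V89.2",
}


def _default_age_sex() -> dict[tuple[str, str], float]:
    w = _DEATH_AGE_SHAPE / _DEATH_AGE_SHAPE.sum()
    return {
        (sex, band): w[i] / 2
        for sex in ("male", "female")
        for i, band in enumerate(mio.AGE_BANDS)
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic panel.

    Parameters
    ----------
    n_countries:
        Number of synthetic countries ("C01", "C02", ...).
    years:
        Inclusive (first, last) calendar year range.
    true_cause_mix:
        Specific-code probabilities summing to 1; garbage codes rejected.
    age_sex_structure:
        (sex, age band) death-distribution probabilities summing to 1.
    total_deaths_per_country_year:
        Expected all-cause deaths per country-year (int, or map country→int).
    garbage_fractions:
        Per-category fraction of eligible specific mass relabelled to that
        category's garbage code; each in [0, 1).
    annual_change:
        Multiplicative drift per year applied to road-traffic causes
        (scalar or map country→rate); the ground-truth trend.
    injection_mode:
        "proportional" (every eligible cell loses the same fraction — the
        redistribution method's assumption holds exactly) or "biased"
        (relabelling propensity ∝ ``bias_weights``, testing its violation).
    bias_weights:
        Relative propensity per cause code, used when biased.
    sampling:
        "deterministic" (fractional expected counts) or "multinomial".
    injection_sampling:
        "fractional" or "binomial"; defaults to match ``sampling``.
    population_per_country:
        Total persons per country (constant over years).
    seed:
        Seed for all randomness.
    """

    n_countries: int = 20
    years: tuple[int, int] = (2015, 2020)
    true_cause_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_MIX)
    )
    age_sex_structure: Mapping[tuple[str, str], float] = field(
        default_factory=_default_age_sex
    )
    total_deaths_per_country_year: int | Mapping[str, int] = 10_000
    garbage_fractions: Mapping[NonspecificCategory, float] = field(default_factory=dict)
    annual_change: float | Mapping[str, float] = 0.0
    injection_mode: str = "proportional"
    bias_weights: Mapping[str, float] | None = None
    sampling: str = "multinomial"
    injection_sampling: str | None = None
    population_per_country: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.years[0] > self.years[1]:
            raise ConfigError(f"bad year range: {self.years}")
        total = sum(self.true_cause_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"true_cause_mix sums to {total}, not 1")
        if any(p < 0 for p in self.true_cause_mix.values()):
            raise ConfigError("negative cause probability")
        reg = default_registry()
        garbage = [
            c for c in self.true_cause_mix
            if reg.classify(validate_code(c)) is not NonspecificCategory.NONE
        ]
        if garbage:
            raise ConfigError(f"true_cause_mix contains garbage codes: {garbage}")
        ages = sum(self.age_sex_structure.values())
        if abs(ages - 1.0) > 1e-6:
            raise ConfigError(f"age_sex_structure sums to {ages}, not 1")
        for cat, f in self.garbage_fractions.items():
            if not isinstance(cat, NonspecificCategory):
                raise ConfigError(f"garbage_fractions key {cat!r} is not a category")
            if not 0 <= f < 1:
                raise ConfigError(f"garbage fraction for {cat.name} must be in [0,1)")
        if self.injection_mode not in ("proportional", "biased"):
            raise ConfigError(f"unknown injection_mode: {self.injection_mode}")
        if self.injection_mode == "biased" and not self.bias_weights:
            raise ConfigError("biased injection requires bias_weights")
        if self.sampling not in ("deterministic", "multinomial"):
            raise ConfigError(f"unknown sampling: {self.sampling}")
        if self.injection_sampling is None:
            self.injection_sampling = (
                "fractional" if self.sampling == "deterministic" else "binomial"
            )
        if self.injection_sampling not in ("fractional", "binomial"):
            raise ConfigError(f"unknown injection_sampling: {self.injection_sampling}")

    @property
    def countries(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_countries)]

    def drift(self, country: str) -> float:
        if isinstance(self.annual_change, Mapping):
            return float(self.annual_change.get(country, 0.0))
        return float(self.annual_change)

    def total_for(self, country: str) -> float:
        if isinstance(self.total_deaths_per_country_year, Mapping):
            return float(self.total_deaths_per_country_year[country])
        return float(self.total_deaths_per_country_year)


@dataclass
class SimulatedPanel:
    """Observed (garbage-injected) panel, its pre-injection truth, and population."""

    observed: pd.DataFrame
    truth: pd.DataFrame
    population: pd.DataFrame
    config: SimulationConfig


def _cell_frame(config: SimulationConfig, registry: CodeSetRegistry) -> pd.DataFrame:
    """One row per (sex, age, cause) with base probability and RT flag."""
    rows = []
    for (sex, band), p_as in config.age_sex_structure.items():
        for cause, p_c in config.true_cause_mix.items():
            rows.append((sex, band, validate_code(cause), p_as * p_c))
    df = pd.DataFrame(rows, columns=["sex", "age_group", "cause", "p"])
    df["is_rt"] = road_traffic_mask(df["cause"], registry)
    return df


def simulate_panel(
    config: SimulationConfig, registry: CodeSetRegistry | None = None
) -> SimulatedPanel:
    """Generate truth, population and garbage-injected observed tables.

    Deterministic given ``config.seed``; with all garbage fractions zero the
    observed table equals the truth.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    cells = _cell_frame(config, registry)
    y0, y1 = config.years
    frames = []
    for country in config.countries:
        g = config.drift(country)
        total = config.total_for(country)
        for year in range(y0, y1 + 1):
            factor = (1.0 + g) ** (year - y0)
            mean = cells["p"] * total * np.where(cells["is_rt"], factor, 1.0)
            if config.sampling == "deterministic":
                deaths = mean.to_numpy(dtype=float)
            else:
                n = int(round(mean.sum()))
                deaths = rng.multinomial(n, (mean / mean.sum()).to_numpy()).astype(float)
            f = cells[["sex", "age_group", "cause"]].copy()
            f.insert(0, "year", year)
            f.insert(0, "country", country)
            f["deaths"] = deaths
            frames.append(f[f["deaths"] > 0])
    truth = mio.validate_mortality(pd.concat(frames, ignore_index=True))

    pop_w = _POP_AGE_SHAPE / _POP_AGE_SHAPE.sum()
    pop_rows = []
    for country in config.countries:
        for year in range(y0, y1 + 1):
            for sex in ("male", "female"):
                for i, band in enumerate(mio.AGE_BANDS):
                    pop_rows.append(
                        (country, year, sex, band,
                         config.population_per_country * pop_w[i] / 2)
                    )
    population = pd.DataFrame(pop_rows, columns=mio.POPULATION_COLUMNS)

    observed = inject_garbage(truth, config, registry, rng=rng)
    return SimulatedPanel(observed=observed, truth=truth,
                          population=population, config=config)


def _biased_removal(
    deaths: np.ndarray, weights: np.ndarray, fraction: float
) -> np.ndarray:
    """Remove ``fraction`` of total mass, spread ∝ weight×mass, capped at each
    cell (water-filling so the total is exact whenever feasible)."""
    target = fraction * deaths.sum()
    removed = np.zeros_like(deaths)
    free = deaths > 0
    for _ in range(64):
        remaining = target - removed.sum()
        if remaining <= 1e-12 or not free.any():
            break
        w = weights * deaths
        w = np.where(free, w, 0.0)
        if w.sum() <= 0:
            # no weighted mass left: fall back to unweighted proportional
            w = np.where(free, deaths, 0.0)
            if w.sum() <= 0:
                break
        step = remaining * w / w.sum()
        cap = deaths - removed
        take = np.minimum(step, cap)
        removed += take
        free = (deaths - removed) > 1e-15
    return removed


def inject_garbage(
    truth: pd.DataFrame,
    config: SimulationConfig,
    registry: CodeSetRegistry | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Relabel specific-cause deaths into garbage codes per the config.

    Categories are applied innermost level first (reverse cascade order);
    each steals from the current specific cells inside its denominator ∩
    target set. Totals are conserved per (country, year, sex, age_group).
    """
    registry = registry or default_registry()
    cats = categorize(truth["cause"], registry)
    if (cats != NonspecificCategory.NONE).any():
        bad = sorted(truth.loc[cats != NonspecificCategory.NONE, "cause"].unique())
        raise ConfigError(f"truth table contains garbage codes: {bad}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    work = truth.copy()
    garbage_frames = []
    for category in reversed(GARBAGE_CASCADE):
        f = float(config.garbage_fractions.get(category, 0.0))
        if f == 0.0:
            continue
        eligible = (
            denominator_mask(work["cause"], category, registry)
            & target_mask(work["cause"], category, registry)
        ).to_numpy()
        if not eligible.any():
            import warnings

            warnings.warn(
                f"no eligible deaths for {category.name}; injection is a no-op"
            )
            continue
        deaths = work.loc[eligible, "deaths"].to_numpy(dtype=float)
        if config.injection_mode == "biased":
            wts = (
                work.loc[eligible, "cause"]
                .map(lambda c: float(config.bias_weights.get(c, 0.0)))
                .to_numpy()
            )
            if config.injection_sampling == "fractional":
                removed = _biased_removal(deaths, wts, f)
            else:
                exp = _biased_removal(deaths, wts, f)
                with np.errstate(invalid="ignore"):
                    p = np.where(deaths > 0, exp / deaths, 0.0)
                removed = rng.binomial(np.round(deaths).astype(int),
                                       np.clip(p, 0, 1)).astype(float)
        else:
            if config.injection_sampling == "fractional":
                removed = deaths * f
            else:
                removed = rng.binomial(np.round(deaths).astype(int), f).astype(float)
        work.loc[eligible, "deaths"] = deaths - removed
        g = work.loc[eligible, ["country", "year", "sex", "age_group"]].copy()
        g["cause"] = CANONICAL_GARBAGE[category]
        g["deaths"] = removed
        garbage_frames.append(g[g["deaths"] > 0])
    parts = [work[work["deaths"] > 0]] + garbage_frames
    out = (
        pd.concat(parts, ignore_index=True)
        .groupby(mio.KEY_COLUMNS, as_index=False)["deaths"].sum()
    )
    return mio.canonical_sort(out)
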