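"""End-to-end orchestration: ingest/simulate → assess → redistribute → rates
→ trends → project → summary.

All stage outputs are written as CSV (plus a JSON summary and run log) so
every tally is recomputable from the artifacts alone. A single seed drives
all randomness; deterministic configurations reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import quality, rates, synthetic, trends
from .redistribution import RedistributedTable, WindowRule, redistribute_all
from .taxonomy import default_registry, load_registry

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable to YAML."""

    mortality_path: str | None = None
    population_path: str | None = None
    simulate: synthetic.SimulationConfig | None = None
    registry_path: str | None = None
    standard_population_path: str | None = None
    year_range: tuple[int, int] = (2015, 2020)
    window_thresholds: tuple[float, ...] = (0.30, 0.50, 0.70)
    window_half_widths: tuple[int, ...] = (0, 1, 2, 3)
    strata: str = "age_sex"
    out_dir: str = "roadmort_out"
    seed: int = 0

    def window_rule(self) -> WindowRule:
        return WindowRule(tuple(self.window_thresholds), tuple(self.window_half_widths))

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = d["simulate"]
            sim["garbage_fractions"] = {
                k.name if hasattr(k, "name") else k: float(v)
                for k, v in self.simulate.garbage_fractions.items()
            }
            sim["age_sex_structure"] = {
                f"{s}|{a}": float(v)
                for (s, a), v in self.simulate.age_sex_structure.items()
            }
            sim["true_cause_mix"] = {
                k: float(v) for k, v in self.simulate.true_cause_mix.items()
            }
        return yaml.safe_dump(d, sort_keys=False)


@dataclass
class PipelineResult:
    observed: pd.DataFrame
    quality: quality.QualityReport
    corrected_l4: RedistributedTable
    corrected_l5: RedistributedTable
    rates: pd.DataFrame
    trends: pd.DataFrame
    projections: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _conservation_check(observed: pd.DataFrame, corrected: RedistributedTable) -> float:
    before = observed.groupby(["country", "year"])["deaths"].sum()
    after = corrected.table.groupby(["country", "year"])["deaths"].sum()
    if len(corrected.unallocated):
        un = corrected.unallocated.groupby(["country", "year"])["deaths"].sum()
        after = after.add(un, fill_value=0.0)
    return float((before - after.reindex(before.index).fillna(0.0)).abs().max())


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Run every stage; optionally write all artifacts under ``config.out_dir``."""
    registry = (
        load_registry(config.registry_path) if config.registry_path else default_registry()
    )
    standard = mio.load_standard_population(config.standard_population_path)
    rule = config.window_rule()

    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            panel = synthetic.simulate_panel(sim, registry)
            observed, population = panel.observed, panel.population
        elif config.mortality_path and config.population_path:
            observed = mio.read_long_csv(config.mortality_path)
            population = mio.read_population_csv(config.population_path)
        else:
            raise StageError("input: need either simulate config or input paths")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"input: {exc}") from exc

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc

    report = stage("assess", quality.assess, observed, registry, config.year_range)
    l4 = stage("redistribute", redistribute_all, observed, registry, rule,
               include_level5=False, strata=config.strata)
    l5 = stage("redistribute", redistribute_all, observed, registry, rule,
               include_level5=True, strata=config.strata)
    rate_df = stage("rates", rates.user_specific_rates,
                    observed, l4, l5, population, standard, registry)

    t_unc = stage("trends", trends.trends_table, observed, registry, False)
    t_cor = stage("trends", trends.trends_table, l4.table, registry, True)
    trend_df = pd.concat([t_unc, t_cor], ignore_index=True)
    p_unc = stage("project", trends.projections_table, observed, registry, False)
    p_cor = stage("project", trends.projections_table, l4.table, registry, True)
    proj_df = pd.concat([p_unc, p_cor], ignore_index=True)

    summary = _summarize(report, rate_df, trend_df, proj_df, observed, l4, l5)
    result = PipelineResult(
        observed=observed, quality=report, corrected_l4=l4, corrected_l5=l5,
        rates=rate_df, trends=trend_df, projections=proj_df, summary=summary,
    )
    if write:
        _write(config, result, population)
    return result


def _summarize(report, rate_df, trend_df, proj_df, observed, l4, l5) -> dict:
    """Recomputable tallies: bin counts, >50% rate shifts, trend signs,
    on-track counts before/after correction, conservation residuals."""
    bins = (
        report.proportions.dropna(subset=["proportion"])
        .groupby(["category", "bin"], observed=True)["country"].nunique()
    )
    over50 = (
        rate_df.dropna(subset=["ratio"])
        .assign(over=lambda d: d["pct_change"] > 50.0)
        .groupby("scope")["over"].mean()
    )
    sign = lambda r: "positive" if r > 0 else ("zero" if r == 0 else "negative")
    trend_signs = {
        ("corrected" if c else "uncorrected"): (
            trend_df[trend_df["corrected"] == c]["r"].map(sign).value_counts().to_dict()
        )
        for c in (False, True)
    }
    on_track = {
        ("corrected" if c else "uncorrected"): int(
            proj_df[proj_df["corrected"] == c]["on_track"].sum()
        )
        for c in (False, True)
    }
    return {
        "countries": int(observed["country"].nunique()),
        "bin_country_counts": {f"{c}|{b}": int(n) for (c, b), n in bins.items()},
        "share_country_years_rate_change_gt50pct": {
            k: float(v) for k, v in over50.items()
        },
        "trend_sign_counts": trend_signs,
        "on_track_counts": on_track,
        "max_conservation_residual_l4": _conservation_check(observed, l4),
        "max_conservation_residual_l5": _conservation_check(observed, l5),
        "unallocated_deaths_l5": float(l5.unallocated["deaths"].sum())
        if len(l5.unallocated) else 0.0,
    }


def _write(config: PipelineConfig, result: PipelineResult, population: pd.DataFrame):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    mio.write_long_csv(result.observed, out / "observed.csv")
    population.to_csv(out / "population.csv", index=False)
    result.quality.availability.to_csv(out / "availability.csv")
    result.quality.proportions.to_csv(out / "quality.csv", index=False)
    for name, red in (("l4", result.corrected_l4), ("l5", result.corrected_l5)):
        mio.write_long_csv(red.table, out / f"corrected_{name}.csv")
        red.provenance.to_csv(out / f"provenance_{name}.csv", index=False)
        red.unallocated.to_csv(out / f"unallocated_{name}.csv", index=False)
    result.rates.to_csv(out / "rates.csv", index=False)
    result.trends.to_csv(out / "trends.csv", index=False)
    result.projections.to_csv(out / "projections.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2, sort_keys=True))
    log.info("pipeline artifacts written to %s", out)
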