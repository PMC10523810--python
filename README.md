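# roadmort

Quality assessment and correction of road traffic mortality statistics from
ICD-10-coded civil-registration data.

National cause-of-death panels (such as those countries report to the WHO
Mortality Database) contain many *nonspecific* ("garbage") ICD-10 codes —
deaths too vaguely certified to assign a specific cause. For road traffic
analysis five categories matter, one at each level of the cause hierarchy:

| level | category | ICD-10 codes | redistributes into |
|---|---|---|---|
| all causes | ill-defined / unknown cause | R95, R96, R98, R99 | all specific causes |
| injuries | undetermined intent | Y34, Y87.2, Y89.9 | specific injury causes |
| unintentional injuries | unspecified unintentional | X59 | specific unintentional causes |
| transport | unspecified transport crash | V99, Y85.9 | specific transport causes |
| road traffic | unspecified road traffic user | V87.0–V87.8, V89.2 | occupant + motorcyclist codes |

Left uncorrected, these codes systematically understate road traffic
mortality — the first four understate the overall and all user-specific
rates, the fifth specifically understates occupant and motorcyclist rates.
`roadmort` classifies every code, measures the share of each garbage
category per country-year, and redistributes garbage deaths to specific
causes by the **proportionate method**: within each (sex, age) stratum, a
category's garbage mass is allocated across its target codes in proportion
to the observed specific-cause counts, pooled over an adaptive temporal
window (1/3/5/7 years as the nonspecific share is <30%, 30–49%, 50–69%,
≥70%; all available years if a nominal window year is missing). Corrected
and uncorrected mortality is then compared as:

- **age-standardized rates** per 100 000, `ASR = 1e5 · Σ_a w_a D_a/P_a`,
  with the WHO world standard population weights `w_a` (18 five-year bands);
- **geometric-mean average annual change**
  `r = (D_last/D_first)^(1/(y_last−y_first)) − 1` of road traffic deaths;
- **projections** `D_Y = D_base (1+r)^(Y−base)` to 2021 and 2030, with the
  projected percent change `100((1+r)^9 − 1)` and an *on-track* flag for
  the UN target of halving road traffic deaths by 2030 (change ≤ −50%).

A synthetic-data module generates panels with known ground truth and
controllable garbage coding, so the whole chain is testable against exact
oracles: deterministic proportional injection is inverted *exactly* by the
redistribution cascade.

## Worked example

```python
from roadmort import SimulationConfig, default_registry, load_standard_population
from roadmort.synthetic import simulate_panel
from roadmort.redistribution import redistribute_all
from roadmort.rates import user_specific_rates
from roadmort.taxonomy import NonspecificCategory as NC

registry = default_registry()
standard = load_standard_population()

config = SimulationConfig(
    n_countries=2, years=(2015, 2020),
    garbage_fractions={NC.ILL_DEFINED: 0.05,
                       NC.UNSPEC_UNINTENTIONAL: 0.20,
                       NC.UNSPEC_RT: 0.35},
    annual_change=-0.06, seed=42,
)
panel = simulate_panel(config)
l4 = redistribute_all(panel.observed, registry, include_level5=False)
l5 = redistribute_all(panel.observed, registry, include_level5=True)
out = user_specific_rates(panel.observed, l4, l5,
                          panel.population, standard, registry)
print(out[out.year == 2015].round(3).to_string(index=False))
```

```
country  year         scope  uncorrected_rate  corrected_rate  ratio  pct_change
    C01  2015  motorcyclist            10.368          20.705  1.997      99.705
    C01  2015      occupant            14.363          28.975  2.017     101.730
    C01  2015    overall_rt            58.407          71.541  1.225      22.488
    C01  2015 pedal_cyclist             3.677           4.970  1.352      35.164
    C01  2015    pedestrian            10.135          13.288  1.311      31.112
    C02  2015  motorcyclist            11.969          22.650  1.892      89.241
    C02  2015      occupant            13.169          25.866  1.964      96.408
    C02  2015    overall_rt            58.048          70.264  1.210      21.044
    C02  2015 pedal_cyclist             2.960           3.809  1.287      28.667
    C02  2015    pedestrian            10.829          13.888  1.283      28.258
```

Rates are deaths per 100 000 standard population. With 35% of road-traffic
deaths hidden behind user-unspecified codes, occupant and motorcyclist
rates roughly double after correction (ratio ≈ 2), while the overall rate
rises ~22% — mostly recovered from ill-defined and X59 deaths. Trends and
projections work the same way on the corrected table:

```python
from roadmort.trends import projections_table
print(projections_table(l4.table, registry, corrected=True).round(2))
```

```
country  deaths_2021  deaths_2030  pct_change_2021_2030  on_track  corrected     r
    C01       513.64       323.56                -37.01     False       True -0.05
    C02       516.91       339.28                -34.36     False       True -0.05
```

Both countries decline ~5%/year, projecting a 34–37% drop in road traffic
deaths from 2021 to 2030 — short of the 50% target, so neither is on track.

A CLI mirrors the library: `roadmort simulate|assess|redistribute|rates|
trends|project|run` (see `roadmort --help`).

## Layout

- `roadmort.taxonomy` — ICD-10 code sets (YAML registry), classification
- `roadmort.io` — WHO Mortality Database dialect + tidy long CSV, population
  tables, standard populations, age-band handling
- `roadmort.synthetic` — ground-truth panel generator and garbage injection
- `roadmort.quality` — availability and coding-quality indicators
- `roadmort.redistribution` — the proportionate cascade with adaptive windows
- `roadmort.rates` — age standardization, corrected/uncorrected comparison
- `roadmort.trends` — geometric-mean trends, projections, on-track status
- `roadmort.pipeline` / `roadmort.cli` — end-to-end orchestration

See `docs/methods.md` for the statistical details and design choices.
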