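# Methods

## The problem

Civil-registration cause-of-death panels code each death with an ICD-10
cause. A substantial share of certificates carry *nonspecific* codes that
cannot support cause-specific analysis. For road traffic mortality, five
garbage categories matter, nested along the cause hierarchy
(all causes ⊃ injuries ⊃ unintentional injuries ⊃ transport ⊃ road
traffic): ill-defined causes (R95/R96/R98/R99), injuries of undetermined
intent (Y34/Y87.2/Y89.9), unspecified unintentional injuries (X59),
unspecified transport crashes (V99/Y85.9), and road traffic crashes of
unspecified user type (V87.0–V87.8/V89.2). Road traffic deaths are V01–V89
at the 3-character level; the fifth category is *inside* road traffic
(deaths known to be road traffic, user unknown), the first four are outside
it and understate it when left in place.

## Code registry

Code sets live in `roadmort/data/code_registry.yaml` and are loaded into an
immutable `CodeSetRegistry`. For each category the registry defines the
garbage set, the denominator (the category's hierarchy level, used for
quality proportions and window selection), and the target ranges
(redistribution destinations; any code in any garbage set is excluded from
every target at evaluation time). Structural invariants — pairwise-disjoint
garbage sets, each garbage code inside its own denominator — are checked at
load. Keeping the sets in a versioned file lets users align them with
GBD/WHO variants without code changes.

Classification details that needed a decision:

- A 4-character child of a 3-character garbage code (e.g. X59.9) is
  garbage. A bare 3-character code whose children .0–.8 are all garbage
  (V87) is garbage even though the .9 residual is treated as specific;
  a stem with a single garbage child (Y87) is specific.
- V87.9, V89.0, V89.1, V89.3 and V89.9 are specific "other road vehicle"
  codes: the garbage list is read literally.
- Fourth-character traffic/non-traffic distinctions are ignored: all
  V01–V89 deaths count as road traffic. The registry ranges are editable if
  a user wants the stricter reading.
- The transport denominator is V01–V99 plus the Y85 block (sequelae of
  transport accidents), so Y85.9 lies inside its own level.
- Road-user groups: pedestrian V01–V09, pedal cyclist V10–V19, motorcyclist
  V20–V29, occupant V30–V79, other road user V80–V89 residuals; V90–V98
  (water/air/other transport) and V99 are transport but not road traffic.

## Quality indicators

*Availability* counts, per country, the years of a declared range
(default 2015–2020) with at least one death row. *Coding quality* is, per
country-year and category, `100 · garbage / denominator`, where the
denominator includes the level's own garbage codes (configurable; the
alternative excludes them). A zero denominator yields a missing value,
never 0%. Percentages are binned into [0,20], (20,40], (40,60], (60,80],
(80,100] — the boundary belongs to the lower bin, consistent with
"0–20%" / "21–40%" style labels on integer-valued percentages.

## Proportionate redistribution with adaptive windows

The proportionate method assumes garbage deaths follow the same cause
distribution as specifically coded deaths in the target set. For each
country-year with garbage mass in a category:

1. The category's nonspecific share p (garbage / denominator, as above)
   selects a temporal window: p < 0.30 → the study year; 0.30–0.49 → three
   years (±1); 0.50–0.69 → five years (±2); ≥ 0.70 → seven years (±3).
   Threshold values belong to the wider window. If *any* nominal window
   year is absent from the country's data, all available years are pooled
   instead — the fallback is deliberately all-or-nothing rather than
   partial-window, reading the rule strictly.
2. Specific deaths in the category's target set are pooled over the window
   per (sex, age band) stratum.
3. Each stratum's garbage mass is split across target causes proportionally
   to the pooled counts (weights only — the allocation is scale-free).
   When a stratum has no pooled targets, a fallback ladder applies: pool
   the sexes within the age band, then pool everything in the country-year
   window, and finally record the mass as *unallocated* with a warning.
   An alternative `strata="none"` mode allocates country-year totals over
   the joint (sex, age, cause) pool.

Categories cascade outermost level first — ill-defined → undetermined
intent → unspecified unintentional → unspecified transport → unspecified
road traffic — and each step's output feeds the next step's proportions and
pools: level-k garbage must be placed before it can serve in level-k+1
denominators. Ill-defined deaths redistribute to *all* specific causes (not
only injuries). The fifth category's target is restricted to occupant and
motorcyclist codes (V20–V79), because user-unspecified road traffic deaths
predominantly hide those two groups; it is applied only in the
five-category cascade. Processed garbage rows are removed; their mass lives
on in specific causes plus the ledger.

The `RedistributedTable` carries a conservation ledger: *provenance* (added
mass per output cell per category) and *unallocated* satisfy, per category,
provenance + unallocated = original garbage mass, and all-cause totals per
country-year are conserved to float precision.

## Rates, trends, projections

Age-standardized rates use `ASR = 1e5 · Σ_a w_a D_a / P_a` over the 18
five-year bands 0–4 … 85+, with the bundled WHO world standard weights
(normalized to sum to 1; any 18-band standard can be supplied). Rates are
per 100 000 and both-sex combined; all downstream comparisons use
corrected/uncorrected ratios and are scale-free. Unknown-age deaths are
reallocated proportionally to the known-age distribution of the same
(country, year, sex, cause) — falling back to the all-cause distribution —
before any rate computation; unknown-sex deaths count in combined totals.
Deaths in a band with no population raise an error naming the band.

Five scopes are reported: overall road traffic (V01–V89 including the
user-unspecified garbage codes, in both the corrected and uncorrected
tables — those deaths are road traffic regardless of coding quality) and
the four user groups (specific codes only). Corrected overall, pedestrian
and pedal-cyclist rates come from the four-category cascade; occupant and
motorcyclist rates from the five-category cascade.

The average annual change of road traffic deaths is the geometric-mean
rate over observed endpoints, `r = (D_last/D_first)^(1/(y_last−y_first)) − 1`,
defined for ≥ 2 observed years with positive first-year deaths; a final
year at zero gives r = −1, and gaps are annualized through the exponent, so
intermediate zeros or spikes do not poison the estimate. Projections chain
from the last observed year, `D_Y = D_base (1+r)^(Y−base)`, so countries
whose data end before 2020 still project to 2021 and 2030. The projected
percent change 2021→2030 is `100((1+r)^9 − 1)` — strictly increasing in r,
−100 at r = −1, 0 at r = 0 — and a country is *on track* for the UN goal of
halving road traffic deaths when it is ≤ −50 (a 1e-9 guard absorbs float
round-off exactly at the halving boundary). Correction-induced shifts are
classified as sign flips (zero counts as its own sign), >10 percentage-point
moves of the annual rate, or minor.

## Synthetic panels and what they do (not) show

The generator draws truth tables from a configurable specific-cause mix ×
(sex, age) death structure, with a per-country multiplicative drift on road
traffic causes providing a known geometric trend, then *injects* garbage by
relabelling specific deaths into canonical garbage codes (R99, Y34, X59,
V99, V89.2), category by category. Injection conserves deaths per
(country, year, sex, age band) — it relabels, never creates.

Injection applies categories **innermost level first** (road-traffic-
unspecified first, ill-defined last), each stealing a fraction f of the
then-current specific mass in its denominator ∩ target set. The
redistribution cascade runs outermost-first and therefore unwinds the
injections in LIFO order: at each step the surviving target cells are a
uniform (1−f) rescaling of the state the step must restore, so
deterministic fractional injection with same-year windows is inverted
*exactly* (to float precision). This is the package's central oracle; the
top-down/top-down pairing would not be exact, because the outermost step
would see targets non-uniformly shrunk by deeper levels.

Two sampling modes per axis: deterministic (expected fractional counts) for
exact oracles; multinomial truth with binomial relabelling for realistic
integer counts. A *biased* injection mode concentrates relabelling on
chosen causes (propensity ∝ weight × mass, water-filled against cell
capacity), deliberately violating the proportionate assumption: stealing
preferentially from non-road-traffic causes makes the correction
*overestimate* road traffic mortality, and vice versa — the method's known
failure mode, demonstrated in the tests rather than hidden.

Defaults (chosen once as plausible study conditions): 20 countries,
2015–2020, 10 000 deaths/country-year, a 41-code cause mix with 88%
non-injury and 7% road traffic deaths, death structure skewed old and
population structure skewed young (so age-specific rates vary by age),
1 000 000 persons/country, no trend. The road traffic share is higher than
typical real-world shares so that injury-level analyses have adequate
counts at the default panel size. What the generator does *not* emulate:
demographic change over time, migration, cohort effects, reporting gaps
within a year, under-registration, or cause misclassification other than
nonspecific coding — so passing tests certify the correction machinery, not
robustness to those additional real-data problems.

## Numerical and interface choices

- Tables are plain pandas DataFrames in a canonical long layout
  (country, year, sex, age band, cause, deaths), validated and sorted by a
  single schema gate; fractional deaths are allowed everywhere (required
  after redistribution).
- The WHO Mortality Database reader supports the fine per-row age formats
  (Frmat 0/1/2, aggregated up to the 18 canonical bands) and a coarse
  lumped format (Frmat 3), split across bands proportionally to a supplied
  population age structure or by span width, with a logged warning;
  unknown formats raise naming the row. `Deaths1` is used only as a
  checksum (warning beyond ±0.5), `Deaths26` maps to the UNKNOWN age band,
  and subnational rows are dropped.
- Conservation checks use absolute tolerance 1e-9 on death counts;
  standard-population weights must sum to 1 within 1e-6.
- Problem sizes in the test suite (panels of 2–20 countries, up to
  100 000 deaths/country-year, 50 stochastic replicates for ledger checks,
  20 per bias direction) were chosen so the full suite completes in a few
  minutes on one CPU while leaving the stochastic assertions comfortable
  margins.

## Known limitations

- The proportionate method's assumption is untestable on real data from
  within; the bias tests quantify only the synthetic failure mode.
- Redistribution of ill-defined deaths to *all* causes means road traffic
  gains mass from every R99 death; methods restricting level-1
  redistribution to injury-adjacent causes would correct less. The registry
  makes the target ranges editable.
- No uncertainty intervals are produced for rates, trends or projections.
- ICD-9/ICD-8 years, WHO tabulation-list (condensed) cause codes and
  infant-age formats are out of scope.
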