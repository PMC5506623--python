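# Methods

## Model structure and assumptions

The engine is an annual, deterministic cohort model. For one country-year
and one condition, the population at risk (pregnancies for postpartum
hemorrhage and obstructed labor, neonates for sepsis, under-5 children for
diarrhea and pneumonia) is multiplied by incidence to give expected cases;
for diarrhea, incidence is episodes per child-year and regularly exceeds 1,
so "cases" are episodes. Cases split across home, clinic, and hospital by a
fixed setting mix describing where cases present or deliveries occur. In
each setting, a case is *effectively treated* with probability
`coverage × effectiveness` — coverage and effectiveness are treated as
independent multiplicative fractions, which is the simplest contract
consistent with a coverage-then-efficacy cascade; "successful receipt" as a
single measured quantity would be an alternative reading and can be encoded
by setting effectiveness to 1 and folding it into coverage. Effectively
treated and not-effectively-treated cases face separate case-fatality
rates (CFRs), with `cfr_treated ≤ cfr_untreated` enforced at validation.

Assumptions carried throughout:

- **No secular trends.** Baseline coverage, effectiveness, incidence, the
  setting mix, and demographic denominators are held constant over the
  horizon unless the input table varies them by year.
- **Expectations, not counts.** Deaths are real-valued; rounding happens
  only in report formatting.
- **One innovation per run.** Scenarios take exactly one innovation;
  results for different innovations against the same condition share a
  baseline and must not be added.
- **No discounting by default.** Costs and deaths are undiscounted nominal
  sums; `EngineConfig.discount_rate` exists as a hook and defaults to 0.
- **No morbidity, stillbirth, or DALY outputs.**

## Innovation mechanisms

Adoption follows a linear ramp: zero before the launch year, then
`peak × min(1, (year − launch + 1)/ramp_years)`. The first launch year
carries `1/ramp_years` of the peak — there is no zero-coverage launch
year — so a 2022 launch with a 5-year ramp reaches its peak in 2026. The
convention matters only for the handful of launch-era years and was chosen
so that "launch" means the product is actually in use.

The six mechanism classes act on one cascade quantity each:

| mechanism | transform |
|---|---|
| incidence_reduction | `λ ← λ·(1 − eligible·cov·eff)` before the setting split |
| mortality_reduction | both CFRs `← CFR·(1 − cov·reduction)` in gated settings |
| coverage_expansion | first-line coverage `← min(1, base + cov)` (expand) or `max(base, cov)` (replace); the innovation-served share uses the innovation's effectiveness |
| second_line_treatment | rescued `= pool · cov · eff` move from untreated to treated CFR; the default pool is first-line failures (covered but ineffective); `second_line_pool="include_untreated"` widens it to never-treated cases |
| adherence_boost | first-line coverage `← min(1, base + boost_points · ramp_fraction)`; the product has no mortality effect of its own |
| diagnostic_improvement | among device adopters, the probability a true case enters treatment rises by `max(0, detection − base_coverage)`; false positives `= noncases · cov · (1 − specificity) · downstream_coverage` incur treatment costs but no mortality change |

Mechanism selection is entirely data-driven from the innovation spec; no
mechanism is hard-coded to an innovation name. Any transform that would
push a fraction outside [0, 1] clips and emits a `ClippingWarning` rather
than raising.

Per-setting gating comes from which settings have non-null peak coverage.
An optional `eligible_population_filter` names a country-level eligibility
share (`eligible_fraction`, e.g. the community-water-source population for
the chlorinator); eligibility is country data, not an innovation property,
which is why the fraction lives on the country row and only the filter name
lives on the spec. For the cord-care preset the home-birth gate is already
expressed by the home setting; its 23% effect is applied to
neonatal-sepsis CFRs among covered home cases rather than to all-cause
neonatal mortality, because the model is condition-specific.

Diagnostic specificity is not part of the published parameter sets; the
package default is 0.95 per preset file (configurable), and the
non-case presenting pool defaults to 3 symptomatic non-cases per true case
(`EngineConfig.noncase_presentation_ratio`), a pneumonia-like outpatient
attendance ratio. Whether the diagnostics' published effectiveness (85%/80%)
is sensitivity alone or folds in referral is unstated; it is treated here
as detection sensitivity with a separate `downstream_treatment_coverage`
knob (default 1).

## Costing

Cumulative incremental cost = innovation cost + introduction cost +
additional downstream treatment (true and false positives) − averted
treatment. Units are purchased by ceiling division of annual uses (doses,
device applications, screens, or people served) by
`units_per_person_covered`; durable devices (chlorinator, oximeter,
respiratory-rate monitor) amortize their unit cost over
`device_lifetime_years` (default 5 for those presets, 1 for consumables) —
replacement policy is otherwise unspecified, so straight-line amortization
was chosen. The single published "cost" figure per innovation is
interpreted per preset (per dose, per device-use, per durable device); the
interpretation is recorded in each preset's `notes`. Introduction cost is a
one-time per-country charge in the launch year. Research-and-development
and economic-productivity costs are out of scope. Negative totals are
reported as cost savings, and negative lives saved are reported with a
warning, never suppressed.

## Sensitivity analysis

`one_at_a_time_sensitivity` is strictly one-at-a-time: each perturbation is
a full model re-run with every other input central. Coverage and
effectiveness move by ±δ (default 0.05, i.e. 5 percentage points) applied
to every operating setting and clipped to [0, 1] with a warning; for the
adherence-boost mechanism the effectiveness axis is the boost itself. Unit
cost takes user-supplied `[lower, upper]` bounds — no default cost range is
assumed — and by construction never changes death counts, since price does
not influence coverage in this model. No joint probabilistic uncertainty
propagation is attempted.

## Synthetic data and the microsimulation oracle

The generator draws, per country: live births log-uniform in [1e5, 2e6]
(neonates equal to births, pregnancies 1.05×, under-5 population 4.8×);
per condition: incidence uniform in per-condition ranges (diarrhea 2.4–3.3
episodes per child-year, matching the range reported for South-East Asia
and sub-Saharan Africa; the other ranges are plausibility choices),
a Dirichlet(4, 3, 2) setting mix, per-setting baseline coverage
(home 0.10–0.40, clinic 0.30–0.70, hospital 0.50–0.90) and effectiveness
(0.50–0.90), untreated CFRs in per-condition ranges with the treated CFR a
uniform 0.10–0.50 multiple, and per-episode treatment costs in
per-condition USD ranges. All draws come from one `numpy` Generator seeded
explicitly; identical seed and config give an identical table, and every
generated row passes validation. Values are constant across years within a
country, matching the engine's no-trend assumption.

What the generator does **not** emulate: real country demographics or
magnitudes, secular trends, correlation between coverage and wealth,
between-year shocks, or age structure within the under-5 population.
Passing tests on synthetic rosters therefore demonstrate internal
correctness of the cascade arithmetic and mechanism semantics — not that
any headline number transfers to real countries, which would require
country-level demographic, survey, and incidence inputs outside this
package's scope.

The microsimulation oracle brute-forces the same cascade per individual
case: setting, first-line coverage, treatment success, mechanism events,
and death are independent Bernoulli draws from one seeded stream
(simulating cases rather than the whole population, and episodes for
diarrhea). Its mean scaled by expected cases estimates deaths with a
binomial standard error (floored at 0.5/n to keep a finite band when no
simulated death occurs). Equivalence tests require the deterministic
engine to sit within 4 standard errors at n = 200,000 — the oracle and the
engine share only the input definitions (ramp schedule, parameter
meanings), not the cascade code path.

## Numerical choices

- Setting-mix closure is validated to 1e-9; worked-example tests assert to
  1e-9; bitwise determinism is asserted for identical inputs (pure float
  arithmetic, no global state).
- The baseline and scenario code paths share their arithmetic ordering so
  that a null innovation (zero peak coverage or post-horizon launch)
  reproduces the baseline bit for bit.
- Year-gap detection rejects country tables with missing years inside a
  country's span, naming the gaps.
- Problem sizes in tests and the acceptance script (rosters of 1–5
  synthetic countries, 200,000-individual oracle runs) keep the full suite
  in the seconds-to-minutes range; the model is linear in roster size, so
  larger rosters change runtime, not behavior.

## Known limitations

- The 49-country roster of the original analysis is not enumerated
  publicly; the package ships a demonstration roster and accepts any
  roster file, plus a named adjustment for the cord-care country list
  (adds Angola, Botswana, Equatorial Guinea, Gabon, Afghanistan, Djibouti;
  drops Bhutan, Indonesia, North Korea, Sri Lanka).
- Coverage expansion counts innovation uses among condition cases only;
  prophylactic use across all deliveries (relevant for uterotonic cost
  accounting) would need a uses-per-delivery extension.
- Market dynamics are limited to expand/replace; there is no price
  elasticity of coverage and no competition model.
- False positives from diagnostics incur costs but no harm; iatrogenic
  effects are not modeled.
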