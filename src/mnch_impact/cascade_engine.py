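"""Deterministic care-cascade engine.

For each country-year the model walks a fixed cascade: the population at
risk times incidence gives annual cases; cases split across home, clinic,
and hospital settings by the setting mix; within each setting a case is
effectively treated with probability coverage x effectiveness; treated and
untreated cases then face their respective case-fatality rates. Summing
deaths over settings gives the country-year death count under the current
standard of care.

A scenario run repeats the computation with exactly one innovation inserted
at the point of the cascade its mechanism targets, using the year-specific
adoption level from the linear ramp. The difference between the two death
trajectories, summed over countries and years, is the innovation's
incremental lives saved.

Deaths are real-valued expectations throughout; rounding happens only at
report time.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import innovation_mechanisms as mech
from .model_inputs import (
    HORIZON,
    MECHANISMS,
    SETTINGS,
    ConfigurationError,
    CountryYearInputs,
    InnovationSpec,
)


@dataclass(frozen=True)
class EngineConfig:
    """Knobs of the deterministic engine.

    noncase_presentation_ratio
        Symptomatic non-cases presenting for every true case; feeds the
        false-positive pathway of diagnostic innovations (default 3, a
        pneumonia-like symptomatic attendance ratio).
    second_line_pool
        Who is eligible for a second-line rescue: ``"failures_only"``
        (first-line treated but ineffective, the default) or
        ``"include_untreated"`` (also cases never reached by first-line
        care).
    downstream_treatment_coverage
        Fraction of newly diagnosed patients who actually receive
        treatment.
    discount_rate
        Annual discount rate applied to future costs and deaths; the model
        reports undiscounted sums by default.
    """

    horizon: tuple[int, int] = HORIZON
    noncase_presentation_ratio: float = 3.0
    second_line_pool: str = "failures_only"
    downstream_treatment_coverage: float = 1.0
    discount_rate: float = 0.0


@dataclass
class CascadeResult:
    """Cascade quantities for one country-year, by setting and in total.

    ``treated`` counts cases receiving first-line treatment (whether or not
    it works) and drives downstream treatment costs; ``treated_effectively``
    counts cases whose treatment works and determines which case-fatality
    rate applies. ``innovation_uses`` is the raw count of innovation
    applications (doses, device uses, screens, people served) before unit
    packaging; ``innovation_units_used`` applies the spec's ceiling rule.
    """

    country_code: str
    year: int
    condition_id: str
    cases: dict[str, float]
    treated: dict[str, float]
    treated_effectively: dict[str, float]
    untreated: dict[str, float]
    deaths: dict[str, float]
    innovation_uses: float = 0.0
    innovation_units_used: float = 0.0
    false_positive_treatments: dict[str, float] = field(
        default_factory=lambda: {s: 0.0 for s in SETTINGS})

    @property
    def total_cases(self) -> float:
        return sum(self.cases.values())

    @property
    def total_deaths(self) -> float:
        return sum(self.deaths.values())

    @property
    def total_false_positive_treatments(self) -> float:
        return sum(self.false_positive_treatments.values())


@dataclass
class ForecastResult:
    """Baseline-vs-scenario trajectories for one innovation over a roster."""

    innovation_id: str
    condition_id: str
    years: list[int]
    baseline_deaths_by_year: dict[int, float]
    scenario_deaths_by_year: dict[int, float]
    lives_saved_by_year: dict[int, float]
    cumulative_lives_saved: float
    incremental_cost_by_year: Optional[dict[int, float]] = None
    cumulative_incremental_cost: Optional[float] = None
    cost_breakdown: Optional[dict[str, float]] = None
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def cases_for_year(inputs: CountryYearInputs) -> float:
    """Expected condition cases in one country-year: population at risk
    times incidence. Real-valued; the population at risk is condition
    specific (pregnancies, neonates, or under-5 children)."""
    return inputs.target_population() * inputs.incidence


def expected_deaths(cases: float, treated_frac: float, cfr_treated: float,
                    cfr_untreated: float) -> float:
    """Expected deaths among ``cases`` of which ``treated_frac`` are
    effectively treated:
    ``cases * (treated_frac * cfr_treated + (1 - treated_frac) * cfr_untreated)``.
    """
    return cases * (treated_frac * cfr_treated
                    + (1.0 - treated_frac) * cfr_untreated)


def _check_contiguous_years(records: Sequence[CountryYearInputs]) -> None:
    by_country: dict[str, set[int]] = {}
    for rec in records:
        by_country.setdefault(rec.country_code, set()).add(rec.year)
    gaps = []
    for country, years in sorted(by_country.items()):
        expected = set(range(min(years), max(years) + 1))
        missing = sorted(expected - years)
        if missing:
            gaps.append(f"{country}: missing years {missing}")
    if gaps:
        raise ValueError("country table has year gaps — " + "; ".join(gaps))


def _baseline_row(rec: CountryYearInputs) -> CascadeResult:
    total_cases = rec.target_population() * rec.incidence
    cases, treated, treated_eff, untreated, deaths = {}, {}, {}, {}, {}
    # mirrors the arithmetic of _scenario_row exactly so that a null
    # innovation reproduces the baseline bitwise
    for s in SETTINGS:
        c = total_cases * rec.setting_mix[s]
        cov, eff = rec.baseline_coverage[s], rec.baseline_effectiveness[s]
        treated_frac = cov * eff
        cases[s] = c
        treated[s] = c * cov
        treated_eff[s] = c * treated_frac
        untreated[s] = c - treated_eff[s]
        deaths[s] = (treated_eff[s] * rec.cfr_treated[s]
                     + untreated[s] * rec.cfr_untreated[s])
    return CascadeResult(rec.country_code, rec.year, rec.condition_id,
                         cases, treated, treated_eff, untreated, deaths)


def run_baseline(records: Sequence[CountryYearInputs], condition: str,
                 config: EngineConfig | None = None) -> list[CascadeResult]:
    """Deaths under the current standard of care, one result per
    country-year of ``condition``."""
    del config  # baseline needs no engine knobs; kept for symmetry
    subset = [r for r in records if r.condition_id == condition]
    if not subset:
        raise ConfigurationError(f"no records for condition {condition!r}")
    _check_contiguous_years(subset)
    return [_baseline_row(r) for r in subset]


def _scenario_row(rec: CountryYearInputs, spec: InnovationSpec,
                  config: EngineConfig) -> CascadeResult:
    eligible = rec.eligible_fraction if spec.eligible_population_filter else 1.0
    operating = spec.settings()

    incidence = rec.incidence
    uses = 0.0
    if spec.mechanism == "incidence_reduction":
        s0 = operating[0]
        cov_y = mech.coverage_at_year(spec, rec.year, s0)
        incidence = mech.apply_incidence_reduction(
            incidence, cov_y, spec.effectiveness[s0], eligible)
        uses += rec.target_population() * eligible * cov_y

    total_cases = rec.target_population() * incidence
    cases, treated, treated_eff, untreated, deaths = {}, {}, {}, {}, {}
    false_pos = {s: 0.0 for s in SETTINGS}

    for s in SETTINGS:
        c = total_cases * rec.setting_mix[s]
        cov0, eff0 = rec.baseline_coverage[s], rec.baseline_effectiveness[s]
        cfr_t, cfr_u = rec.cfr_treated[s], rec.cfr_untreated[s]
        treated_frac = cov0 * eff0
        covered = cov0
        extra_eff = 0.0  # effectively treated beyond the treated_frac share

        in_scope = s in operating
        cov_y = mech.coverage_at_year(spec, rec.year, s) * eligible if in_scope else 0.0

        if spec.mechanism == "mortality_reduction" and in_scope:
            reduction = spec.effectiveness[s]
            cfr_t = mech.apply_mortality_reduction(cfr_t, cov_y, reduction)
            cfr_u = mech.apply_mortality_reduction(cfr_u, cov_y, reduction)
            uses += rec.target_population() * rec.setting_mix[s] * cov_y

        elif spec.mechanism == "coverage_expansion" and in_scope:
            new_cov = mech.apply_coverage_expansion(cov0, cov_y,
                                                    spec.market_behavior)
            if spec.market_behavior == "expand":
                innov_share = new_cov - cov0
                base_share = cov0
            else:  # replace: innovation serves its adopters, comparator the rest
                innov_share = min(cov_y, new_cov)
                base_share = new_cov - innov_share
            treated_frac = (base_share * eff0
                            + innov_share * spec.effectiveness[s])
            covered = new_cov
            uses += innov_share * c

        elif spec.mechanism == "second_line_treatment" and in_scope:
            pool = c * cov0 * (1.0 - eff0)
            if config.second_line_pool == "include_untreated":
                pool += c * (1.0 - cov0)
            rescued = mech.apply_second_line(pool, cov_y, spec.effectiveness[s])
            extra_eff = rescued
            uses += pool * cov_y

        elif spec.mechanism == "adherence_boost" and in_scope:
            ramp = mech.ramp_fraction_at_year(spec, rec.year)
            new_cov = mech.apply_adherence_boost(
                cov0, spec.coverage_boost_points * eligible, ramp)
            treated_frac = new_cov * eff0
            covered = new_cov
            uses += cov_y * c  # product given alongside first-line treatment

        elif spec.mechanism == "diagnostic_improvement" and in_scope:
            detection = spec.effectiveness[s]
            down = config.downstream_treatment_coverage
            # baseline pathway already identifies cov0 of cases; the device
            # adds the detection margin above that among its adopters
            add_frac = cov_y * max(0.0, detection - cov0) * down
            treated_frac = (cov0 + add_frac) * eff0
            covered = cov0 + add_frac
            noncases = c * config.noncase_presentation_ratio
            _, fp = mech.apply_diagnostic(c, noncases, cov_y, detection,
                                          spec.specificity, down)
            false_pos[s] = fp
            uses += (c + noncases) * cov_y

        cases[s] = c
        treated[s] = c * covered
        treated_eff[s] = c * treated_frac + extra_eff
        untreated[s] = c - treated_eff[s]
        deaths[s] = (treated_eff[s] * cfr_t + untreated[s] * cfr_u)

    units = math.ceil(uses / spec.units_per_person_covered) if uses > 0 else 0
    return CascadeResult(rec.country_code, rec.year, rec.condition_id,
                         cases, treated, treated_eff, untreated, deaths,
                         innovation_uses=uses, innovation_units_used=units,
                         false_positive_treatments=false_pos)


def run_scenario(records: Sequence[CountryYearInputs], condition: str,
                 innovation: InnovationSpec,
                 config: EngineConfig | None = None) -> list[CascadeResult]:
    """Deaths with ``innovation`` inserted into the cascade.

    Identical to :func:`run_baseline` except that the innovation's
    mechanism transform is applied in its operating settings, at the
    adoption level the linear ramp reaches in each year.
    """
    config = config or EngineConfig()
    if innovation.condition_id != condition:
        raise ConfigurationError(
            f"innovation {innovation.innovation_id!r} targets condition "
            f"{innovation.condition_id!r}, not {condition!r}")
    if innovation.mechanism not in MECHANISMS:
        raise ConfigurationError(f"unknown mechanism {innovation.mechanism!r}")
    subset = [r for r in records if r.condition_id == condition]
    if not subset:
        raise ConfigurationError(f"no records for condition {condition!r}")
    _check_contiguous_years(subset)
    return [_scenario_row(r, innovation, config) for r in subset]


def incremental_lives_saved(baseline: Sequence[CascadeResult],
                            scenario: Sequence[CascadeResult],
                            innovation_id: str = "",
                            ) -> ForecastResult:
    """Per-year and cumulative lives saved: baseline deaths minus scenario
    deaths, aggregated over the roster. Negative values (a harmful
    configuration) are reported and flagged with a warning, never hidden."""
    base_keys = [(r.country_code, r.year) for r in baseline]
    scen_keys = [(r.country_code, r.year) for r in scenario]
    if sorted(base_keys) != sorted(scen_keys):
        raise ValueError("baseline and scenario cover different country-years")
    condition = baseline[0].condition_id if baseline else ""

    base_by_year: dict[int, float] = {}
    scen_by_year: dict[int, float] = {}
    for r in baseline:
        base_by_year[r.year] = base_by_year.get(r.year, 0.0) + r.total_deaths
    for r in scenario:
        scen_by_year[r.year] = scen_by_year.get(r.year, 0.0) + r.total_deaths

    years = sorted(base_by_year)
    saved = {y: base_by_year[y] - scen_by_year[y] for y in years}
    notes = []
    if any(v < 0 for v in saved.values()):
        msg = f"negative lives saved in some years for {innovation_id or condition}"
        warnings.warn(msg, UserWarning, stacklevel=2)
        notes.append(msg)
    return ForecastResult(
        innovation_id=innovation_id,
        condition_id=condition,
        years=years,
        baseline_deaths_by_year=base_by_year,
        scenario_deaths_by_year=scen_by_year,
        lives_saved_by_year=saved,
        cumulative_lives_saved=sum(saved[y] for y in years),
        warnings=notes,
    )


def results_to_frame(results: Sequence[CascadeResult]) -> pd.DataFrame:
    """Tidy serialization: one row per country-year-setting."""
    rows = []
    for r in results:
        for s in SETTINGS:
            rows.append({
                "country_code": r.country_code,
                "year": r.year,
                "condition_id": r.condition_id,
                "setting": s,
                "cases": r.cases[s],
                "treated": r.treated[s],
                "treated_effectively": r.treated_effectively[s],
                "untreated": r.untreated[s],
                "deaths": r.deaths[s],
                "false_positive_treatments": r.false_positive_treatments[s],
            })
    return pd.DataFrame(rows)
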