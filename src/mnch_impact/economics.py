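"""Incremental costing, forecast orchestration, and sensitivity analysis.

The incremental cost of a scenario decomposes into four terms, all summed
over countries and years:

* **innovation cost** — units purchased (ceiling division of uses by the
  persons-served-per-unit factor) times unit cost, amortized over the
  device lifetime for durables;
* **introduction cost** — a one-time per-country charge in the launch year;
* **downstream treatment cost** — standard-of-care treatment given to cases
  the innovation newly routes into care, plus treatment given to
  false-positive diagnoses;
* **averted treatment cost** — treatment no longer needed for cases the
  innovation prevents; entered with a negative sign, so a prevention
  innovation for a high-treatment-cost condition can make the total
  negative (a net cost saving).

Research-and-development costs and economic-productivity effects are out of
scope. Sums are undiscounted nominal USD by default; a discount-rate hook
exists but is off.

One-at-a-time sensitivity re-runs the full model once per perturbation
(coverage or effectiveness shifted by +/- delta percentage points, unit
cost set to user-supplied bounds) with every other input at its central
value.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from . import cascade_engine as engine
from .cascade_engine import CascadeResult, EngineConfig, ForecastResult
from .model_inputs import (
    SETTINGS,
    ConfigurationError,
    CountryYearInputs,
    InnovationSpec,
    validate_inputs,
)


class ValidationFailed(ValueError):
    """Raised when a country table fails input validation."""

    def __init__(self, report):
        self.report = report
        lines = [f"  {loc}: [{rule}] {msg}" for loc, rule, msg in report.errors]
        super().__init__("input validation failed:\n" + "\n".join(lines))


@dataclass
class CostInputs:
    """Everything the costing step needs, detached from the engine.

    ``treatment_cost`` maps (country, year, setting) to the per-case cost of
    standard-of-care treatment. ``false_positive_unit_cost`` overrides the
    cost charged per false-positive treatment; by default the setting's
    treatment cost is used.
    """

    unit_cost: float
    introduction_cost: float
    units_per_person_covered: float
    device_lifetime_years: float
    launch_year: int
    treatment_cost: dict[tuple[str, int, str], float]
    false_positive_unit_cost: Optional[float] = None

    @classmethod
    def from_inputs(cls, records: Sequence[CountryYearInputs],
                    spec: InnovationSpec) -> "CostInputs":
        table = {
            (r.country_code, r.year, s): r.treatment_cost_per_case[s]
            for r in records if r.condition_id == spec.condition_id
            for s in SETTINGS
        }
        return cls(
            unit_cost=spec.unit_cost,
            introduction_cost=spec.introduction_cost,
            units_per_person_covered=spec.units_per_person_covered,
            device_lifetime_years=spec.device_lifetime_years,
            launch_year=spec.launch_year,
            treatment_cost=table,
        )


@dataclass
class SensitivityResult:
    """One row of a one-at-a-time sensitivity table."""

    parameter: str
    perturbation: str
    cumulative_lives_saved: float
    cumulative_incremental_cost: float
    delta_lives_saved: float
    delta_cost: float


def incremental_cost(baseline: Sequence[CascadeResult],
                     scenario: Sequence[CascadeResult],
                     costs: CostInputs,
                     discount_rate: float = 0.0,
                     ) -> tuple[dict[int, float], float, dict[str, float]]:
    """Per-year and cumulative incremental cost of a scenario.

    Returns ``(cost_by_year, cumulative, breakdown)``. Negative totals mean
    the innovation saves money overall.
    """
    base_by_key = {(r.country_code, r.year): r for r in baseline}
    scen_by_key = {(r.country_code, r.year): r for r in scenario}
    if set(base_by_key) != set(scen_by_key):
        raise ValueError("baseline and scenario cover different country-years")

    years = sorted({y for _, y in base_by_key})
    first_year = years[0] if years else 0
    cost_by_year = {y: 0.0 for y in years}
    breakdown = {
        "innovation_cost": 0.0,
        "introduction_cost": 0.0,
        "additional_treatment_cost": 0.0,
        "false_positive_treatment_cost": 0.0,
        "averted_treatment_cost": 0.0,
    }
    for (country, year), scen in scen_by_key.items():
        base = base_by_key[(country, year)]
        year_cost = 0.0

        innovation = (scen.innovation_units_used * costs.unit_cost
                      / costs.device_lifetime_years)
        breakdown["innovation_cost"] += innovation
        year_cost += innovation

        for s in SETTINGS:
            delta_treated = scen.treated[s] - base.treated[s]
            fp = scen.false_positive_treatments[s]
            if delta_treated == 0.0 and fp == 0.0:
                continue
            try:
                per_case = costs.treatment_cost[(country, year, s)]
            except KeyError:
                raise ConfigurationError(
                    f"no treatment cost for ({country}, {year}, {s})"
                ) from None
            if delta_treated >= 0.0:
                breakdown["additional_treatment_cost"] += delta_treated * per_case
            else:
                breakdown["averted_treatment_cost"] += -delta_treated * per_case
            fp_cost = (costs.false_positive_unit_cost
                       if costs.false_positive_unit_cost is not None else per_case)
            breakdown["false_positive_treatment_cost"] += fp * fp_cost
            year_cost += delta_treated * per_case + fp * fp_cost

        if year == costs.launch_year or (costs.launch_year < first_year
                                         and year == first_year):
            breakdown["introduction_cost"] += costs.introduction_cost
            year_cost += costs.introduction_cost

        if discount_rate:
            year_cost /= (1.0 + discount_rate) ** (year - first_year)
        cost_by_year[year] += year_cost

    cumulative = sum(cost_by_year.values())
    return cost_by_year, cumulative, breakdown


def _config_hash(spec: InnovationSpec, config: EngineConfig) -> str:
    payload = json.dumps(
        {"spec": spec.to_dict(), "config": dataclasses.asdict(config)},
        sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_forecast(records: Sequence[CountryYearInputs],
                 innovation: InnovationSpec,
                 config: EngineConfig | None = None,
                 out_dir: str | Path | None = None,
                 validate: bool = True) -> ForecastResult:
    """Full pipeline: validate, run baseline and scenario, difference the
    death trajectories, and cost the scenario.

    When ``out_dir`` is given, writes ``forecast.csv`` (tidy per
    country-year-setting rows for both arms), ``summary.json`` and
    ``manifest.json`` there.
    """
    config = config or EngineConfig()
    condition = innovation.condition_id
    subset = [r for r in records if r.condition_id == condition]
    if validate:
        report = validate_inputs(subset)
        if not report.ok:
            raise ValidationFailed(report)

    baseline = engine.run_baseline(subset, condition, config)
    scenario = engine.run_scenario(subset, condition, innovation, config)
    forecast = engine.incremental_lives_saved(baseline, scenario,
                                              innovation.innovation_id)
    costs = CostInputs.from_inputs(subset, innovation)
    cost_by_year, cumulative_cost, breakdown = incremental_cost(
        baseline, scenario, costs, config.discount_rate)
    forecast.incremental_cost_by_year = cost_by_year
    forecast.cumulative_incremental_cost = cumulative_cost
    forecast.cost_breakdown = breakdown
    saved = forecast.cumulative_lives_saved
    forecast.metadata = {
        "innovation_id": innovation.innovation_id,
        "condition_id": condition,
        "roster": sorted({r.country_code for r in subset}),
        "config_hash": _config_hash(innovation, config),
        "cost_per_death_averted": (cumulative_cost / saved) if saved > 0 else None,
    }

    if out_dir is not None:
        _write_outputs(Path(out_dir), forecast, baseline, scenario)
    return forecast


def _write_outputs(out_dir: Path, forecast: ForecastResult,
                   baseline: Sequence[CascadeResult],
                   scenario: Sequence[CascadeResult]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    base_df = engine.results_to_frame(baseline).assign(arm="baseline")
    scen_df = engine.results_to_frame(scenario).assign(arm="scenario")
    import pandas as pd

    pd.concat([base_df, scen_df], ignore_index=True).to_csv(
        out_dir / "forecast.csv", index=False)
    summary = {
        "innovation_id": forecast.innovation_id,
        "condition_id": forecast.condition_id,
        "years": forecast.years,
        "baseline_deaths_by_year": forecast.baseline_deaths_by_year,
        "scenario_deaths_by_year": forecast.scenario_deaths_by_year,
        "lives_saved_by_year": forecast.lives_saved_by_year,
        "cumulative_lives_saved": forecast.cumulative_lives_saved,
        "incremental_cost_by_year": forecast.incremental_cost_by_year,
        "cumulative_incremental_cost": forecast.cumulative_incremental_cost,
        "cost_breakdown": forecast.cost_breakdown,
        "warnings": forecast.warnings,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    (out_dir / "manifest.json").write_text(json.dumps(forecast.metadata, indent=1))


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity
# ---------------------------------------------------------------------------

def _clip01(x: float, label: str) -> float:
    if x < 0.0 or x > 1.0:
        clipped = min(1.0, max(0.0, x))
        warnings.warn(f"sensitivity: {label} {x:.4g} clipped to {clipped:.4g}",
                      UserWarning, stacklevel=3)
        return clipped
    return x


def _perturb_spec(spec: InnovationSpec, parameter: str, value: float) -> InnovationSpec:
    if parameter == "peak_coverage":
        new = {s: (None if v is None else _clip01(v + value, f"peak_coverage_{s}"))
               for s, v in spec.peak_coverage.items()}
        return replace(spec, peak_coverage=new)
    if parameter == "effectiveness":
        if spec.mechanism == "adherence_boost":
            return replace(spec, coverage_boost_points=_clip01(
                spec.coverage_boost_points + value, "coverage_boost_points"))
        new = {s: (None if v is None else _clip01(v + value, f"effectiveness_{s}"))
               for s, v in spec.effectiveness.items()}
        return replace(spec, effectiveness=new)
    if parameter == "unit_cost":
        if value < 0:
            raise ValueError("unit_cost bound must be non-negative")
        return replace(spec, unit_cost=value)
    raise ValueError(
        f"unknown sensitivity parameter {parameter!r}; "
        "expected peak_coverage, effectiveness, or unit_cost")


def one_at_a_time_sensitivity(records: Sequence[CountryYearInputs],
                              innovation: InnovationSpec,
                              parameters: Sequence[str] = ("peak_coverage",
                                                           "effectiveness"),
                              delta: float = 0.05,
                              cost_bounds: Optional[tuple[float, float]] = None,
                              config: EngineConfig | None = None,
                              ) -> list[SensitivityResult]:
    """Vary each input in isolation and re-run the full model.

    Coverage and effectiveness move by ``+delta`` and ``-delta`` (in
    percentage-point units, default 0.05); ``unit_cost``, when requested via
    ``cost_bounds=(lower, upper)``, is set to each bound. The central run
    appears once, first, with zero deltas.
    """
    config = config or EngineConfig()
    central = run_forecast(records, innovation, config)
    results = [SensitivityResult(
        parameter="central", perturbation="central",
        cumulative_lives_saved=central.cumulative_lives_saved,
        cumulative_incremental_cost=central.cumulative_incremental_cost,
        delta_lives_saved=0.0, delta_cost=0.0)]

    runs: list[tuple[str, str, InnovationSpec]] = []
    for parameter in parameters:
        if parameter == "unit_cost":
            continue
        for signed in (+delta, -delta):
            label = f"{signed:+g}"
            runs.append((parameter, label,
                         _perturb_spec(innovation, parameter, signed)))
    if cost_bounds is not None:
        lower, upper = cost_bounds
        runs.append(("unit_cost", "lower", _perturb_spec(innovation, "unit_cost", lower)))
        runs.append(("unit_cost", "upper", _perturb_spec(innovation, "unit_cost", upper)))

    for parameter, label, perturbed in runs:
        fc = run_forecast(records, perturbed, config, validate=False)
        results.append(SensitivityResult(
            parameter=parameter,
            perturbation=label,
            cumulative_lives_saved=fc.cumulative_lives_saved,
            cumulative_incremental_cost=fc.cumulative_incremental_cost,
            delta_lives_saved=(fc.cumulative_lives_saved
                               - central.cumulative_lives_saved),
            delta_cost=(fc.cumulative_incremental_cost
                        - central.cumulative_incremental_cost),
        ))
    return results
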