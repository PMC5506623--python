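"""Data model for country-year inputs and innovation specifications.

The forecast engine consumes two kinds of inputs:

* **Country tables** — one row per (country, year, condition) carrying the
  demographic denominators (births, neonates, pregnancies, under-5
  population), condition incidence, the home/clinic/hospital setting mix,
  the baseline care cascade (coverage and effectiveness of the current
  standard of care per setting), treated/untreated case-fatality rates,
  and per-case treatment costs.
* **Innovation specifications** — the parameters of a candidate innovation:
  the mechanism class by which it perturbs the cascade, launch year, linear
  adoption ramp, per-setting peak coverage and effectiveness, and costs.

Eight innovation presets covering postpartum hemorrhage, obstructed labor,
neonatal sepsis, diarrhea, and pneumonia ship as packaged JSON files.
"""
from __future__ import annotations

import csv
import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

SETTINGS = ("home", "clinic", "hospital")

#: Conditions the engine knows, mapped to the population at risk whose size
#: multiplies incidence to give annual cases.
CONDITION_TARGET_POPULATION = {
    "pph": "pregnancies",
    "obstructed_labor": "pregnancies",
    "neonatal_sepsis": "neonates",
    "diarrhea": "under5_population",
    "pneumonia": "under5_population",
}

MECHANISMS = (
    "incidence_reduction",
    "mortality_reduction",
    "coverage_expansion",
    "second_line_treatment",
    "adherence_boost",
    "diagnostic_improvement",
)

HORIZON = (2015, 2030)

#: Demonstration roster of ISO-3166 alpha-3 codes. The model accepts any
#: roster supplied in a country table; this list only seeds examples and
#: synthetic data.
DEMO_ROSTER = (
    "NGA", "ETH", "COD", "TZA", "KEN", "UGA", "MOZ", "IND", "PAK", "BGD",
    "IDN", "MMR", "AFG", "NER", "MLI",
)

#: Named roster adjustments. The neonatal-sepsis (chlorhexidine) analysis
#: uses a slightly different country list tied to WHO home-birth cord-care
#: recommendations: a handful of countries enter and a handful leave.
ROSTER_ADJUSTMENTS = {
    "chlorhexidine": {
        "include": ("AGO", "BWA", "GNQ", "GAB", "AFG", "DJI"),
        "exclude": ("BTN", "IDN", "PRK", "LKA"),
    },
}


def adjust_roster(roster: Sequence[str], name: str) -> tuple[str, ...]:
    """Apply a named roster adjustment (e.g. ``"chlorhexidine"``)."""
    try:
        adj = ROSTER_ADJUSTMENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown roster adjustment {name!r}; "
            f"available: {sorted(ROSTER_ADJUSTMENTS)}"
        ) from None
    kept = [c for c in roster if c not in adj["exclude"]]
    kept.extend(c for c in adj["include"] if c not in kept)
    return tuple(kept)


@dataclass
class CountryYearInputs:
    """One (country, year, condition) row of model inputs.

    Per-setting fields are mappings keyed by ``home``/``clinic``/``hospital``.
    ``incidence`` is events per person at risk per year; for diarrhea it is
    episodes per child-year and may exceed 1. ``eligible_fraction`` is the
    share of the population an innovation can physically reach (e.g. the
    community-water-source share for a water treatment device); it defaults
    to 1 and is only consulted for innovations that declare an eligibility
    filter.
    """

    country_code: str
    year: int
    condition_id: str
    live_births: float
    neonates: float
    under5_population: float
    pregnancies: float
    incidence: float
    setting_mix: dict[str, float]
    baseline_coverage: dict[str, float]
    baseline_effectiveness: dict[str, float]
    cfr_treated: dict[str, float]
    cfr_untreated: dict[str, float]
    treatment_cost_per_case: dict[str, float]
    eligible_fraction: float = 1.0

    def target_population(self) -> float:
        """Size of the population at risk for this row's condition."""
        try:
            attr = CONDITION_TARGET_POPULATION[self.condition_id]
        except KeyError:
            raise ConfigurationError(
                f"condition {self.condition_id!r} has no mapped target "
                f"population; known conditions: "
                f"{sorted(CONDITION_TARGET_POPULATION)}"
            ) from None
        return getattr(self, attr)


@dataclass
class InnovationSpec:
    """Parameters of one innovation to insert into the cascade.

    ``effectiveness`` has a mechanism-specific meaning: the success
    probability of the innovation's treatment (coverage expansion, second
    line), the proportional reduction it achieves (incidence or mortality
    reduction), or the detection sensitivity (diagnostics). For the
    adherence-boost mechanism the effect size lives in
    ``coverage_boost_points`` instead (percentage points added to baseline
    first-line coverage at full adoption).
    """

    innovation_id: str
    condition_id: str
    mechanism: str
    launch_year: int
    unit_cost: float
    peak_coverage: dict[str, float]
    effectiveness: dict[str, float] = field(default_factory=dict)
    ramp_years: int = 5
    units_per_person_covered: float = 1.0
    introduction_cost: float = 0.0
    market_behavior: str = "expand"
    eligible_population_filter: Optional[str] = None
    specificity: float = 0.95
    coverage_boost_points: float = 0.0
    device_lifetime_years: float = 1.0
    notes: str = ""

    def settings(self) -> tuple[str, ...]:
        """Settings in which this innovation operates (non-null peak coverage)."""
        return tuple(s for s in SETTINGS if self.peak_coverage.get(s) is not None)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "InnovationSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown InnovationSpec fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ValidationReport:
    """All invariant violations found in a batch of inputs.

    Violations are data, not exceptions: every rule is checked for every
    row and the report lists them all.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, locator: str, rule: str, message: str) -> None:
        self.errors.append((locator, rule, message))


class SchemaError(ValueError):
    """A file is missing required columns/fields or a value cannot parse."""


class ConfigurationError(ValueError):
    """Model configuration is inconsistent (unknown condition, mechanism...)."""


# ---------------------------------------------------------------------------
# country-table i/o
# ---------------------------------------------------------------------------

_SCALAR_COLUMNS = (
    "country_code", "year", "condition_id", "live_births", "neonates",
    "under5_population", "pregnancies", "incidence", "eligible_fraction",
)
_SETTING_FIELDS = (
    "setting_mix", "baseline_coverage", "baseline_effectiveness",
    "cfr_treated", "cfr_untreated", "treatment_cost_per_case",
)


def _columns() -> list[str]:
    cols = list(_SCALAR_COLUMNS)
    for f in _SETTING_FIELDS:
        cols.extend(f"{f}_{s}" for s in SETTINGS)
    return cols


def _record_to_row(rec: CountryYearInputs) -> dict[str, object]:
    row: dict[str, object] = {c: getattr(rec, c) for c in _SCALAR_COLUMNS}
    for f in _SETTING_FIELDS:
        mapping = getattr(rec, f)
        for s in SETTINGS:
            row[f"{f}_{s}"] = mapping[s]
    return row


def _row_to_record(row: Mapping[str, object], locator: str) -> CountryYearInputs:
    missing = [c for c in _columns() if c not in row]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    kwargs: dict[str, object] = {}
    for c in _SCALAR_COLUMNS:
        raw = row[c]
        if c in ("country_code", "condition_id"):
            kwargs[c] = str(raw)
        elif c == "year":
            try:
                kwargs[c] = int(raw)
            except (TypeError, ValueError):
                raise SchemaError(f"{locator}: cannot parse year={raw!r}") from None
        else:
            try:
                kwargs[c] = float(raw)
            except (TypeError, ValueError):
                raise SchemaError(f"{locator}: cannot parse {c}={raw!r}") from None
    for f in _SETTING_FIELDS:
        mapping = {}
        for s in SETTINGS:
            col = f"{f}_{s}"
            try:
                mapping[s] = float(row[col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{locator}: cannot parse {col}={row[col]!r}"
                ) from None
        kwargs[f] = mapping
    return CountryYearInputs(**kwargs)


def load_country_table(path: str | Path, format: Optional[str] = None) -> list[CountryYearInputs]:
    """Read a country table (CSV with header, or a JSON array of rows).

    Returns one record per (country, year, condition), sorted by country
    then year then condition. The format is inferred from the suffix when
    not given.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows: list[Mapping[str, object]]
    if fmt == "csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    elif fmt == "json":
        with open(path) as fh:
            rows = json.load(fh)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'json')")
    records = [
        _row_to_record(row, locator=f"{path.name}:row {i + 1}")
        for i, row in enumerate(rows)
    ]
    records.sort(key=lambda r: (r.country_code, r.year, r.condition_id))
    return records


def write_country_table(records: Iterable[CountryYearInputs], path: str | Path,
                        format: Optional[str] = None) -> None:
    """Write records back to CSV or JSON with the canonical column schema."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = [_record_to_row(r) for r in records]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_columns())
            writer.writeheader()
            writer.writerows(rows)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'csv' or 'json')")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _check_fraction(report: ValidationReport, locator: str, name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        report.add(locator, "fraction_bounds", f"{name}={value} outside [0, 1]")


def validate_inputs(records: Sequence[CountryYearInputs]) -> ValidationReport:
    """Check every invariant on every record; report all violations.

    Rules: setting mix sums to 1 (±1e-9); all fractions in [0, 1];
    incidence, counts, and costs non-negative; treated CFR no greater than
    untreated CFR in each setting; year within the 2015–2030 horizon.
    """
    report = ValidationReport()
    for rec in records:
        loc = f"{rec.country_code}/{rec.year}/{rec.condition_id}"
        mix_sum = sum(rec.setting_mix[s] for s in SETTINGS)
        if abs(mix_sum - 1.0) > 1e-9:
            report.add(loc, "setting_mix_sum",
                       f"setting_mix sums to {mix_sum}, expected 1")
        for s in SETTINGS:
            _check_fraction(report, loc, f"setting_mix_{s}", rec.setting_mix[s])
            _check_fraction(report, loc, f"baseline_coverage_{s}", rec.baseline_coverage[s])
            _check_fraction(report, loc, f"baseline_effectiveness_{s}", rec.baseline_effectiveness[s])
            _check_fraction(report, loc, f"cfr_treated_{s}", rec.cfr_treated[s])
            _check_fraction(report, loc, f"cfr_untreated_{s}", rec.cfr_untreated[s])
            if rec.cfr_treated[s] > rec.cfr_untreated[s]:
                report.add(loc, "cfr_order",
                           f"cfr_treated_{s}={rec.cfr_treated[s]} exceeds "
                           f"cfr_untreated_{s}={rec.cfr_untreated[s]}")
            if rec.treatment_cost_per_case[s] < 0:
                report.add(loc, "cost_nonnegative",
                           f"treatment_cost_per_case_{s}="
                           f"{rec.treatment_cost_per_case[s]} is negative")
        _check_fraction(report, loc, "eligible_fraction", rec.eligible_fraction)
        if rec.incidence < 0:
            report.add(loc, "incidence_nonnegative", f"incidence={rec.incidence} < 0")
        for count_field in ("live_births", "neonates", "under5_population", "pregnancies"):
            if getattr(rec, count_field) < 0:
                report.add(loc, "count_nonnegative",
                           f"{count_field}={getattr(rec, count_field)} < 0")
        if not (HORIZON[0] <= rec.year <= HORIZON[1]):
            report.add(loc, "year_in_horizon",
                       f"year={rec.year} outside [{HORIZON[0]}, {HORIZON[1]}]")
        if rec.condition_id not in CONDITION_TARGET_POPULATION:
            report.add(loc, "known_condition",
                       f"unknown condition {rec.condition_id!r}")
    return report


def validate_spec(spec: InnovationSpec) -> ValidationReport:
    """Check an innovation specification's own invariants."""
    report = ValidationReport()
    loc = spec.innovation_id
    if spec.mechanism not in MECHANISMS:
        report.add(loc, "known_mechanism", f"unknown mechanism {spec.mechanism!r}")
    if spec.condition_id not in CONDITION_TARGET_POPULATION:
        report.add(loc, "known_condition", f"unknown condition {spec.condition_id!r}")
    if spec.ramp_years < 1:
        report.add(loc, "ramp_years", f"ramp_years={spec.ramp_years} < 1")
    if spec.unit_cost < 0:
        report.add(loc, "cost_nonnegative", f"unit_cost={spec.unit_cost} < 0")
    if spec.introduction_cost < 0:
        report.add(loc, "cost_nonnegative",
                   f"introduction_cost={spec.introduction_cost} < 0")
    if not spec.settings():
        report.add(loc, "peak_coverage_present",
                   "no setting has a non-null peak_coverage")
    for s, v in spec.peak_coverage.items():
        if v is not None and not (0.0 <= v <= 1.0):
            report.add(loc, "fraction_bounds", f"peak_coverage_{s}={v} outside [0, 1]")
    for s, v in spec.effectiveness.items():
        if v is not None and not (0.0 <= v <= 1.0):
            report.add(loc, "fraction_bounds", f"effectiveness_{s}={v} outside [0, 1]")
    for name in ("specificity", "coverage_boost_points"):
        v = getattr(spec, name)
        if not (0.0 <= v <= 1.0):
            report.add(loc, "fraction_bounds", f"{name}={v} outside [0, 1]")
    if spec.market_behavior not in ("expand", "replace"):
        report.add(loc, "market_behavior",
                   f"market_behavior={spec.market_behavior!r} not in expand/replace")
    return report


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "oxytocin_new_formulation",
    "ubt",
    "odon",
    "chlorhexidine",
    "diarrhea_treatment",
    "water_chlorinator",
    "pulse_oximeter",
    "rr_monitor",
)


def builtin_preset(name: str) -> InnovationSpec:
    """Load one of the eight shipped innovation presets by identifier."""
    if name not in PRESET_NAMES:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {list(PRESET_NAMES)}"
        )
    data = (resources.files("mnch_impact") / "presets" / f"{name}.json").read_text()
    return InnovationSpec.from_dict(json.loads(data))


def load_innovation_spec(path: str | Path) -> InnovationSpec:
    """Read an innovation specification from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return InnovationSpec.from_dict(data)


def write_innovation_spec(spec: InnovationSpec, path: str | Path) -> None:
    path = Path(path)
    data = spec.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))
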