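"""Costing decomposition, forecast orchestration, and OAT sensitivity."""
import math

import pytest

from mnch_impact import (
    CostInputs,
    EngineConfig,
    SETTINGS,
    SynthConfig,
    ValidationFailed,
    builtin_preset,
    generate_country_inputs,
    incremental_cost,
    one_at_a_time_sensitivity,
    run_baseline,
    run_forecast,
    run_scenario,
)
from .conftest import make_record, make_spec


def diarrhea_records(seed=11, n=2):
    return [r for r in generate_country_inputs(
        SynthConfig(seed=seed, n_countries=n, conditions=("diarrhea",)))]


class TestIncrementalCost:
    def test_zero_coverage_innovation_costs_nothing(self, horizon_records):
        spec = make_spec(peak_coverage={s: 0.0 for s in SETTINGS})
        fc = run_forecast(horizon_records, spec)
        assert fc.cumulative_incremental_cost == 0.0

    def test_unit_ceiling_rule(self):
        # 500 persons covered by a 1000-person device -> 1 unit at $70
        rec = make_record(
            condition_id="diarrhea", under5_population=2000.0, incidence=3.0,
            eligible_fraction=1.0, year=2020)
        spec = make_spec(
            condition_id="diarrhea", mechanism="incidence_reduction",
            launch_year=2015, ramp_years=1, unit_cost=70.0,
            units_per_person_covered=1000.0,
            peak_coverage={"home": 0.25, "clinic": None, "hospital": None},
            effectiveness={"home": 0.84},
            eligible_population_filter="community_water")
        [scen] = run_scenario([rec], "diarrhea", spec)
        assert scen.innovation_uses == pytest.approx(500.0)
        assert scen.innovation_units_used == 1
        baseline = run_baseline([rec], "diarrhea")
        costs = CostInputs.from_inputs([rec], spec)
        _, _, breakdown = incremental_cost(baseline, [scen], costs)
        assert breakdown["innovation_cost"] == pytest.approx(70.0)

    def test_prevention_of_costly_disease_saves_money(self):
        records = diarrhea_records()
        fc = run_forecast(records, builtin_preset("water_chlorinator"))
        assert fc.cumulative_incremental_cost < 0
        assert fc.cost_breakdown["averted_treatment_cost"] > \
            fc.cost_breakdown["innovation_cost"]

    def test_cost_identity_recomputed_from_results(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        baseline = run_baseline(records, "diarrhea")
        scenario = run_scenario(records, "diarrhea", spec)
        costs = CostInputs.from_inputs(records, spec)
        by_year, cumulative, breakdown = incremental_cost(baseline, scenario, costs)

        # independent recomputation of the four-term decomposition
        lookup = {(r.country_code, r.year): r for r in records}
        innovation = sum(r.innovation_units_used * spec.unit_cost
                         / spec.device_lifetime_years for r in scenario)
        additional = averted = fp_cost = 0.0
        for b, s in zip(baseline, scenario):
            rec = lookup[(b.country_code, b.year)]
            for st in SETTINGS:
                delta = s.treated[st] - b.treated[st]
                per_case = rec.treatment_cost_per_case[st]
                if delta >= 0:
                    additional += delta * per_case
                else:
                    averted += -delta * per_case
                fp_cost += s.false_positive_treatments[st] * per_case
        intro = spec.introduction_cost * len({r.country_code for r in records})
        assert breakdown["innovation_cost"] == pytest.approx(innovation, rel=1e-9)
        assert breakdown["averted_treatment_cost"] == pytest.approx(averted, rel=1e-9)
        assert cumulative == pytest.approx(
            innovation + intro + additional + fp_cost - averted, rel=1e-9)
        assert cumulative == pytest.approx(sum(by_year.values()), rel=1e-9)

    def test_introduction_cost_charged_once_per_country(self):
        records = diarrhea_records(n=3)
        spec = builtin_preset("water_chlorinator")
        fc_free = run_forecast(records, spec)
        import dataclasses
        fc_paid = run_forecast(
            records, dataclasses.replace(spec, introduction_cost=10_000.0))
        assert fc_paid.cumulative_incremental_cost - \
            fc_free.cumulative_incremental_cost == pytest.approx(30_000.0)
        assert fc_paid.cost_breakdown["introduction_cost"] == 30_000.0


class TestRunForecast:
    def test_validation_failure_raises(self):
        bad = make_record(incidence=-1.0)
        with pytest.raises(ValidationFailed, match="incidence"):
            run_forecast([bad], make_spec())

    def test_determinism_identical_outputs(self, tmp_path):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        a = run_forecast(records, spec, out_dir=tmp_path / "a")
        b = run_forecast(records, spec, out_dir=tmp_path / "b")
        assert a.metadata == b.metadata
        assert a.lives_saved_by_year == b.lives_saved_by_year
        assert (tmp_path / "a" / "summary.json").read_bytes() == \
            (tmp_path / "b" / "summary.json").read_bytes()
        assert (tmp_path / "a" / "manifest.json").read_bytes() == \
            (tmp_path / "b" / "manifest.json").read_bytes()

    def test_country_additivity(self):
        records = diarrhea_records(n=3)
        spec = builtin_preset("water_chlorinator")
        full = run_forecast(records, spec)
        parts = []
        for code in sorted({r.country_code for r in records}):
            subset = [r for r in records if r.country_code == code]
            parts.append(run_forecast(subset, spec))
        assert full.cumulative_lives_saved == pytest.approx(
            sum(p.cumulative_lives_saved for p in parts), rel=1e-12)

    def test_cost_per_death_averted_derived_field(self):
        records = diarrhea_records()
        fc = run_forecast(records, builtin_preset("diarrhea_treatment"))
        expected = fc.cumulative_incremental_cost / fc.cumulative_lives_saved
        assert fc.metadata["cost_per_death_averted"] == pytest.approx(expected)


class TestSensitivity:
    def test_zero_delta_equals_central(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        rows = one_at_a_time_sensitivity(records, spec, ("peak_coverage",),
                                         delta=0.0)
        central = rows[0]
        assert central.parameter == "central"
        for row in rows[1:]:
            assert row.cumulative_lives_saved == central.cumulative_lives_saved
            assert row.delta_lives_saved == 0.0

    def test_perturbation_equals_explicit_rerun(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        rows = one_at_a_time_sensitivity(records, spec, ("peak_coverage",),
                                         delta=0.05)
        plus = next(r for r in rows if r.perturbation == "+0.05")
        import dataclasses
        perturbed = dataclasses.replace(
            spec, peak_coverage={"home": 0.30, "clinic": None, "hospital": None})
        explicit = run_forecast(records, perturbed)
        assert plus.cumulative_lives_saved == explicit.cumulative_lives_saved

    def test_linear_mechanism_symmetric_deltas(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")  # linear, clipping-free
        rows = one_at_a_time_sensitivity(records, spec, ("peak_coverage",),
                                         delta=0.05)
        up = next(r for r in rows if r.perturbation == "+0.05")
        down = next(r for r in rows if r.perturbation == "-0.05")
        assert abs(up.delta_lives_saved) == pytest.approx(
            abs(down.delta_lives_saved), rel=1e-9)

    def test_cost_bounds_never_change_deaths(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        rows = one_at_a_time_sensitivity(records, spec, ("unit_cost",),
                                         cost_bounds=(35.0, 140.0))
        central = rows[0]
        cost_rows = [r for r in rows if r.parameter == "unit_cost"]
        assert len(cost_rows) == 2
        for row in cost_rows:
            assert row.cumulative_lives_saved == central.cumulative_lives_saved
            assert row.delta_cost != 0.0

    def test_out_of_range_delta_clips_with_warning(self):
        records = diarrhea_records()
        spec = builtin_preset("water_chlorinator")
        with pytest.warns(UserWarning, match="clipped"):
            rows = one_at_a_time_sensitivity(records, spec, ("peak_coverage",),
                                             delta=0.9)
        down = next(r for r in rows if r.perturbation == "-0.9")
        assert math.isfinite(down.cumulative_lives_saved)
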