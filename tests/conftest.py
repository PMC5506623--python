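import pytest

from mnch_impact import CountryYearInputs, InnovationSpec, SETTINGS


def make_record(**overrides) -> CountryYearInputs:
    """A valid single-country-year row with overridable fields."""
    base = dict(
        country_code="XAA",
        year=2020,
        condition_id="pph",
        live_births=95_000.0,
        neonates=95_000.0,
        under5_population=450_000.0,
        pregnancies=100_000.0,
        incidence=0.05,
        setting_mix={"home": 0.5, "clinic": 0.3, "hospital": 0.2},
        baseline_coverage={"home": 0.2, "clinic": 0.5, "hospital": 0.8},
        baseline_effectiveness={"home": 0.6, "clinic": 0.8, "hospital": 0.9},
        cfr_treated={"home": 0.02, "clinic": 0.01, "hospital": 0.005},
        cfr_untreated={"home": 0.10, "clinic": 0.08, "hospital": 0.06},
        treatment_cost_per_case={"home": 5.0, "clinic": 20.0, "hospital": 50.0},
        eligible_fraction=1.0,
    )
    base.update(overrides)
    return CountryYearInputs(**base)


def make_spec(**overrides) -> InnovationSpec:
    """A valid innovation spec with overridable fields."""
    base = dict(
        innovation_id="test_innovation",
        condition_id="pph",
        mechanism="coverage_expansion",
        launch_year=2015,
        ramp_years=5,
        unit_cost=1.0,
        peak_coverage={"home": 0.2, "clinic": 0.2, "hospital": 0.2},
        effectiveness={"home": 0.6, "clinic": 0.8, "hospital": 0.9},
        market_behavior="expand",
    )
    base.update(overrides)
    return InnovationSpec(**base)


@pytest.fixture
def single_setting_record():
    """All cases present at home: coverage 0.5, effectiveness 0.8,
    CFR 0.01 treated / 0.10 untreated, 1000 annual cases."""
    return make_record(
        condition_id="pph",
        pregnancies=20_000.0,
        incidence=0.05,  # 1000 cases
        setting_mix={"home": 1.0, "clinic": 0.0, "hospital": 0.0},
        baseline_coverage={"home": 0.5, "clinic": 0.0, "hospital": 0.0},
        baseline_effectiveness={"home": 0.8, "clinic": 0.0, "hospital": 0.0},
        cfr_treated={"home": 0.01, "clinic": 0.01, "hospital": 0.01},
        cfr_untreated={"home": 0.10, "clinic": 0.10, "hospital": 0.10},
    )


@pytest.fixture
def horizon_records():
    """One country, full 2015-2030 horizon, PPH condition."""
    return [make_record(year=y) for y in range(2015, 2031)]
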