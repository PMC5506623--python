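"""Seeded synthetic country tables and a per-individual microsimulation
oracle.

The generator produces country-year-condition rows with the statistical
structure the deterministic engine assumes: demographic denominators drawn
log-uniformly, condition incidence drawn from per-condition ranges
(diarrhea episodes per child-year around the 2.4-3.3 band typical of
South-East Asia and sub-Saharan Africa), a Dirichlet setting mix, baseline
cascade parameters per setting, case-fatality rates with the treated rate
strictly below the untreated rate, and per-case treatment costs. Values are
constant across years within a country (the engine assumes no secular
trend). Identical seed and config give an identical table, and every
generated row passes input validation. No attempt is made to match real
country demographics.

The microsimulation oracle is a brute-force realization of the same
cascade: each simulated case draws its setting, first-line coverage,
treatment success, innovation-mechanism events, and death as independent
Bernoulli variables. Its mean equals the deterministic engine's expectation
whenever both encode the cascade correctly, which is what the equivalence
tests exploit.
"""
from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import innovation_mechanisms as mech
from .cascade_engine import EngineConfig
from .model_inputs import (
    CONDITION_TARGET_POPULATION,
    HORIZON,
    SETTINGS,
    ConfigurationError,
    CountryYearInputs,
    InnovationSpec,
)

ALL_CONDITIONS = tuple(CONDITION_TARGET_POPULATION)


def _default_incidence_ranges() -> dict[str, tuple[float, float]]:
    return {
        "diarrhea": (2.4, 3.3),        # episodes per child-year
        "pneumonia": (0.15, 0.40),
        "pph": (0.03, 0.08),           # per pregnancy
        "obstructed_labor": (0.02, 0.06),
        "neonatal_sepsis": (0.005, 0.03),
    }


def _default_cfr_untreated_ranges() -> dict[str, tuple[float, float]]:
    return {
        "diarrhea": (0.001, 0.005),    # per episode
        "pneumonia": (0.02, 0.10),
        "pph": (0.01, 0.06),
        "obstructed_labor": (0.02, 0.10),
        "neonatal_sepsis": (0.10, 0.30),
    }


def _default_cost_ranges() -> dict[str, tuple[float, float]]:
    return {
        "diarrhea": (2.0, 10.0),       # ORS + zinc + antibiotics per episode
        "pneumonia": (5.0, 25.0),
        "pph": (10.0, 60.0),
        "obstructed_labor": (20.0, 120.0),
        "neonatal_sepsis": (10.0, 60.0),
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic country-table generator."""

    seed: int = 0
    n_countries: int = 5
    conditions: tuple[str, ...] = ALL_CONDITIONS
    years: tuple[int, int] = HORIZON
    live_births_range: tuple[float, float] = (1e5, 2e6)
    incidence_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_incidence_ranges)
    setting_mix_alpha: tuple[float, float, float] = (4.0, 3.0, 2.0)
    coverage_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"home": (0.10, 0.40), "clinic": (0.30, 0.70),
                                 "hospital": (0.50, 0.90)})
    effectiveness_range: tuple[float, float] = (0.50, 0.90)
    cfr_untreated_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_cfr_untreated_ranges)
    cfr_treated_ratio_range: tuple[float, float] = (0.10, 0.50)
    treatment_cost_ranges: dict[str, tuple[float, float]] = field(
        default_factory=_default_cost_ranges)
    eligible_fraction_range: tuple[float, float] = (0.30, 0.90)


@dataclass
class MicrosimEstimate:
    """Monte-Carlo estimate of deaths for one country-year."""

    deaths: float
    se: float
    n_individuals: int
    seed: int


def _country_codes(n: int) -> list[str]:
    letters = string.ascii_uppercase
    codes = [f"X{a}{b}" for a, b in itertools.product(letters, letters)]
    return codes[:n]


def _check_range(name: str, rng_pair: tuple[float, float]) -> None:
    lo, hi = rng_pair
    if lo > hi:
        raise ConfigurationError(f"infeasible range for {name}: ({lo}, {hi})")


def generate_country_inputs(config: SynthConfig) -> list[CountryYearInputs]:
    """Generate a full synthetic country table.

    One row per (country, year, condition) over the configured horizon;
    deterministic in the seed; every row satisfies the input invariants.
    """
    _check_range("live_births", config.live_births_range)
    _check_range("effectiveness", config.effectiveness_range)
    _check_range("cfr_treated_ratio", config.cfr_treated_ratio_range)
    _check_range("eligible_fraction", config.eligible_fraction_range)
    for s in SETTINGS:
        _check_range(f"coverage_{s}", config.coverage_ranges[s])
    for cond in config.conditions:
        if cond not in CONDITION_TARGET_POPULATION:
            raise ConfigurationError(f"unknown condition {cond!r}")
        _check_range(f"incidence[{cond}]", config.incidence_ranges[cond])
        _check_range(f"cfr_untreated[{cond}]", config.cfr_untreated_ranges[cond])
        _check_range(f"treatment_cost[{cond}]", config.treatment_cost_ranges[cond])

    rng = np.random.default_rng(config.seed)
    years = range(config.years[0], config.years[1] + 1)
    records: list[CountryYearInputs] = []

    for code in _country_codes(config.n_countries):
        lo, hi = config.live_births_range
        live_births = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        neonates = live_births
        pregnancies = live_births * 1.05        # pregnancy loss margin
        under5 = live_births * 4.8              # ~5 cohorts net of mortality
        eligible = float(rng.uniform(*config.eligible_fraction_range))

        for cond in config.conditions:
            incidence = float(rng.uniform(*config.incidence_ranges[cond]))
            mix = rng.dirichlet(config.setting_mix_alpha)
            mix = mix / mix.sum()
            setting_mix = {s: float(m) for s, m in zip(SETTINGS, mix)}
            coverage = {s: float(rng.uniform(*config.coverage_ranges[s]))
                        for s in SETTINGS}
            effectiveness = {s: float(rng.uniform(*config.effectiveness_range))
                             for s in SETTINGS}
            cfr_untreated = {
                s: float(rng.uniform(*config.cfr_untreated_ranges[cond]))
                for s in SETTINGS}
            cfr_treated = {
                s: cfr_untreated[s] * float(
                    rng.uniform(*config.cfr_treated_ratio_range))
                for s in SETTINGS}
            cost = {s: float(rng.uniform(*config.treatment_cost_ranges[cond]))
                    for s in SETTINGS}
            for year in years:
                records.append(CountryYearInputs(
                    country_code=code, year=year, condition_id=cond,
                    live_births=live_births, neonates=neonates,
                    under5_population=under5, pregnancies=pregnancies,
                    incidence=incidence, setting_mix=dict(setting_mix),
                    baseline_coverage=dict(coverage),
                    baseline_effectiveness=dict(effectiveness),
                    cfr_treated=dict(cfr_treated),
                    cfr_untreated=dict(cfr_untreated),
                    treatment_cost_per_case=dict(cost),
                    eligible_fraction=eligible,
                ))
    records.sort(key=lambda r: (r.country_code, r.year, r.condition_id))
    return records


def microsim_oracle(inputs: CountryYearInputs,
                    innovation: Optional[InnovationSpec] = None,
                    n_individuals: int = 200_000,
                    seed: int = 0,
                    config: EngineConfig | None = None) -> MicrosimEstimate:
    """Estimate expected deaths for one country-year by simulating cases.

    Each simulated case (an episode, for diarrhea) draws setting, coverage,
    treatment success, any innovation-mechanism event, and death as
    independent Bernoulli variables from one explicitly seeded stream; the
    mean death indicator scaled by the expected case count estimates
    deaths, with a binomial-style standard error.
    """
    if n_individuals < 1000:
        raise ValueError("n_individuals must be at least 1000")
    config = config or EngineConfig()
    rng = np.random.default_rng(seed)
    n = n_individuals
    total_cases = inputs.target_population() * inputs.incidence
    spec = innovation
    eligible = 1.0
    if spec is not None and spec.eligible_population_filter:
        eligible = inputs.eligible_fraction

    alive_case = np.ones(n, dtype=bool)
    if spec is not None and spec.mechanism == "incidence_reduction":
        s0 = spec.settings()[0]
        cov_y = mech.coverage_at_year(spec, inputs.year, s0)
        p_prevented = eligible * cov_y * spec.effectiveness[s0]
        alive_case = rng.random(n) >= p_prevented

    mix = np.array([inputs.setting_mix[s] for s in SETTINGS])
    setting_idx = rng.choice(len(SETTINGS), size=n, p=mix / mix.sum())

    u_cov = rng.random(n)
    u_eff = rng.random(n)
    u_death = rng.random(n)

    death = np.zeros(n, dtype=bool)
    for i, s in enumerate(SETTINGS):
        sel = (setting_idx == i) & alive_case
        if not sel.any():
            continue
        cov0 = inputs.baseline_coverage[s]
        eff0 = inputs.baseline_effectiveness[s]
        cfr_t = np.full(sel.sum(), inputs.cfr_treated[s])
        cfr_u = np.full(sel.sum(), inputs.cfr_untreated[s])
        u_c, u_e, u_d = u_cov[sel], u_eff[sel], u_death[sel]

        in_scope = spec is not None and s in spec.settings()
        cov_y = (mech.coverage_at_year(spec, inputs.year, s) * eligible
                 if in_scope else 0.0)

        covered = u_c < cov0
        effective = covered & (u_e < eff0)

        if in_scope and spec.mechanism == "mortality_reduction":
            device = rng.random(sel.sum()) < cov_y
            reduction = spec.effectiveness[s]
            cfr_t = np.where(device, cfr_t * (1.0 - reduction), cfr_t)
            cfr_u = np.where(device, cfr_u * (1.0 - reduction), cfr_u)

        elif in_scope and spec.mechanism == "coverage_expansion":
            eff_i = spec.effectiveness[s]
            if spec.market_behavior == "expand":
                added = min(cov_y, 1.0 - cov0)
                via_innov = (u_c >= cov0) & (u_c < cov0 + added)
            else:  # replace: the innovation serves [0, cov_y)
                new_cov = max(cov0, cov_y)
                via_innov = u_c < cov_y
                covered = u_c < new_cov
                effective = covered & ~via_innov & (u_e < eff0)
            effective = effective | (via_innov & (u_e < eff_i))

        elif in_scope and spec.mechanism == "second_line_treatment":
            pool = covered & ~effective
            if config.second_line_pool == "include_untreated":
                pool = pool | ~covered
            rescued = pool & (rng.random(sel.sum()) < cov_y * spec.effectiveness[s])
            effective = effective | rescued

        elif in_scope and spec.mechanism == "adherence_boost":
            ramp = mech.ramp_fraction_at_year(spec, inputs.year)
            new_cov = min(1.0, cov0 + spec.coverage_boost_points * eligible * ramp)
            covered = u_c < new_cov
            effective = covered & (u_e < eff0)

        elif in_scope and spec.mechanism == "diagnostic_improvement":
            detection = spec.effectiveness[s]
            add = cov_y * max(0.0, detection - cov0) * config.downstream_treatment_coverage
            covered = u_c < cov0 + add
            effective = covered & (u_e < eff0)

        p_death = np.where(effective, cfr_t, cfr_u)
        death[sel] = u_d < p_death

    p = death.mean()
    estimate = float(p * total_cases)
    se_p = float(np.sqrt(p * (1.0 - p) / n))
    se_p = max(se_p, 0.5 / n)  # floor so degenerate outcomes keep a finite band
    return MicrosimEstimate(deaths=estimate, se=se_p * total_cases,
                            n_individuals=n, seed=seed)
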