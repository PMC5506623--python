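"""Adoption ramp and the six mechanism classes that perturb the care cascade.

Every innovation acts on exactly one quantity of the cascade:

``incidence_reduction``
    scales condition incidence down among covered, eligible people
    (prevention before the case occurs).
``mortality_reduction``
    scales case fatality down among covered cases in gated settings
    (prevention of death given a case, e.g. antiseptic cord care).
``coverage_expansion``
    raises the fraction of cases receiving first-line treatment, either
    adding to the existing market (``expand``) or displacing it
    (``replace``).
``second_line_treatment``
    rescues first-line failures with a backup intervention (e.g. balloon
    tamponade after uterotonic failure).
``adherence_boost``
    raises coverage/adherence of an existing first-line treatment by a
    fixed number of percentage points at full adoption.
``diagnostic_improvement``
    raises the probability that a true case is identified and routed to
    existing treatment; false positives incur treatment costs but no
    mortality change.

Adoption follows a linear ramp: coverage is 0 before the launch year,
climbs in equal annual steps from ``peak/ramp_years`` in the launch year,
and reaches the peak in ``launch_year + ramp_years - 1``.

All functions are scalar, pure, and clip results to their legal range;
clipping emits a :class:`ClippingWarning` rather than raising.
"""
from __future__ import annotations

import warnings

from .model_inputs import InnovationSpec


class ClippingWarning(UserWarning):
    """A mechanism output left [0, 1] (or went negative) and was clipped."""


def _clip_fraction(value: float, context: str) -> float:
    if value < 0.0 or value > 1.0:
        clipped = min(1.0, max(0.0, value))
        warnings.warn(
            f"{context}: value {value:.6g} clipped to {clipped:.6g}",
            ClippingWarning,
            stacklevel=3,
        )
        return clipped
    return value


def coverage_at_year(spec: InnovationSpec, year: int, setting: str | None = None) -> float:
    """Innovation coverage reached in ``year`` under the linear adoption ramp.

    The first launch year carries ``1/ramp_years`` of the peak (there is no
    zero-coverage launch year); the peak is reached ``ramp_years - 1`` years
    after launch and held thereafter.

    When ``setting`` is None the spec must operate in a single setting.
    """
    if setting is None:
        operating = spec.settings()
        if len(operating) != 1:
            raise ValueError(
                f"{spec.innovation_id} operates in {operating}; pass setting="
            )
        setting = operating[0]
    peak = spec.peak_coverage.get(setting)
    if peak is None:
        return 0.0
    if year < spec.launch_year:
        return 0.0
    ramp_fraction = min(1.0, (year - spec.launch_year + 1) / spec.ramp_years)
    return peak * ramp_fraction


def ramp_fraction_at_year(spec: InnovationSpec, year: int) -> float:
    """Fraction of peak adoption reached in ``year`` (0 before launch)."""
    if year < spec.launch_year:
        return 0.0
    return min(1.0, (year - spec.launch_year + 1) / spec.ramp_years)


def apply_incidence_reduction(incidence: float, coverage: float,
                              effectiveness: float,
                              eligible_fraction: float = 1.0) -> float:
    """Incidence after a preventive innovation reaches ``coverage`` of the
    eligible population and removes ``effectiveness`` of their episodes.

    Returns ``incidence * (1 - eligible_fraction * coverage * effectiveness)``.
    """
    adjusted = incidence * (1.0 - eligible_fraction * coverage * effectiveness)
    if adjusted < 0.0:
        warnings.warn(
            f"incidence_reduction: adjusted incidence {adjusted:.6g} clipped to 0",
            ClippingWarning, stacklevel=2,
        )
        adjusted = 0.0
    return adjusted


def apply_mortality_reduction(cfr: float, coverage: float,
                              mortality_reduction: float) -> float:
    """Case fatality after a mortality-reducing intervention covers
    ``coverage`` of cases: ``cfr * (1 - coverage * mortality_reduction)``.
    """
    return _clip_fraction(cfr * (1.0 - coverage * mortality_reduction),
                          "mortality_reduction")


def apply_coverage_expansion(baseline_coverage: float, innovation_coverage: float,
                             market_behavior: str = "expand") -> float:
    """Total first-line treatment coverage once the innovation enters the
    market.

    ``expand``: the innovation adds to the existing market,
    ``min(1, baseline + innovation)``. ``replace``: the innovation displaces
    the comparator where adopted, ``max(baseline, innovation)``.
    """
    if market_behavior == "expand":
        return _clip_fraction(baseline_coverage + innovation_coverage,
                              "coverage_expansion")
    if market_behavior == "replace":
        return max(baseline_coverage, innovation_coverage)
    raise ValueError(f"unknown market_behavior {market_behavior!r}")


def apply_second_line(uterotonic_failures: float, coverage: float,
                      effectiveness: float) -> float:
    """Count of first-line failures additionally rescued by a second-line
    intervention: ``failures * coverage * effectiveness``. These cases move
    from the untreated to the treated case-fatality rate.
    """
    if uterotonic_failures < 0:
        raise ValueError("failure count must be non-negative")
    return uterotonic_failures * coverage * effectiveness


def apply_adherence_boost(baseline_coverage: float, boost_points: float,
                          ramp_fraction: float = 1.0) -> float:
    """First-line coverage after an adherence-boosting product adds
    ``boost_points`` (scaled by the adoption ramp) percentage points:
    ``min(1, baseline + boost_points * ramp_fraction)``.
    """
    return _clip_fraction(baseline_coverage + boost_points * ramp_fraction,
                          "adherence_boost")


def apply_diagnostic(presenting_cases: float, presenting_noncases: float,
                     coverage: float, detection_prob: float,
                     specificity: float = 0.95,
                     downstream_treatment_coverage: float = 1.0,
                     ) -> tuple[float, float]:
    """Gross effect of a diagnostic device on presenting patients.

    Returns ``(diagnosed_and_treated, false_positive_treatments)`` where

    * ``diagnosed_and_treated = cases * coverage * detection_prob *
      downstream_treatment_coverage`` — true cases the device identifies and
      routes to treatment;
    * ``false_positive_treatments = noncases * coverage * (1 - specificity)
      * downstream_treatment_coverage`` — non-cases treated after a
      false-positive result. They incur treatment costs but receive no
      mortality benefit.

    The incremental effect relative to the baseline diagnostic pathway is
    computed by the cascade engine, not here.
    """
    if presenting_cases < 0 or presenting_noncases < 0:
        raise ValueError("presenting counts must be non-negative")
    diagnosed = (presenting_cases * coverage * detection_prob
                 * downstream_treatment_coverage)
    false_positives = (presenting_noncases * coverage * (1.0 - specificity)
                       * downstream_treatment_coverage)
    return diagnosed, false_positives
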