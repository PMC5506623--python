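{
 "innovation_id": "ubt",
 "condition_id": "pph",
 "mechanism": "second_line_treatment",
 "launch_year": 2015,
 "ramp_years": 5,
 "unit_cost": 5.0,
 "units_per_person_covered": 1.0,
 "device_lifetime_years": 1.0,
 "peak_coverage": {"home": null, "clinic": 0.5, "hospital": 0.75},
 "effectiveness": {"clinic": 0.85, "hospital": 0.85},
 "market_behavior": "expand",
 "notes": "Low-cost uterine balloon tamponade offered to women who fail first-line uterotonic drugs in clinic and hospital settings only (not home). Effectiveness equals existing approved UBT devices. Unit cost is per device used."
}
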