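{
 "innovation_id": "odon",
 "condition_id": "obstructed_labor",
 "mechanism": "coverage_expansion",
 "launch_year": 2018,
 "ramp_years": 5,
 "unit_cost": 25.0,
 "units_per_person_covered": 1.0,
 "device_lifetime_years": 1.0,
 "peak_coverage": {"home": null, "clinic": 0.4, "hospital": null},
 "effectiveness": {"clinic": 0.72, "hospital": 0.81},
 "market_behavior": "expand",
 "notes": "Simple assisted-delivery device expanding coverage of existing assisted vaginal delivery in clinic settings. Effectiveness is similar to existing assisted-delivery devices. Unit cost is per use, similar to other instrumented delivery options."
}
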