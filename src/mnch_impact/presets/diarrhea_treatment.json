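{
 "innovation_id": "diarrhea_treatment",
 "condition_id": "diarrhea",
 "mechanism": "adherence_boost",
 "launch_year": 2018,
 "ramp_years": 5,
 "unit_cost": 0.5,
 "units_per_person_covered": 1.0,
 "device_lifetime_years": 1.0,
 "peak_coverage": {"home": 0.8, "clinic": null, "hospital": null},
 "effectiveness": {},
 "coverage_boost_points": 0.15,
 "market_behavior": "expand",
 "notes": "New severe-diarrhea therapeutics used concurrently with ORS; not effective at reducing mortality in isolation, but raise ORS coverage and adherence by 15 percentage points at full adoption. Unit cost per course, based on ORS."
}
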