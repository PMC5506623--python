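{
 "innovation_id": "rr_monitor",
 "condition_id": "pneumonia",
 "mechanism": "diagnostic_improvement",
 "launch_year": 2015,
 "ramp_years": 5,
 "unit_cost": 50.0,
 "units_per_person_covered": 1000.0,
 "device_lifetime_years": 5.0,
 "peak_coverage": {"home": null, "clinic": 0.5, "hospital": 0.6},
 "effectiveness": {"clinic": 0.8, "hospital": 0.8},
 "specificity": 0.95,
 "market_behavior": "replace",
 "notes": "Improved respiratory-rate monitor for pneumonia diagnosis in clinics and hospitals; effectiveness based on respiratory-rate counting and chest-wall-indrawing evaluations. Unit cost per durable device; one device per ~1000 screens per year, amortized over 5 years. Specificity is a package default, not a published value."
}
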