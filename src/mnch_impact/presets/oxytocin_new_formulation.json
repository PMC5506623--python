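{
 "innovation_id": "oxytocin_new_formulation",
 "condition_id": "pph",
 "mechanism": "coverage_expansion",
 "launch_year": 2022,
 "ramp_years": 5,
 "unit_cost": 0.5,
 "units_per_person_covered": 1.0,
 "device_lifetime_years": 1.0,
 "peak_coverage": {"home": 0.25, "clinic": 0.2, "hospital": 0.1},
 "effectiveness": {"home": 0.4, "clinic": 0.45, "hospital": 0.45},
 "market_behavior": "expand",
 "notes": "Heat-stable, non-injectable oxytocin formulations (sublingual tablet or inhaled powder) expand the uterotonic drug market without replacing conventional oxytocin. Effectiveness equals conventional oxytocin. Unit cost is per dose, assumed similar to misoprostol."
}
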