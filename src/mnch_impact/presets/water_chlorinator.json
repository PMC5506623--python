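{
 "innovation_id": "water_chlorinator",
 "condition_id": "diarrhea",
 "mechanism": "incidence_reduction",
 "launch_year": 2015,
 "ramp_years": 5,
 "unit_cost": 70.0,
 "units_per_person_covered": 1000.0,
 "device_lifetime_years": 5.0,
 "peak_coverage": {"home": 0.25, "clinic": null, "hospital": null},
 "effectiveness": {"home": 0.84},
 "market_behavior": "expand",
 "eligible_population_filter": "community_water",
 "notes": "Automated batch chlorinator for small-scale water treatment; 84% reduction in diarrhea incidence among covered users (Safe Water System data). Coverage applies to the population served by community water sources. One product serves 1000 people; device amortized over a 5-year service life."
}
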