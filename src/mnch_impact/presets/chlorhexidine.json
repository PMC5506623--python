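{
 "innovation_id": "chlorhexidine",
 "condition_id": "neonatal_sepsis",
 "mechanism": "mortality_reduction",
 "launch_year": 2015,
 "ramp_years": 5,
 "unit_cost": 0.36,
 "units_per_person_covered": 1.0,
 "device_lifetime_years": 1.0,
 "peak_coverage": {"home": 0.55, "clinic": null, "hospital": null},
 "effectiveness": {"home": 0.23},
 "market_behavior": "expand",
 "eligible_population_filter": "home_births",
 "notes": "Chlorhexidine umbilical cord care for home births: 23% reduction in neonatal mortality among covered births, applied here to neonatal-sepsis case fatality in the home setting. Effectiveness from low-resource-country meta-analysis; unit cost per birth from the UNICEF supply catalog."
}
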