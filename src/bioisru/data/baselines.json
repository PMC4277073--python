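{
  "propellant": {
    "mars_methane_delivery_o2_production": {
      "shipped_mass_kg": 7512,
      "source_note": "DRA 5.0 option 1: deliver CH4 from Earth, make O2 on Mars"
    },
    "mars_h2_delivery": {
      "shipped_mass_kg": 3251,
      "source_note": "DRA 5.0 option 2: deliver H2, make CH4 and O2 on Mars"
    },
    "mars_soil_water_3wt": {
      "shipped_mass_kg": 2658,
      "source_note": "DRA 5.0 option 3a: Martian soil water at 3 wt%"
    },
    "mars_soil_water_8wt": {
      "shipped_mass_kg": 2021,
      "source_note": "DRA 5.0 option 3b: Martian soil water at 8 wt%"
    },
    "moon_h2_delivery_feo_5wt": {
      "shipped_mass_kg": 4060,
      "source_note": "lunar option 1: deliver H2, regolith FeO at 5 wt%"
    },
    "moon_h2_delivery_feo_14wt": {
      "shipped_mass_kg": 3681,
      "source_note": "lunar option 1: deliver H2, regolith FeO at 14 wt%"
    },
    "moon_water_harvest": {
      "shipped_mass_kg": 1807,
      "source_note": "lunar option 2: harvest water from regolith"
    }
  },
  "plants": {
    "soil_processing_plant_kg": 1828,
    "rwgs_plant_note": "reverse water-gas shift plant kept as a baseline line item only"
  },
  "food": {
    "iss_container_rate_kg_per_crew_day": 1.83,
    "dry_biomass_rate_kg_per_crew_day": 0.617,
    "reference_crew": 6,
    "reference_days": 916,
    "vegetarian": {"total_916d_kg": 10403, "shipped_916d_kg": 4542},
    "mixed": {"total_916d_kg": 9537, "shipped_916d_kg": 4995}
  },
  "habitat": {
    "reference_habitat_volume_m3": 40,
    "total_shipped_t": 8.0,
    "dry_salts_t": 3.8,
    "structure_volume_m3": 6.0,
    "phb_density_kg_m3": 1250,
    "min_volume_per_person_m3": 20,
    "recommended_volume_per_person_m3": 120
  },
  "pharma": {
    "small_vessel_power_mw": 43.7,
    "small_vessel_note": "cited power draw of a 3 L pharma vessel at 2 L working volume; stored constant, below the catalog range"
  }
}
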