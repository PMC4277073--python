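{
  "methanogenesis": {
    "reactants": {"hydrogen": 4, "carbon_dioxide": 1},
    "products": {"methane": 1, "water": 2},
    "note": "hydrogenotrophic methanogenesis (Methanobacterium)"
  },
  "methanogenesis_net_recycle": {
    "reactants": {"hydrogen": 2, "carbon_dioxide": 1},
    "products": {"methane": 1, "oxygen": 1},
    "note": "net form with both product waters electrolysed back to H2; the O2 credit is the electrolyser output"
  },
  "water_electrolysis": {
    "reactants": {"water": 2},
    "products": {"hydrogen": 2, "oxygen": 1},
    "note": ""
  },
  "acetogenesis": {
    "reactants": {"hydrogen": 4, "carbon_dioxide": 2},
    "products": {"acetic_acid": 1, "water": 2},
    "note": "overall Wood-Ljungdahl stoichiometry, acid form for exact balance"
  },
  "phb_synthesis_net": {
    "reactants": {"hydrogen": 3, "carbon_dioxide": 4},
    "products": {"phb_monomer": 1, "oxygen": 3},
    "note": "net per repeating unit after full product-water recycle; 3 H2 make-up per monomer"
  },
  "cell_mass_placeholder": {
    "reactants": {"hydrogen": 2, "carbon_dioxide": 1},
    "products": {"biomass_placeholder": 1, "water": 1},
    "note": "placeholder CH2O growth reaction; real cell-mass stoichiometry is organism-specific"
  }
}
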