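name,formula,note
hydrogen,H2,
oxygen,O2,
water,H2O,
carbon_dioxide,CO2,
carbon_monoxide,CO,
methane,CH4,
ammonia,NH3,
nitrogen,N2,
acetate,C2H3O2,acetate ion (59.04 g/mol); the ion mass reproduces the reported molar yields
acetic_acid,C2H4O2,protonated form used in the balanced acetogenesis reaction
phb_monomer,C4H6O2,polyhydroxybutyrate repeating unit (86.09 g/mol)
ethylene,C2H4,
acetaminophen,C8H9NO2,
biomass_placeholder,CH2O,generic CH2O cell-mass placeholder for growth accounting
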