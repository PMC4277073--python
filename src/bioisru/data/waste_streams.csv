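stream,component,rate_kg_per_crew_day,note
carbon_dioxide,total,1.0,
carbon_dioxide,carbon,0.273,
carbon_dioxide,oxygen,0.727,printed Mars-residence oxygen cell is garbled (216); recomputed 2164
urine_water,total,1.5,
urine_water,nitrogen,0.012,ammoniacal nitrogen; printed Mars-outbound cell garbled (154); recomputed 15.1
nonrecycled_water,total,2.37,assumes recapture
nonrecycled_water,hydrogen,0.266,
nonrecycled_water,oxygen,2.104,
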