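max_working_volume_l,min_working_volume_l,empty_mass_kg,power_density_mw_per_l,skid_volume_m3
50,12,165,7.665,0.710
200,40,239,5.978,1.553
500,100,333,4.082,2.202
1000,200,446,3.240,3.356
2000,400,794,2.407,4.948
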