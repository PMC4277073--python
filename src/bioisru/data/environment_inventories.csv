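location,compound,weight_percent
mars_atmosphere,carbon_dioxide,95.32
mars_atmosphere,nitrogen,2.7
mars_atmosphere,argon,1.6
mars_atmosphere,oxygen,0.13
mars_atmosphere,carbon_monoxide,0.07
mars_atmosphere,water_vapour,0.03
mars_atmosphere,nitric_oxide,0.013
moon_crater_ejecta,carbon_dioxide,0.12
moon_crater_ejecta,carbon_monoxide,0.023
moon_crater_ejecta,water_vapour,5.6
moon_crater_ejecta,hydrogen_sulfide,0.94
moon_crater_ejecta,ammonia,0.34
moon_crater_ejecta,sulfur_dioxide,0.18
moon_crater_ejecta,ethylene,0.17
moon_crater_ejecta,methanol,0.09
moon_crater_ejecta,hydrogen,0.047
moon_crater_ejecta,methane,0.04
moon_crater_ejecta,hydroxide,0.002
mars_soil,silicon_dioxide,45.8
mars_soil,ferric_oxide,17.6
mars_soil,alumina,10.0
mars_soil,magnesium_oxide,9.3
mars_soil,calcium_oxide,6.1
mars_soil,sodium_oxide,3.3
mars_soil,titanium_dioxide,0.81
mars_soil,potassium_oxide,0.41
moon_regolith,silicon_dioxide,47.3
moon_regolith,alumina,17.8
moon_regolith,magnesium_oxide,9.6
moon_regolith,calcium_oxide,11.4
moon_regolith,sodium_oxide,0.7
moon_regolith,titanium_dioxide,1.6
moon_regolith,potassium_oxide,0.6
moon_regolith,ferrous_oxide,10.5
moon_regolith,chromic_oxide,0.2
moon_regolith,manganous_oxide,0.1
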