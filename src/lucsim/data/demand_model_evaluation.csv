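model,class,year,predicted_km2,actual_km2
gm11,paddy_field,2015,41666.11,41483.58
gm11,unirrigated_field,2015,35485.84,35446.85
gm11,forest_land,2015,32074.64,32039.40
gm11,grass_land,2015,8302.01,8283.79
gm11,water_area,2015,6429.65,6513.68
gm11,wet_land,2015,1028.66,983.80
gm11,built_up_land,2015,15200.21,15383.28
gm11,paddy_field,2018,41133.32,41108.65
gm11,unirrigated_field,2018,35270.74,35095.26
gm11,forest_land,2018,32021.62,32002.42
gm11,grass_land,2018,8274.11,8285.71
gm11,water_area,2018,6629.84,6683.98
gm11,wet_land,2018,993.72,969.29
gm11,built_up_land,2018,15984.16,15992.16
markov,paddy_field,2015,42649.47,41483.58
markov,unirrigated_field,2015,35898.24,35446.85
markov,forest_land,2015,31886.70,32039.40
markov,grass_land,2015,8342.97,8283.79
markov,water_area,2015,6185.98,6513.68
markov,wet_land,2015,1089.83,983.80
markov,built_up_land,2015,13410.43,15383.28
markov,paddy_field,2018,41068.75,41108.65
markov,unirrigated_field,2018,35446.85,35095.26
markov,forest_land,2018,31719.00,32002.42
markov,grass_land,2018,8200.95,8285.71
markov,water_area,2018,6513.68,6683.98
markov,wet_land,2018,993.63,969.29
markov,built_up_land,2018,15229.44,15992.16
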