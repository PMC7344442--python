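simulated_class,paddy_field,unirrigated_field,forest_land,grass_land,water_area,wet_land,built_up_land
paddy_field,9601,98,256,47,80,18,353
unirrigated_field,116,8511,39,25,32,11,254
forest_land,296,28,7658,94,17,3,31
grass_land,32,20,107,1779,5,0,12
water_area,78,51,15,7,1430,23,13
wet_land,12,2,2,1,35,194,2
built_up_land,351,253,36,7,17,6,2910
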