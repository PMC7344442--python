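from_class,paddy_field,unirrigated_field,forest_land,grass_land,water_area,wet_land,built_up_land
paddy_field,1,1,1,1,1,1,1
unirrigated_field,1,1,1,1,1,1,1
forest_land,0,0,1,0,1,1,0
grass_land,0,0,1,1,1,1,0
water_area,0,0,0,0,1,0,0
wet_land,0,0,0,0,1,1,0
built_up_land,1,1,1,1,1,1,1
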