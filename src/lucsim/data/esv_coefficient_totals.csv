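class,total
paddy_field,1020.50
unirrigated_field,1051.99
forest_land,6020.71
grass_land,5165.48
water_area,32952.59
wet_land,13646.95
built_up_land,-3150.71
unused_land,52.47
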