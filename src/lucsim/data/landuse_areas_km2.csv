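class,y2018,y2025,y2030
paddy_field,41108.65,40251.44,39555.08
unirrigated_field,35095.26,34691.72,34268.24
forest_land,32002.42,32545.68,32463.44
grass_land,8285.71,8260.36,8238.72
water_area,6683.98,6782.28,6932.36
wet_land,969.29,954.92,927.84
built_up_land,15992.16,16402.08,17502.80
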