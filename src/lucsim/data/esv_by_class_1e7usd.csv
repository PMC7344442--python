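class,y1995,y2000,y2005,y2010,y2015,y2018,y2025,y2030
paddy_field,262.79,274.56,255.77,291.13,320.65,332.03,317.78,321.00
unirrigated_field,225.84,238.17,222.33,255.15,282.44,292.20,282.33,286.67
forest_land,1124.34,1193.68,1118.34,1297.11,1461.09,1524.95,1515.89,1554.27
grass_land,250.36,265.75,248.76,288.26,324.10,338.74,330.09,338.42
water_area,1158.27,1233.39,1163.45,1363.49,1625.77,1743.21,1728.98,1816.58
wet_land,86.52,92.24,86.14,100.49,101.69,104.69,100.82,100.69
built_up_land,-201.47,-224.72,-216.30,-282.62,-367.11,-398.79,-399.79,-438.53
unused_land,0.00,0.00,0.00,0.00,0.01,0.01,0.00,0.00
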