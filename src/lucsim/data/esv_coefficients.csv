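service,category,paddy_field,unirrigated_field,forest_land,grass_land,water_area,wet_land,built_up_land,unused_land
food_production,provisioning,356.78,222.99,76.08,99.69,209.87,133.79,2.62,0.00
raw_material_production,provisioning,23.61,104.94,173.14,146.91,60.34,131.17,0.00,0.00
water_supply,provisioning,-689.96,5.25,89.20,81.33,2174.80,679.46,-1970.18,0.00
gas_regulation,regulating,291.20,175.77,569.28,516.81,202.00,498.45,-634.86,5.25
climate_regulation,regulating,149.53,94.44,1705.21,1366.79,600.76,944.43,0.00,0.00
hydrological_regulation,regulating,713.57,70.83,1243.49,1002.14,26821.69,6356.51,0.00,7.87
environmental_purification,regulating,44.60,26.23,506.32,451.23,1455.99,944.43,-645.36,26.23
soil_formation_retention,supporting,2.62,270.21,695.20,629.62,243.98,606.01,5.25,5.25
nutrient_cycling,supporting,49.84,31.48,52.47,47.22,18.36,47.22,0.00,0.00
biodiversity_protection,supporting,55.09,34.10,632.24,571.90,668.97,2064.62,89.20,5.25
recreation_culture,cultural,23.61,15.74,278.08,251.85,495.82,1240.87,2.62,2.62
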