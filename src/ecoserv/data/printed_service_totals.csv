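service,row,forest,grassland,water,urban_rural,unused,paddy,dry
carbon_1e8t,value_1990,12.0598,0.3402,0.2480,0.2933,0.0188,0.7578,1.6862
carbon_1e8t,value_2020,11.9858,0.2549,0.3053,0.3933,0.0070,0.7285,1.5981
carbon_1e8t,printed_change,-0.0740,-0.0853,0.0573,0.0999,-0.0117,-0.0293,-0.0880
carbon_1e8t,printed_change_pct,-1,-25,23,34,-63,-4,-5
habitat_sum,value_1990,18548.55,6091.1439,2240.899,0,0,0,0
habitat_sum,value_2020,18867.4,4979.60,2818.27,0,0,0,0
habitat_sum,printed_change,318.8890,-1111.535,577.373,0,0,0,0
habitat_sum,printed_change_pct,2,-18,26,0,0,0,0
food_material_1e8yuan,value_1990,28.7966,11.2252,10.992,0,0,110.3017,244.1407
food_material_1e8yuan,value_2020,28.6198,8.4116,13.531,0,0,106.0418,231.397
food_material_1e8yuan,printed_change,-0.1768,-2.8136,2.539,0,0,-4.2599,-12.7431
food_material_1e8yuan,printed_change_pct,-1,-25,23,0,0,-4,-5
erosion_1e4t,value_1990,251.194,142.351,0,764.8605,36.1510,112.9683,1394.96
erosion_1e4t,value_2020,899.043,395.154,0,1872.404,28.7228,451.0758,2013.20
erosion_1e4t,printed_change,647.849,252.803,0,1107.544,-7.4282,338.1075,618.238
erosion_1e4t,printed_change_pct,258,178,0,145,-21,299,44
water_yield_1e8m3,value_1990,0.0380,0.0243,0.0020,0.2116,0.0009,0.0470,0.1193
water_yield_1e8m3,value_2020,0.0922,0.0270,0.0098,0.3125,0.0003,0.0896,0.1539
water_yield_1e8m3,printed_change,0.0542,0.0027,0.0078,0.1009,-0.0006,0.0426,0.0347
water_yield_1e8m3,printed_change_pct,142,11,396,48,-64,91,29
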