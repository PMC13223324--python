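class,food_production,raw_material,combined_printed
dry,1280,602,1882
paddy,2048,136,2183
forest,380,873,1254
grassland,452,670,1122
water,1205,346,1551
urban_rural,0,0,0
unused,0,0,0
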