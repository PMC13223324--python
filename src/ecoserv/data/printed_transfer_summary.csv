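class,sum_1990_km2,sum_2020_km2,printed_abs_change_km2,printed_pct_change
forest,23659,23550,-109,-0.46
grassland,11015,8065,-2950,-26.78
water,12854,14969,2115,16.45
urban_rural,30542,40234,9692,31.73
unused,741,165,-576,-77.73
paddy,51555,49807,-1748,-3.39
dry,131038,124614,-6424,-4.90
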