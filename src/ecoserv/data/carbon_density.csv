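class,c_above,c_below,c_soil,c_dead
forest,67.45,30.32,136.98,3.40
grassland,2.83,23.52,138.83,2.90
water,0.14,0,71.77,0
urban_rural,0.02,3.20,64.6,0
unused,0.02,4.90,66.02,0
paddy,18.90,12.50,85.5,2.40
dry,17.90,11.50,80,1.40
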