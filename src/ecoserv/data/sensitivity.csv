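class,suitability,urban_rural,unused,paddy,dry
forest,1,0.8,0.7,0.6,0.5
grassland,1,0.7,0.6,0.5,0.4
water,1,0.9,0.6,0.5,0.5
urban_rural,0,0,0,0,0
unused,0,0.5,0.4,0.3,0.3
paddy,0,0.7,0.4,0.3,0.3
dry,0,0.6,0.5,0.3,0.3
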