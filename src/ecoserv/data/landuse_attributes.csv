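class,c_factor,p_factor,root_depth_mm,kc
forest,0.025,1,7000,1.008
grassland,0.034,1,2600,0.85
water,0,1,10,0.975
urban_rural,0.99,1,1,0.2
unused,0.85,1,5000,0.75
paddy,0.412,0.2,2000,1.125
dry,0.412,0.6,2000,0.954
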