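threat,weight,max_distance_km,decay
urban_rural,1,12,linear
unused,1,5,linear
paddy,0.5,3,linear
dry,0.5,3,linear
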