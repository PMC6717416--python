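metal,lod,unit
Ba,0.05,ppb
Cd,0.05,ppb
Ag,0.05,ppb
Cr,0.05,ppb
Cu,0.1,ppb
Co,0.1,ppb
Fe,0.1,ppm
Mn,0.1,ppm
Al,1,ppb
Pb,0.01,ppm
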