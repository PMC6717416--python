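brand,country,metal,mean,sd,unit,censored
brand_1,Italy,Al,0.42,0.43,ppm,False
brand_1,Italy,Ba,,,ppm,True
brand_1,Italy,Cd,0.45,0.39,ppb,False
brand_1,Italy,Cu,168.77,174.14,ppb,False
brand_1,Italy,Fe,0.41,0.165,ppm,False
brand_1,Italy,Pb,240.3,106.4,ppb,False
brand_2,Iran,Al,1.59,1.43,ppm,False
brand_2,Iran,Ba,1.07,1.34,ppm,False
brand_2,Iran,Cd,0.33,0.152,ppb,False
brand_2,Iran,Cu,21.4,24.47,ppb,False
brand_2,Iran,Fe,5.2,5.71,ppm,False
brand_2,Iran,Pb,225.12,106.16,ppb,False
brand_3,Spain,Al,0.41,0.26,ppm,False
brand_3,Spain,Ba,0.495,0.417,ppm,False
brand_3,Spain,Cd,0.85,0.49,ppb,False
brand_3,Spain,Cu,41.65,27.53,ppb,False
brand_3,Spain,Fe,0.53,0.61,ppm,False
brand_3,Spain,Pb,195.17,126.9,ppb,False
brand_4,Iran,Al,0.3,0.15,ppm,False
brand_4,Iran,Ba,0.26,0.197,ppm,False
brand_4,Iran,Cd,0.43,0.23,ppb,False
brand_4,Iran,Cu,15.86,10.15,ppb,False
brand_4,Iran,Fe,0.5,0.35,ppm,False
brand_4,Iran,Pb,155.38,25.42,ppb,False
brand_5,Spain,Al,0.46,0.19,ppm,False
brand_5,Spain,Ba,0.09,0.028,ppm,False
brand_5,Spain,Cd,0.17,0.11,ppb,False
brand_5,Spain,Cu,86.2,124.59,ppb,False
brand_5,Spain,Fe,0.53,0.35,ppm,False
brand_5,Spain,Pb,155.03,53.17,ppb,False
brand_6,Iran,Al,0.21,0.12,ppm,False
brand_6,Iran,Ba,0.125,0.077,ppm,False
brand_6,Iran,Cd,0.75,0.212,ppb,False
brand_6,Iran,Cu,151.75,208.8,ppb,False
brand_6,Iran,Fe,0.49,0.36,ppm,False
brand_6,Iran,Pb,189.95,135.57,ppb,False
brand_7,Italy,Al,0.28,0.23,ppm,False
brand_7,Italy,Ba,1.69,2.44,ppm,False
brand_7,Italy,Cd,0.5,0.14,ppb,False
brand_7,Italy,Cu,21.03,10.98,ppb,False
brand_7,Italy,Fe,1.52,1.82,ppm,False
brand_7,Italy,Pb,118.56,77.79,ppb,False
brand_8,Germany,Al,0.68,0.14,ppm,False
brand_8,Germany,Ba,0.376,0.261,ppm,False
brand_8,Germany,Cd,,,ppb,True
brand_8,Germany,Cu,13.9,13.71,ppb,False
brand_8,Germany,Fe,0.32,0.1,ppm,False
brand_8,Germany,Pb,203.23,54.19,ppb,False
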