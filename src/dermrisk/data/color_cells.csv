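color,metal,mean,sd,unit,censored
black,Al,0.51,0.32,ppm,False
black,Ba,1.08,1.67,ppm,False
black,Cd,0.483,0.285,ppb,False
black,Cu,82.8,114.8,ppb,False
black,Fe,2.29,3.98,ppm,False
black,Pb,169.9,106.59,ppb,False
blonde,Al,0.41,0.31,ppm,False
blonde,Ba,,,ppm,True
blonde,Cd,0.5,0.37,ppb,False
blonde,Cu,69.28,117.61,ppb,False
blonde,Fe,0.44,0.42,ppm,False
blonde,Pb,228.7,100.36,ppb,False
light_brown,Al,0.81,1.19,ppm,False
light_brown,Ba,0.3,0.09,ppm,False
light_brown,Cd,0.45,0.4,ppb,False
light_brown,Cu,70.04,117.72,ppb,False
light_brown,Fe,1.56,2.81,ppm,False
light_brown,Pb,167.8,69.74,ppb,False
dark_brown,Al,0.44,0.31,ppm,False
dark_brown,Ba,1.14,1.9,ppm,False
dark_brown,Cd,0.32,0.17,ppb,False
dark_brown,Cu,14.51,11.93,ppb,False
dark_brown,Fe,0.46,0.26,ppm,False
dark_brown,Pb,174.93,84.09,ppb,False
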