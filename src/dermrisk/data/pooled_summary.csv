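metal,unit,n,mean,sd,median,min,max,p90,family,rfd_ing,rfd_derm
Al,ppm,32,0.54,0.64,0.38,0.1,3.7,0.91,lognormal,1,0.1
Ba,ppm,32,0.86,1.43,0.2,0.07,4.51,3.97,loggamma,0.7,0.0049
Cd,ppb,32,0.45,0.3,0.4,0.1,1.2,0.95,weibull,0.001,0.000025
Cu,ppb,32,61.32,100.59,18.7,2.6,334.7,285.4,lognormal,0.04,0.012
Fe,ppm,32,1.19,2.46,0.39,0.17,11.58,2.28,pareto,0.3,0.3
Pb,ppb,32,185.34,90.49,155.7,3.74,385.5,361.21,loglaplace,0.0035,0.00052
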