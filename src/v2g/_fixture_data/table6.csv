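patient,group,dEF,WT,C-cur,L-cur,EDV,Stress,Strain
P1,1,1.4,0.37,0.50,1.52,406.9,76.2,0.44
P2,1,-3.4,0.35,0.40,0.77,328.8,109.9,0.70
P3,1,-2.6,0.59,0.38,1.15,408.8,58.9,0.50
P4,1,-2.9,0.45,0.55,1.60,364.6,89.9,0.53
P5,1,4.0,0.47,0.44,0.90,323.3,127.8,0.65
P6,1,5.6,0.48,0.50,1.23,204.0,92.2,0.66
P7,1,6.6,0.40,0.55,2.19,193.7,46.0,0.66
P8,1,2.0,0.51,0.53,1.83,188.3,62.1,0.56
P9,2,-18.0,0.45,0.43,0.81,385.1,161.2,0.78
P10,2,-8.4,0.39,1.38,1.40,204.2,121.5,0.65
P11,2,-15.2,0.72,0.37,0.65,665.1,109.9,0.37
P12,2,-7.0,0.75,0.48,0.75,334.8,146.0,0.67
P13,2,-5.0,0.49,0.46,0.99,277.2,151.8,0.74
P14,2,-9.5,0.40,0.64,1.71,365.0,90.0,0.62
P15,2,-12.3,0.47,0.45,1.36,299.0,182.6,0.66
P16,2,-13.4,0.56,0.32,1.34,571.1,108.5,0.48
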