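peptide,residue,position,ha,hb2,hb3,hg,hd2,hd3,ca,cb,cg,cd,delta_cb_cg,delta_ca
MpRS,Pro,1,4.61,2.54,2.04,2.04,3.42,3.37,61.76,30.86,26.51,49.28,4.35,-1.58
MpRS,Pro,2,4.76,2.39,1.88,2.01,3.69,3.54,61.62,30.57,27.26,50.37,3.31,-1.72
MpRS,Pro,3,4.71,2.29,1.84,2.05,3.80,3.60,61.24,30.49,27.32,50.20,3.17,-2.10
MpRS,(4R)-FPro,4,4.89,2.73,2.03,5.44,4.20,3.81,59.72,37.22,95.66,56.52,-58.44,-3.62
MpRS,Pro,5,4.45,2.28,1.88,2.01,3.85,3.64,62.86,32.06,27.26,50.51,4.80,-0.48
MpRS,Ser,6,4.70,3.85,3.72,,,,56.46,62.97,,,,-2.25
MpRS,Pro,7,4.62,2.37,1.96,2.05,3.82,3.68,61.53,30.78,27.32,50.69,3.46,-1.81
MpRS,(4S)-FPro,8,4.86,2.62,2.38,5.41,4.07,3.96,60.35,36.90,95.63,56.50,-58.73,-2.99
MpRS,Pro,9,4.69,2.30,1.87,2.02,3.74,3.56,61.22,30.52,27.25,50.13,3.27,-2.12
MpRS,Pro,10,4.68,2.31,1.87,2.02,3.82,3.59,61.19,30.73,27.25,50.25,3.48,-2.15
MpRS,Pro,11,4.37,2.26,1.83,2.00,3.80,3.59,62.82,32.01,27.26,50.33,4.75,-0.52
MpRS,Arg,12,4.24,1.68,1.67,1.54,3.13,3.13,55.80,30.80,26.96,43.17,,-0.98
MpRS,Val,13,4.06,1.94,,0.85,,,61.83,33.03,20.97,,,-0.71
MpRS,Tyr,14,4.57,3.01,2.87,,7.10,,57.51,39.09,,133.19,,-0.67
MpRS,Lys,15,4.28,1.84,1.72,1.34,1.65,1.62,55.16,32.72,24.63,28.84,,-1.80
MpSR,Pro,1,4.61,2.54,2.39,2.05,3.42,3.37,61.75,30.91,26.52,49.30,4.39,-1.59
MpSR,Pro,2,4.76,2.39,1.88,2.01,3.70,3.54,61.65,30.64,27.27,50.36,3.37,-1.69
MpSR,Pro,3,4.63,2.38,1.96,2.06,3.82,3.59,61.31,30.63,27.30,50.28,3.33,-2.03
MpSR,(4S)-FPro,4,4.87,2.59,2.43,5.42,4.07,3.99,60.32,36.97,95.09,56.55,-58.12,-3.02
MpSR,Pro,5,4.43,2.27,1.88,2.02,3.85,3.62,63.06,31.89,27.27,50.44,4.62,-0.28
MpSR,Ser,6,4.71,3.84,3.72,,,,56.24,63.04,,,,-2.47
MpSR,Pro,7,4.68,2.31,1.89,2.02,3.79,3.64,61.51,30.66,27.26,50.50,3.40,-1.83
MpSR,(4R)-FPro,8,4.88,2.72,2.06,5.45,4.22,3.84,59.77,37.20,95.10,56.58,-57.90,-3.57
MpSR,Pro,9,4.71,2.32,1.89,2.03,3.75,3.61,61.37,30.68,27.29,50.21,3.39,-1.97
MpSR,Pro,10,4.68,2.28,1.87,1.99,3.81,3.63,61.26,30.62,27.27,50.32,3.35,-2.08
MpSR,Pro,11,4.37,2.26,1.84,2.00,3.79,3.61,62.79,32.01,27.27,50.36,4.74,-0.55
MpSR,Arg,12,4.23,1.70,,1.56,3.13,,55.82,30.82,26.94,43.17,,-0.96
MpSR,Val,13,4.06,1.93,,0.86,,,61.82,33.04,20.41,,,-0.72
MpSR,Tyr,14,4.57,3.01,2.88,,7.10,,57.52,39.09,,133.19,,-0.66
MpSR,Lys,15,4.27,1.84,,1.34,1.63,,55.23,32.74,24.61,28.87,,-1.73
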