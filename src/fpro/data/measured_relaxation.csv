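peptide,signal,r1_s1,r1_err_s1,noe_max_pct,rho_s1,sigma_s1,r2_echo_s1,r2_echo_err_s1,r2_cpmg_s1,r2_cpmg_err_s1
MpRS,P4(4R),2.23,0.04,-6.8,1.85,-0.12,20.3,0.5,8.6,0.5
MpRS,P8(4S),2.20,0.01,-19.9,1.76,-0.33,24.96,0.6,8.2,0.3
MpSR,P4(4S),2.30,0.01,-9.3,2.25,-0.20,12.4,0.5,5.4,0.3
MpSR,P8(4R),2.13,0.01,-19.0,1.59,-0.28,18.5,0.4,9.7,0.5
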