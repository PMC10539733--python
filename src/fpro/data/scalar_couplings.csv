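label,jf_b2,jf_b3,jf_d2,jf_d3,jab2,jab3
MpRS P4 (4R),42.3,18.8,38.2,21.7,10.1,8.1
MpRS P8 (4S),21.0,42.5,24.6,35.2,3.0,10.5
MpSR P4 (4S),20.9,43.1,24.7,35.4,3.1,10.2
MpSR P8 (4R),42.1,18.9,38.3,21.9,10.2,8.1
free (4R)-FPro,40.5,19.6,37.4,20.1,10.4,8.1
free (4S)-FPro,20.5,41.9,19.4,37.6,2.8,10.5
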