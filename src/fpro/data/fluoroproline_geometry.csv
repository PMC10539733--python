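label,r_HG,r_HB2,r_HB3,r_HD2,r_HD3,delta_sigma_ppm,eta,anti_xy_ppm,anti_xz_ppm,anti_yz_ppm
(4R)-exo major,2.03,3.29,2.56,3.30,2.50,-74.2,0.120,4.71,2.21,-3.45
(4R)-endo minor,2.02,2.89,2.50,2.97,2.44,-25.6,0.396,7.29,2.34,4.42
(4S)-endo major,2.01,2.49,3.29,2.40,3.25,-84.9,0.392,-3.26,-4.27,-6.01
(4S)-exo minor,2.02,2.49,2.89,2.52,2.88,-33.3,0.483,5.78,2.20,-2.32
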