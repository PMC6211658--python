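lam_printed,lam_unit,ki_per_s,thalf_printed,thalf_unit,k_minus_i_per_s,kd_nM,koff_per_s,konss_M_per_s,exceeds_diffusion_limit
83333,hr,1e-8,19254,hr,1e-8,1,,,0
833,hr,1e-6,192.5,hr,1e-6,1,1e-5,1e4,0
83,hr,1e-5,19.25,hr,1e-5,1,1e-4,1e5,0
8.33,hr,1e-4,1.9,hr,1e-4,1,1e-3,1e6,0
50,min,1e-3,11.6,min,1e-3,1,1e-2,1e7,0
5,min,1e-2,1.16,min,1e-2,1,1e-1,1e8,0
30,s,1e-1,6.9,s,1e-1,1,1e0,1e9,1
3,s,1e0,0.69,s,1e0,1,1e1,1e10,1
300,ms,1e1,69,ms,1e1,1,1e2,1e11,1
199,hr,1e-4,1.9,hr,1e-6,1,1e-3,1e6,0
20,hr,8e-4,14.4,min,1e-5,1,1e-2,1e7,0
2.1,hr,3e-3,3.9,min,1e-4,1,1e-1,1e8,0
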