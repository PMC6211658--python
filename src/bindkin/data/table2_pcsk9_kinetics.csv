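variant,ph,kon_M_per_s,konss_over_kon,koff_per_s,koff_prime_per_s,kd_M,kd_prime_M
wt,7.4,1.86e3,53763,1.17e-3,1.17e-3,628e-9,628e-9
wt,5.3,4.73e5,211,1.97e-3,1.97e-3,4.19e-9,4.19e-9
D374Y,7.4,4.57e3,21881,4.64e-4,2.3e-3,101e-9,503e-9
D374Y,5.3,6.74e5,148,3.64e-4,2.3e-3,0.54e-9,3.4e-9
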