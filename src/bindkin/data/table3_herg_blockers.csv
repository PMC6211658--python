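kon_M_per_s,koff_per_s,koff_prime_per_s,proarrhythmic_occupancy_pct,n_kd_prime_M,n_kd_M
1e4,5e-2,2,42,2.6e-4,3.6e-6
1e5,5e-1,2,45,2.9e-5,4.1e-6
1e6,5e0,2,53,7.8e-6,5.7e-6
1e7,5e1,2,54,6.2e-6,5.9e-6
1e8,5e2,2,55,6.0e-6,6.1e-6
1e9,5e3,2,55,6.0e-6,6.1e-6
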