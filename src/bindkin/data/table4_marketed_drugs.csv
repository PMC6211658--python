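name,target,kon_M_per_s,koff_per_s,t_half_min,kd_M
Aliskiren,Renin,4.00E+05,1.1E-04,105,3.00E-10
Aclidinium,Muscarinic M3 receptor,1.10E+06,2.0E-05,578,1.80E-11
Ipratropium,Muscarinic M3 receptor,4.10E+06,1.1E-03,11,2.60E-10
Tiotropium,Muscarinic M3 receptor,7.60E+05,7.2E-06,1604,9.50E-12
Candesartan,Human angiotensin II type 1 receptor,2.60E+04,1.9E-04,61,7.40E-09
Telmisartan,Human angiotensin II type 1 receptor,9.10E+04,1.5E-04,77,1.70E-09
Granisetron,5-HT3,7.50E+05,7.5e-04,15,1.00E-09
Lapatinib,ERBB2/EGFR,1.30E+04,3.9e-05,296,3.00E-09
Desloratadine,Histamine H1 receptor,3.20E+04,3.2e-05,361,1.00E-09
Amlodipine,L-type calcium channel,1.50E+05,3.0E-04,39,2.00E-09
Verapamil,L-type calcium channel,9.20E+07,2.8E0,0.004,3.00E-08
Phenytoin,Na+ channel,2.50E+04,5.0E-01,0.02,2.00E-05
Amprenavir,HIV-1 protease,4.40E+06,4.9E-03,2,1.10E-09
Atazanavir,HIV-1 protease,1.70E+06,6.9E-04,17,4.00E-10
Indinavir,HIV-1 protease,1.50E+06,1.6e-03,7,1.10E-09
Lopinavir,HIV-1 protease,6.60E+06,6.5E-04,18,1.00E-10
Ritonavir,HIV-1 protease,3.90E+06,2.2E-03,5,6.10E-10
Saqunavir,HIV-1 protease,8.20E+05,2.3E-04,50,3.20E-10
Nelfinavir,HIV-1 protease,6.60E+05,6.7E-04,17,1.60E-09
Boceprevir,Hepatitis C virus nonstructural protease (NS3),2.40E+03,4.9E-05,236,2.00E-08
Ciluprevir,Hepatitis C virus nonstructural protease (NS3),9.10E+05,7.3E-04,16,6.20E-09
Telaprevir,Hepatitis C virus nonstructural protease (NS3),2.20E+03,9.6E-05,120,4.30E-08
Deoxy-conformycin,Adenosine deaminase,2.40E+06,4.8E-06,2406,2.00E-12
Efavirenz,HIV-1 reverse transcriptase,1.40E+01,6.8E-05,170,5.00E-06
Elvitegravir,HIV integrase,2.10E+06,8.3e-03,1,4.00E-09
Raltegravir,HIV integrase,2.50E+05,2.5e-03,5,1.00E-08
Methotrexate,Chicken dihydrofolate reductase,3.70E+07,3.3e-04,35,9.00E-12
Trimethoprim,Escherichia coli dihydrofolate reductase,7.20E+07,1.4e-03,8,2.00E-11
Oseltamivir,Viral neuraminidase,7.90E+05,2.5e-04,46,3.10E-10
Saxagliptin,Human dipeptidyl-peptidase IV,1.60E+05,5.4e-05,214,3.50E-10
Vildagliptin,Human dipeptidyl-peptidase IV,8.70E+04,9.8e-04,12,1.10E-08
Triclosan,Enoyl-ACP reductase and Francisella tularensis,8.20E+06,4.2e-04,28,5.10E-11
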