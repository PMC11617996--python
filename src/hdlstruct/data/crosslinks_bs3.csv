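residue_a,residue_b,protein_a,protein_b,peptide_a,peptide_b,mass_h12_da,mass_d12_da,ppm
K59,K30,APOA1,APOA2,LLDNWDSVTSTFSKLR,VKSPELQAEAK,3220.7,3232.8,2.453
K182,K30,APOA1,APOA2,LEALKENGGAR,VKSPELQAEAK,2497.4,2509.5,5.384
K182,S40,APOA1,APOA2,LEALKENGGAR,SPELQAEAKSYFEK,2925.5,2937.6,0.016
K182,K46,APOA1,APOA2,LEALKENGGAR,SKEQLTPLIK,2750.7,2762.7,2.359
K195,K46,APOA1,APOA2,LAEYHAKATEHLSTLSEK,SKEQLTPLIK,3325.8,3337.9,3.620
K208,K30/S31/K39,APOA1,APOA2,AKPALEDLR,VKSPELQAEAK,3162.7,3174.8,2.812
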