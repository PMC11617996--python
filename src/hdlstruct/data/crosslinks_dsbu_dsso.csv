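residue_a,residue_b,protein_a,protein_b,peptide_a,peptide_b,peptide_b_dsso,mass_dsbu_da,mass_dsso_da,ppm_dsbu,ppm_dsso
K40,K30,APOA1,APOA2,DSGRDYVSQFEGSALGKQLNLK,VKSPELQAEAK,,3810.01,3771.91,12.160,1.876
K59,K30,APOA1,APOA2,LLDNWDSVTSTFSKLR,VKSPELQAEAK,,3279.73,3241.67,0.837,0.834
K182,K28,APOA1,APOA2,LEALKENGGAR,DLMEKVK,,2234.20,2196.11,3.988,0.975
K182,K39,APOA1,APOA2,LEALKENGGAR,SPELQAEAKSYFEK,,2982.53,2944.45,1.435,1.257
K182,K46,APOA1,APOA2,LEALKENGGAR,SKEQLTPLIK,SKEQLTPLIKK,2512.43,2603.45,1.033,1.885
K208,K30,APOA1,APOA2,AKPALEDLR,VKSPELQAEAK,,2409.34,2372.26,1.243,1.664
K208,K39,APOA1,APOA2,AKPALEDLR,SPELQAEAKSYFEK,,2837.49,2799.40,2.167,1.518
K208,K44,APOA1,APOA2,AKPALEDLR,SYFEKSK,,2098.13,2061.05,3.749,1.571
K226,K30,APOA1,APOA2,QGLLPVLESFKVSFLSALEEYTK,VKSPELQAEAK,,3996.19,3958.09,2.465,1.938
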