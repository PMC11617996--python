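>APOA2 mature human apolipoprotein A-II chain (77 aa) accession=P02652
QAKEPCVESLVSQYFQTVTDYGKDLMEKVKSPELQAEAKSYFEKSKEQLTPLIKKAGTE
LVNFLSYFVELGTQPATQ
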