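# Amino-acid biosynthesis pathway delineation used by the
# half-missing essentiality rule (matches the synthetic models).
amino_acid	reaction_ids
ala	SYN_ala_1;SYN_ala_2;SYN_ala_3
arg	SYN_arg_1;SYN_arg_2;SYN_arg_3
asn	SYN_asn_1;SYN_asn_2;SYN_asn_3
asp	SYN_asp_1;SYN_asp_2;SYN_asp_3
cys	SYN_cys_1;SYN_cys_2;SYN_cys_3
gln	SYN_gln_1;SYN_gln_2;SYN_gln_3
glu	SYN_glu_1;SYN_glu_2;SYN_glu_3
gly	SYN_gly_1;SYN_gly_2;SYN_gly_3
his	SYN_his_1;SYN_his_2;SYN_his_3
ile	SYN_ile_1;SYN_ile_2;SYN_ile_3
leu	SYN_leu_1;SYN_leu_2;SYN_leu_3
lys	SYN_lys_1;SYN_lys_2;SYN_lys_3
met	SYN_met_1;SYN_met_2;SYN_met_3
phe	SYN_phe_1;SYN_phe_2;SYN_phe_3
pro	SYN_pro_1;SYN_pro_2;SYN_pro_3
ser	SYN_ser_1;SYN_ser_2;SYN_ser_3
thr	SYN_thr_1;SYN_thr_2;SYN_thr_3
trp	SYN_trp_1;SYN_trp_2;SYN_trp_3
tyr	SYN_tyr_1;SYN_tyr_2;SYN_tyr_3
val	SYN_val_1;SYN_val_2;SYN_val_3
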