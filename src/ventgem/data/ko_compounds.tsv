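# Synthetic compound registry for the KO snapshot (toy chemistry).
id	name	formula	charge	compartment
ac	acetate	C2H3O2	-1	c
adp	ADP	C10H12N5O10P2	-3	c
ala	L-alanine	C3H7NO2	0	c
atp	ATP	C10H12N5O13P3	-4	c
biomass	biomass			c
co2	carbon dioxide	CO2	0	c
fdox	oxidised ferredoxin	Fe8S8	0	c
fdred	reduced ferredoxin	Fe8S8	-1	c
glc	D-glucose	C6H12O6	0	c
h	proton	H	1	c
h2	dihydrogen	H2	0	c
h2o	water	H2O	0	c
h2s	hydrogen sulfide	H2S	0	c
lac	L-lactate	C3H5O3	-1	c
na_c	sodium (cytosol)	Na	1	c
na_p	sodium (periplasm)	Na	1	p
nad	NAD+	C21H26N7O14P2	-1	c
nadh	NADH	C21H27N7O14P2	-2	c
nadp	NADP+	C21H25N7O17P3	-3	c
nadph	NADPH	C21H26N7O17P3	-4	c
nh4	ammonium	H4N	1	c
pi	phosphate	HO4P	-2	c
pyr	pyruvate	C3H3O3	-1	c
s0	elemental sulfur	S	0	c
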