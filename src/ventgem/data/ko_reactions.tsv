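# Synthetic offline KO->reaction snapshot covering the toy
# energy-network chemistry; KO assignments are illustrative.
ko	reaction_id	name	equation	reversibility
K00259	AADH	alanine dehydrogenase	ala + 2 fdox + h2o => 2 fdred + 2 h + nh4 + pyr	irreversible
K00873	GLYC	glycolysis (lumped; pyruvate kinase marker)	2 adp + glc + 2 nad + 2 pi => 2 atp + 2 h + 2 h2o + 2 nadh + 2 pyr	irreversible
K00169	PFOR	pyruvate:ferredoxin oxidoreductase (lumped)	adp + 2 fdox + pi + pyr => ac + atp + co2 + 2 fdred + h	irreversible
K00016	LDH	L-lactate dehydrogenase	h + nadh + pyr => lac + nad	irreversible
K14090	MBH	membrane-bound hydrogenase complex	2 fdred + 2 h + na_c => 2 fdox + h2 + na_p	irreversible
K14086	MBS	membrane-bound sulfur reductase complex	2 fdred + 2 h + 3 na_c + s0 => 2 fdox + h2s + 3 na_p	irreversible
K17993	SH1	soluble hydrogenase I	h2 + nadp <=> h + nadph	reversible
K22158	NFN2	NADP-dependent ferredoxin oxidoreductase II	2 fdred + h + nadh + 2 nadp <=> 2 fdox + nad + 2 nadph	reversible
K02117	ATPS	Na+-driven ATP synthase	adp + h + 3 na_p + pi => atp + h2o + 3 na_c	irreversible
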