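# Default hydrothermal-vent culture condition (synthetic stand-in
# bounds; uptake/secretion magnitudes in mmol/gDW/h).
exchange_id	max_uptake	max_secretion
EX_h2	10	1000
EX_co2	10	1000
EX_s0	10	1000
EX_nh4	10	1000
EX_pi	1000	1000
EX_ala	5	1000
EX_glc	2	1000
EX_h2o	1000	1000
EX_h	1000	1000
EX_ac	0	1000
EX_lac	0	1000
EX_h2s	0	1000
EX_biomass	0	1000
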