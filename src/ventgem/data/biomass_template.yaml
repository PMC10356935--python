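# Ancestor biomass template (synthetic stand-in for a core-model-derived
# objective): DNA+RNA+protein mass fractions sum to ~0.8 of dry weight,
# building blocks in mmol/gDW, energy cost in mmol ATP/gDW.
macromolecule_fractions:
  protein: 0.55
  RNA: 0.205
  DNA: 0.045
  other: 0.2
building_blocks:
  ala: 1.0
  nadph: 2.0
energy_cost: 10.0
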