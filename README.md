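# ventgem

Constraint-based modelling of the energy metabolism of anaerobic,
sulfur-reducing thermophiles from deep-sea hydrothermal vents — and of the
ancestral metabolisms inferred for their deep-branching clades.

The package is aimed at microbial physiologists and evolutionary systems
biologists who work with genome-scale metabolic models (GEMs) of organisms
whose respiration runs on ferredoxin-driven membrane complexes: a
hydrogen-evolving membrane-bound hydrogenase (MBH), a membrane-bound sulfur
reductase (MBS, reducing S⁰ to H₂S), soluble hydrogenase (SH1), the
electron-bifurcating transhydrogenase Nfn2 and a Na⁺-driven ATP synthase.
It covers the full analysis loop for such models:

* **Model curation** — SBML L3+FBC and a spreadsheet-style YAML+TSV dialect;
  per-reaction formula balance, charge balance, and LP-based stoichiometric
  (mass) consistency checks.
* **Simulation** — flux balance analysis (FBA: maximise an objective flux
  `v_obj` subject to `S·v = 0` and bounds), flux variability analysis (FVA:
  per-reaction `[min v_i, max v_i]` with `v_obj ≥ f·v*`), and
  gene/complex knockouts through gene–protein–reaction (GPR) rules.
* **Gap-filling** — penalty-minimal completion of a draft network until
  biomass precursors and essential cofactors are producible.
* **Protocols** — carbon-source scans at fixed total carbon, electron-
  acceptor scans, leave-one-out amino-acid essentiality, the genomic
  half-missing-pathway essentiality rule, and growth-rate estimation
  `μ = ln(OD₂/OD₁)/(t₂−t₁)` (two-point or 4–6-point log-linear regression).
* **Ancestral reconstruction** — filter reconciliation-style gene-family
  copy-number tables at a copy-number threshold, map KO terms to reactions
  through an offline snapshot, attach a template biomass (DNA+RNA+protein
  ≈ 80 % of dry weight) and simulate under a hydrothermal-vent medium.
* **Synthetic data** — seeded generators for a ≤25-reaction toy energy
  network (element- and charge-balanced by construction), gene-family
  tables with planted ancestors, auxotrophy models and OD₆₀₀ curves, so the
  entire test suite runs offline.

## Worked example

```python
from ventgem import solve_fba, delete_genes
from ventgem.synth import make_toy_energy_model, toy_sulfur_medium

model = make_toy_energy_model()          # 23 reactions, all checks green
medium = toy_sulfur_medium()             # amino acids + glucose + S0 + H2

wt = solve_fba(model, medium)
print(f"WT biomass optimum: {wt.objective_value:.3f}")

mbs = delete_genes(model, medium, {"mbs"}, atp_synthase_id="ATPS",
                   find_blocked=True)
print(f"-MBS biomass: {100 * mbs.biomass_relative:.1f}% of WT")
print(f"blocked exchanges: {sorted(mbs.blocked_exchanges)}")
```

prints

```
WT biomass optimum: 2.615
-MBS biomass: 67.7% of WT
blocked exchanges: ['EX_h2s', 'EX_pi', 'EX_s0']
```

Read: on the sulfur condition the wild-type toy network grows at 2.615
mmol biomass·gDW⁻¹·h⁻¹; knocking out the sulfur-reducing complex abolishes
S⁰ uptake and H₂S secretion (the phosphate exchange is idle in every
condition) and drops the maximum yield to 67.7 % of wild type, because the
remaining hydrogen-evolving MBH pumps less Na⁺ per electron pair.

The same operations are exposed on the command line:

```sh
vent-gem synth toy-model --seed 1 --out toy/
vent-gem check toy/
vent-gem fba toy/
vent-gem deletions toy/ --complexes complexes.yaml --atp-synthase ATPS --all-combos
```

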