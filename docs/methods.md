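# Methods

## Scope and model formalism

The package treats a metabolic network as a stoichiometric matrix `S`
(compounds × reactions) with flux bounds, gene–protein–reaction (GPR)
boolean rules and one designated biomass objective. Flux balance analysis
(FBA) solves `max c·v  s.t.  S·v = 0, lb ≤ v ≤ ub`; flux variability
analysis (FVA) re-solves `min/max v_i` per reaction with the objective
pinned to a fraction of its optimum. All linear programs run on the
deterministic HiGHS simplex (scipy). Only objective values and FVA ranges
are treated as contractual outputs: the flux vector of a degenerate optimum
is solver-dependent and is never asserted in tests.

Conventions: exchange reactions touch exactly one compound; uptake is a
negative flux, so a maximum uptake `U` is `lower_bound = −U`. A compound's
unknown formula (`None`) is distinct from a known element-free formula
(`{}`); unknown charge is `None`. GPR grammar is infix with `and` binding
tighter than `or`, parentheses allowed, keywords case-insensitive; a
reaction with an empty GPR is constitutive and can never be disabled by
gene deletion.

Stoichiometric coefficients are stored as floats. Every supported source
format (TSV decimals, SBML doubles) is float-typed already, and balance
checks use a 1e-9 residual tolerance, so exact-rational bookkeeping would
add complexity without changing any decision the checks make.

## Consistency checks

Three per-reaction checks precede any simulation:

* **Formula balance** — per-element residual `Σ coef·count`; any
  participant with an unknown formula makes the verdict `skipped_unknown`,
  never balanced/unbalanced.
* **Charge balance** — the same for `Σ coef·charge`.
* **Mass consistency** — existence of a strictly positive molecular-mass
  vector `m ≥ 1` with `Sᵀm = 0` over internal reactions. When none exists,
  the elastic variant (minimise the L1 residual of `Sᵀm`) localises the
  violation; reactions with nonzero residual are flagged. With a single
  planted violator the flag is exact; with interacting violations the L1
  solution names a small covering set rather than every involved reaction.

Exchange reactions and the biomass pseudo-reaction are unbalanced by
construction and reported `exempt_exchange` in all three checks — including
the mass check, where treating biomass as internal would poison the whole
LP through its formula-less pseudo-compound.

## Biomass construction

`BiomassComposition` carries macromolecule mass fractions (DNA, RNA,
protein, other; the three polymers default to ≈0.8 of dry weight), building
blocks in mmol·gDW⁻¹ and a growth-associated maintenance cost in mmol ATP
hydrolysed·gDW⁻¹. The builder consumes building blocks, charges the ATP
cost as `ATP + H₂O → ADP + Pi + H⁺` and produces one unit of a biomass
pseudo-compound. Redox cofactors among the building blocks (NADPH, NADH,
reduced ferredoxin) return their oxidised partner one-for-one: without
this, any NADPH-requiring biomass is structurally blocked, because nothing
else regenerates the oxidised pool at steady state.

## Knockouts and the ATP-synthase readout

Complex deletion evaluates each reaction's GPR with the deleted genes set
to false and forces failing reactions to zero flux; `and` means obligate
subunits, `or` isozymes. Reported metrics are the biomass optimum and the
maximum ATP-synthase flux, both relative to wild type. The ATP-synthase
maximum defaults to a plain LP maximisation with **no** biomass
requirement (`fraction_of_optimum = 0`); requiring a biomass fraction
instead is one keyword away (`atp_synthase_biomass_fraction`). Both are
defensible readouts; the choice is explicit and switchable. Exchanges
whose FVA range collapses to `{0}` in the mutant are reported as blocked
(e.g. S⁰ uptake and H₂S secretion after deleting the sulfur-reducing
complex).

## Gap-filling

A target is producible when a temporary demand on it supports at least
ε = 1e-3 mmol·gDW⁻¹·h⁻¹ (a conventional threshold; configurable). Targets
are tested one at a time, since joint producibility can mask single-target
gaps. Demands are moiety-aware: ATP is probed as hydrolysis turnover
(ATP + H₂O → ADP + Pi + H⁺) and reduced carriers as re-oxidation to their
partner, because a plain sink on a conserved-moiety cofactor can never
balance. The filler returns a penalty-minimal subset of the universal
database: exhaustive ordered search up to 12 candidates (provably minimal,
ties broken lexicographically on the sorted id tuple), and above that an
LP-relaxation candidate pool followed by exact search on the pool or a
verified greedy prune. A full-database infeasibility is detected first and
reported with the unreachable targets.

## Growth protocols

Concentrations in experimental media (mM) are mapped to maximum-uptake
fluxes (mmol·gDW⁻¹·h⁻¹) with a global scale factor of 1: only yield ratios
are interpreted, and ratios are scale-invariant. Carbon sources are
normalised to 10 carbon-mmol total — uptake bound `10 / (C atoms)` — so a
hexose is not trivially favoured over formate; essential amino acids ride
along at 1 each. Growth calls partition the non-negative yields totally:
`-` below the solver noise floor (1e-6), `++` at ≥1.5-fold of the
all-amino-acid reference (boundary inclusive), `+` everything else,
including yields below the reference — "similar growth" is deliberately
not quantified more finely. The genomic essentiality rule calls an amino
acid essential when at least half of its biosynthesis pathway's reactions
are absent from the model (boundary inclusive). Growth rates come from
`μ = ln(OD(t₂)/OD(t₁))/(t₂−t₁)` or an OLS slope of `ln OD` vs time over a
4–6 point window.

## Ancestral reconstruction

Gene-tree/species-tree reconciliation output is consumed, not produced:
one row per gene family with KO terms and the average copy number at a
named internal node. Families with copy number **strictly** greater than
0.3 (the conventional presence threshold for reconciliation-averaged copy
numbers) are retained; the per-node value is used as-is. Retained KO terms
map to reactions through a frozen offline snapshot (live database queries
are irreproducible); duplicate reactions merge with an OR-GPR over the
contributing families, and unmapped KOs are reported, never fatal. The
assembled model gets an exchange per medium compound (the medium's bounds
are applied to the returned model), the template biomass, optional
gap-filling to biomass producibility, and uptake grants (1 mmol·gDW⁻¹·h⁻¹)
for amino acids that the half-missing rule calls essential — ancestral
annotation of amino-acid biosynthesis is too incomplete to treat a missing
pathway as a hard auxotrophy.

## Synthetic fixtures: what they emulate and what they do not

`make_toy_energy_model` builds a 23-reaction anaerobic energy network:
Fd-linked alanine deamination and pyruvate oxidation, lumped NAD-linked
glycolysis, lactate dehydrogenase, MBH (2 Fd_red → H₂, pumping 1 Na⁺), MBS
(2 Fd_red + S⁰ → H₂S, pumping 3 Na⁺), reversible SH1 (H₂ + NADP⁺ ⇌ NADPH)
and Nfn2 (NADH + 2 Fd_red + 2 NADP⁺ ⇌ NAD⁺ + 2 Fd_ox + 2 NADPH), a
Na⁺-driven ATP synthase (3 Na⁺ per ATP) and a biomass consuming alanine,
NADPH and ATP. Every internal reaction is element- and charge-balanced by
construction (sodium is an explicit compartment-tagged species). Default
uptakes: amino acid 10, glucose 1, S⁰ 20, H₂ 10 mmol·gDW⁻¹·h⁻¹ — chosen so
growth is ATP-limited, which is what makes the Na⁺ yield difference between
MBS and MBH visible in biomass.

The toy network encodes the *qualitative* structure only: sulfur
respiration outperforms hydrogen fermentation, the sulfur complex deletion
blocks S⁰/H₂S exchange while fermentative growth persists, SH1 and Nfn2
are the only NADPH sources so their double deletion abolishes growth. Its
deletion percentages are properties of this 23-reaction motif, not
calibrated predictions for any genome-scale model — quantitative
reproduction of published knockout percentages requires the curated model
distribution, which tests look for under `data/curated/`.

`make_auxotrophy_model` plants auxotrophies in a 20-amino-acid network:
non-essential amino acids carry a complete 3-step pathway (one exactly
balanced lumped synthesis from pyruvate/ammonium/sulfide, solved
analytically per target formula, plus two isomerisations); planted
essential ones retain only the middle step, so the FBA leave-one-out scan
and the genomic half-missing rule agree by construction. The default
planted set has the 11 members observed experimentally in the modelled
organism. `make_gene_family_table` gives truth families copy number 1.0
and noise families unmapped KOs with sub-threshold copies;
`make_growth_curve` is `OD(t) = OD₀·e^{μt}·e^{ε_t}`, `ε_t ~ N(0, σ²)`.
All generators are pure functions of (parameters, seed).

What passing tests on these fixtures shows: the algorithms implement their
contracts (LP optimality against an independent solver, exact planted-truth
recovery, provable gap-fill minimality at small size). What they do not
show: anything about curation quality, annotation error, or kinetic
realism of real genome-scale models — the fixtures have no missing
annotations, no promiscuous enzymes, no thermodynamic infeasibilities.

## Numerical choices

LP feasibility/optimality are HiGHS defaults (~1e-9); reporting tolerance
for fluxes, blocked ranges and steady-state residuals is 1e-6; balance
residual tolerance 1e-9. FVA pins the objective with a 1e-9 relaxation so
the fraction-1.0 problem stays feasible under round-off. The growth-call
noise floor is 1e-6 in objective units. Degenerate inputs are defined, not
errors: an empty model is valid, an empty medium closes all uptakes, a
zero-building-block biomass produces biomass from nothing (and is exempt
from balance checks), gap-filling an already-complete draft returns the
empty set.

## Problem sizes

Test and acceptance workloads use the sizes the fixtures are designed
around: 23-reaction toy network, 100-model I/O round-trip sweeps,
50-model FBA-vs-oracle sweeps, 100 random nested deletion chains, ≤12
gap-fill candidates for provable minimality, 50 noise families per
planted-ancestor table, 6-point growth curves.

## Known limitations

* No parsimonious FBA, MOMA/ROOM, dynamic FBA or thermodynamic (ΔG)
  curation; reaction directionality is taken from the source bounds.
* The mass-consistency localisation is an L1 heuristic beyond the
  single-violator case.
* The KO→reaction snapshot, vent medium and biomass template ship as small
  synthetic curated files covering the toy chemistry; swap in organism-
  specific tables for real analyses.
* The greedy large-instance gap-fill path verifies feasibility but not
  global minimality above the exhaustive threshold.
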