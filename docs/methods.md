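# Methods

This note documents the models and conventions the package implements,
the defaults and why they were chosen, what the synthetic fixtures do and
do not emulate, and the numerical choices that matter for reproducing its
output.

## Reaction rules and network expansion

A rule is an EC-third-level generalization of an enzyme action: an RDKit
reaction SMARTS acting on one organic substrate, plus a fixed cofactor
stoichiometry (O₂, H₂O, NAD(P)H/NAD(P)⁺, Cl⁻, H⁺, CoA, Pi, CO₂, and a
massless electron species of charge −1). Expansion is breadth-first:
seeds are generation 0, and a generation-g reaction consumes a compound
first created in generation g−1; it stops at closure or at the generation
cap (default 10). Compounds are identified by canonical SMILES, so
alternative spellings deduplicate, and reactions deduplicate on their full
stoichiometry (symmetric attack sites collapse). Every generated reaction
must balance elements and charge exactly (integer atom counts from the
structures; electrons count as charge −1); an imbalanced rewrite is an
error, not a warning, because balance is what makes overall-reaction
composition meaningful.

The shipped rule set covers chloroaromatic degradation chemistry: aromatic
ring dioxygenation (EC 1.14.12, restricted to chlorinated rings — the toy
scope is halogenated aromatics funnelling into central metabolism),
cis-dihydrodiol dehydrogenation (1.3.1), intradiol ring cleavage
(1.13.11), hydrolytic (3.8.1) and reductive (1.97.1) dechlorination in
aromatic and vinylic variants, enol/keto tautomerization (5.3.2), enoate
reduction (1.3.1), and hydrolytic C–C cleavage of β-keto acids (3.7.1).
Reductive dechlorination consumes two electrons per chloride released.
From 1,2,4-trichlorobenzene this set closes at 422 compounds and 971
reactions within 10 generations and contains both reference routes:

* the 9-step known route — dioxygenation → dehydrogenation →
  ring cleavage → 2× hydrolytic dechlorination → tautomerization →
  reductive dechlorination → enoate reduction → C–C hydrolysis — whose
  net reaction is
  `TCB + 2 O₂ + NADH + 3 H₂O + 2 e⁻ → NAD⁺ + 3 Cl⁻ + 3 H⁺ + glycolate + succinate`;
* a 3-step catechol route,
  `TCB + 2 H₂O + 2 e⁻ → 3 Cl⁻ + H⁺ + catechol`.

Production rule sets are user-suppliable as JSON (pattern, rewrite,
cofactors, reversibility, optional substructure filter).

## Pathways and overall reactions

A pathway is an ordered simple reaction sequence (no compound revisited —
the cycle policy that keeps enumeration finite) connecting the seed to a
sink through non-cofactor compounds, terminating the first time a sink is
reached; the cofactor set never connects steps and is configurable. Two
orderings of the same reactions are distinct pathways. Screens: length at
most the known route's 9 steps (configurable), all touched compounds
catalogued in the registry, and terminal products native to the host
model. The overall reaction sums member stoichiometries; in a linear
pathway every internal intermediate cancels exactly, and the result must
re-balance. Reducing equivalents = electrons consumed / 2 + net NAD(P)H
consumed; NAD(P)H regenerated inside the route nets out, which is why the
known route counts 2 despite three redox steps.

## Constraint-based analysis

The model object is the standard (metabolites, reactions, bounds, biomass)
container with the sparse stoichiometric matrix N; SBML L3+fbc is read and
written via libsbml (L2 kinetic-law bounds are also understood; absent
bounds default from reversibility with a warning). Media are exchange
bounds: nutrients at [−100, 1000] mmol/gDW/h, O₂ at least −18.5, the
xenobiotic at least −10, everything else secretion-only — the in-silico
minimal-medium convention.

All LPs use HiGHS (scipy.optimize.linprog). FVA fixes the objective inside
a ±10⁻⁹-scaled window around its optimum (exact equality is numerically
brittle) and classifies each reaction from its flux interval with
ε = 10⁻⁹: essential (interval excludes 0), blocked (interval ⊆ [−ε, ε]),
substitutable otherwise. The deliberately tiny ε means reactions whose
only freedom is the ~10⁻⁸-scale fixing window classify as substitutable
rather than blocked; comparisons against other FVA implementations should
label both sides at a common ε above solver noise. Shadow prices are the
duals of the mass-balance rows in the maximization orientation (limiting
nutrient ⇒ negative price; convention verified against cobra), reduced
costs the duals of the flux bounds. At degenerate optima duals are
basis-dependent; the report sets `basis_caveat` (detected via nonzero FVA
widths) and only signs and orderings should be interpreted — digit-level
dual values are not reproducible across solvers and are not claimed.

Augmentation inserts degradation reactions (overall reactions or
individual network steps) into a model copy: cofactor ids map to model
metabolites, registry entries map catalogued compounds, and novel
intermediates become new cytoplasmic metabolites with formula and charge
derived from their structures. Routes consuming electrons trigger the
electron-donor half-reaction. The donor default is complete acetate
oxidation, `ac + 2 h₂o → 2 co₂ + 7 h⁺ + 8 e⁻`: the donor substrate is
named in the source material but its oxidation products are not, so the
half-reaction is configurable (a 2-electron partial oxidation can be
substituted), and this choice materially affects how much carbon the
donor diverts — it is the single most consequential free choice in the
augmentation step.

## Thermodynamics

Compound tables carry transformed standard formation energies (pH 7,
298 K, kcal/mol) with standard errors, as produced by a group-contribution
method; the package consumes them and never re-estimates them. Reaction
energies at the 1 mM reference state are
`Δ_r G'^m = Σ ν_j ΔfG'_j + RT Σ ν_j ln a_ref,j` with RT = 1.9872×10⁻³ ×
298 = 0.59219 kcal/mol, reference activity 10⁻³ M for every species except
H⁺ and H₂O (no concentration term — the transformed convention absorbs
them) and dissolved H₂ and O₂ (saturation reference, 3.4×10⁻⁵ and
5.5×10⁻⁵ M). Standard errors combine in quadrature. Transport across the
cytoplasmic membrane adds `c·F·Δψ + 2.303·RT·(pH_out − pH_in)·n_H` with
pH 7.2 cytoplasm / 7.7 periplasm and Δψ defaulting to 0.15 V (the
potential's magnitude is a documented gap in the source conventions).
Oxygenase reactions release free energy largely uncoupled from carrier
reduction; the exploitable release is capped by a pluggable strategy
(default: truncate below −25 kcal/mol). Electron donors are ranked by
p-norm distance of (degree of reductance, dissipation) from the
Minkevich–Eroshin regularity values (4.291, 26.95), ties lexicographic;
acetate (γ = 4.0) is the shipped choice.

## TMFA

Every reaction splits into non-negative forward/backward directions with
binary indicators; `v_dir ≤ v_max·z_dir`, `z_f + z_b ≤ 1`, and for each
direction with an energy estimate
`±(Δ_r G'^m + s + RT Σ ν_j (ln a_j − ln a_ref,j)) ≤ M(1 − z_dir)` with
big-M = 1000 kcal/mol and slack `|s| ≤ 3·se` (equilibrium, Δ_r G' = 0, is
allowed). Activity bounds: 10⁻⁵–0.02 M by default; H₂/O₂ from 10⁻⁸ M to
saturation; CO₂ 10⁻⁴–1.4×10⁻³ M; the xenobiotic and its dihydrodiol get
the expanded window 8×10⁻⁷–0.025 M, applied in all calculations once
enabled (this expansion is what lets the +10.6 kcal/mol first
dioxygenation step run). Exchanges, biomass and reactions with missing
table entries carry direction binaries but no energy row — their
directionality is restricted by the model bounds only, with a user
override table as the escape hatch. The MILP solves with
scipy.optimize.milp (HiGHS, mip_rel_gap 10⁻⁹), and every returned solution
is re-verified by an independent checker (mass balance, bounds, slack
windows, and the second law recomputed from the returned activities);
nothing is trusted from the solver. Useful arithmetic: a unit-coefficient
reaction over k non-exempt species can harvest at most
RT·[ln(0.02/10⁻³)] ≈ 1.77 kcal/mol per substrate and
RT·[ln(10⁻³/10⁻⁵)] ≈ 2.73 kcal/mol per product from concentrations, so a
4-species step buys ≈ 9 kcal/mol — a +12.5 kcal/mol step therefore needs
part of its 3·se slack, and +50 kcal/mol is unrescuable.

Thermodynamic FVA re-runs the MILP per reaction with the objective held at
(1 − 10⁻⁹) of the TMFA optimum; pathways containing any blocked reaction
are screened out. Label flips in both directions occur: an endergonic
step blocks a mass-balance-essential route (making a previously blocked
bypass essential), and conversely.

## Synthetic fixtures

`make_toy_model` builds a ~50-reaction core model: a lumped glycolytic
backbone (glucose → 2 pyruvate + 2 NADH + 2 ATP), pyruvate-based biomass,
full TCA cycle with a redundant aconitase pair (a guaranteed substitutable
pair plus a thermodynamically forbidden futile loop), glyoxylate shunt,
malic enzyme, pyruvate carboxylase, glycolate dehydrogenase, catechol
1,2-dioxygenase with a lumped β-ketoadipate funnel, uncoupled NADH oxidase
and ATPase (so excess redox/energy drains against O₂ rather than
deadlocking conserved pools), acetate oxidation as the electron donor, and
overflow exchanges (pyruvate, glycolate, succinate, catechol). Cofactor
moieties use placeholder element symbols (Q = nicotinamide core, A/P =
adenosine/phosphate units, R = CoA, Z = NADP core) so that every internal
reaction balances exactly while cofactor structures stay abstract.

The closed-form optimum — biomass = yield_coefficient × carbon-uptake
bound (default 0.05 × 10 = 0.5) — holds because pyruvate is the only
biomass precursor, two per glucose, with oxygen demand (~1 mmol O₂ per
glucose at the optimum) well inside the −18.5 bound and all byproduct
pools drained. A maintenance demand above the ATP supply capacity
(2 × uptake) makes the problem infeasible, reported as biomass 0. On TCB,
oxygen is binding instead, which creates the growth/degradation trade-off
and the negative O₂ shadow prices; glucose shows a flat maximize-mode
uptake curve because its assimilation needs no extra reducing power.

Thermodynamic tables are generated by solving a small LP for compound
formation energies such that every core (cytoplasmic, non-exchange,
non-biomass) reaction is exergonic by a margin (default 5 kcal/mol),
except planted reactions pinned to chosen positive values; a seeded random
objective picks a reproducible vertex, so additivity over composed
pathways holds exactly by construction (all energies derive from one
potential per compound). Profiles: `all_downhill`, `one_uphill` (succinate
dehydrogenase at +12.5 by default), `mixed` (1–3 seeded uphill steps from
a menu chosen so the equality constraints stay feasible against the
downhill background). Transport reactions carry no estimate. The same LP
construction covers all 422 network compounds for the pathway-screening
stage, with the known route's first dioxygenation step pinned at
+10.6 kcal/mol. All fixture randomness flows from one integer seed
(package default 1404, arbitrary).

What the fixtures do **not** emulate: genome-scale scope (no amino-acid,
nucleotide or lipid biosynthesis; biomass is a single-precursor sink), a
periplasm (no transport energetics in the toy tables), growth-rate-coupled
maintenance, realistic yields (fixture yields are ~0.024–0.037 g/mmol and
are not comparable to genome-scale values), or the production rule set
behind published network and pathway totals. Passing tests therefore
demonstrate correctness of the algorithms and conventions — balance,
enumeration completeness, LP/MILP optimality, second-law compliance, dual
signs, screen semantics — not numerical agreement with any genome-scale
reconstruction. Reproducing published genome-scale yields requires the
iJN746 SBML as an external input (`external/iJN746.xml`), which is not
redistributed here.

## Numerical choices

* LP/MILP: HiGHS via scipy; FVA ε = 10⁻⁹; objective-fixing scale 10⁻⁹;
  MILP relative gap 10⁻⁹; mass-balance residual tolerance 10⁻⁶; second-law
  tolerance 10⁻⁶ on positive-flux directions.
* Stoichiometry comparisons and intermediate cancellation use an absolute
  tolerance of 10⁻⁹ on coefficients.
* Canonical ordering everywhere (sorted compound/reaction ids, sorted JSON
  keys) makes expansion, classification and report bundles byte-stable
  across runs.
* Ties in electron-donor ranking break lexicographically; overall-reaction
  group keys are the sorted stoichiometry rounded to 9 decimals.

## Known limitations

* Pathway identity is the ordered reaction sequence; counting reaction
  *sets* would give smaller totals.
* Dual values at degenerate optima are basis-dependent; only signs and
  orderings are stable (hence `basis_caveat`).
* The donor half-reaction and the oxygenase cap are modeling choices, not
  measurements; both are configurable and both shift absolute yields.
* No ionic-strength or pKa adjustment of formation energies, and no
  group-contribution estimation — tables are inputs.
* TMFA treats energy-less reactions as bound-restricted only; a special
  constraint scheme for them can be supplied by the user but none is
  derived automatically.
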