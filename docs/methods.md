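# Methods

## Constraint-based model and FBA

A model is metabolites in two compartments (cytoplasm `c`, extracellular
`e`), reactions with signed stoichiometry, flux bounds in mmol gDCW⁻¹ h⁻¹
and optional boolean gene-protein-reaction (GPR) associations, and one
biomass objective. FBA maximizes the biomass flux subject to steady state
`S v = 0` and the bounds; the optimum is the specific growth rate (h⁻¹).

The LP is solved with HiGHS through `scipy.optimize.linprog`, single
threaded and deterministic. Feasibility tolerance is 1e-9 (standard double
precision LP practice); objective values are compared at 1e-6. Only the
objective value is unique under degeneracy: the returned flux vector is one
optimal vertex, and every downstream analysis consumes the objective only.
Solver failures surface as an explicit `failed` status, never a silent
zero. The default bound magnitude for effectively unbounded reactions is
1000 mmol gDCW⁻¹ h⁻¹.

An independent reference implementation
(`labflux.bruteforce.enumerate_lp_optimum`) enumerates all basic feasible
solutions — for a bounded feasible LP the optimum sits on a vertex, and
every vertex pins all but at most rank(S) variables at a bound — and is
used in tests and the acceptance script to verify the engine on random
networks of at most 6 reactions, where enumeration is exact and cheap. The
test suite additionally cross-checks growth on the mini-LAB fixture against
cobrapy with the GLPK solver, reading labflux's own SBML export.

## Media

A medium maps exchange ids to maximum uptakes; application closes every
exchange for uptake and opens the named ones as `lb = -uptake`, leaving
secretion (upper) bounds untouched. Closing unlisted exchanges is
deliberate: omission analysis is meaningless if an unlisted nutrient can
leak in. Three presets encode the workflow's standard conditions:

| preset        | amino acids | lipid | vitamins | oxygen | carbon |
|---------------|-------------|-------|----------|--------|--------|
| `validation`  | 5           | 5     | 1e-4     | 1e-10  | measured uptake |
| `omission`    | 5           | 1     | 1e-4     | 1e-10  | glucose 25 |
| `carbon_scan` | 1           | 1     | 1        | 1e-10  | scanned per grid point |

(all mmol gDCW⁻¹ h⁻¹). The omission preset's defining constraints are
glucose 25 / lipid 1 / oxygen 1e-10; amino acids and vitamins stay at the
validation rates because the omission scan requires every panel nutrient
present at positive uptake before it can be withdrawn. Water, phosphate and
ammonium are opened at the default bound in every preset — a defined medium
always supplies its inorganic salts.

## Biomass and maintenance energetics

Monomer coefficients follow from mass fractions (g per gDCW over protein,
carbohydrate, lipid, nucleotide, vitamin), per-macromolecule monomer mole
fractions, and monomer weights: `1000 · f_M · x_i / M̄_M` with `M̄_M` the
mole-fraction-weighted mean monomer weight, so total consumed monomer mass
is exactly 1 g per g biomass (checked to 1e-6 over random compositions).
Coefficients are emitted at 12 significant digits — far inside that
tolerance — so models round-trip exactly through every text serialization,
including SBML's double formatting. Polymerization water loss is ignored;
free monomer weights are used.

GAM (mmol ATP per gDCW formed) rides inside the biomass reaction as an
ATP + H₂O → ADP + Pi + H⁺ term, the standard GSMM convention for a cost
proportional to growth; NGAM (mmol ATP gDCW⁻¹ h⁻¹) is a lower bound on the
dedicated maintenance reaction, a cost paid regardless of growth. GAM
fitting uses bisection, not gradient methods, because growth is monotone
non-increasing in GAM; the biomass reaction is reassembled at each iterate,
the measurement must be bracketed by growth at the two bracket ends (a
clear error reports both growths otherwise), and iteration stops when
simulated growth is within `tol` (default 1e-8 h⁻¹) of the measurement,
capped at 100 iterations. On the fixtures the growth-to-GAM sensitivity
makes that tolerance equivalent to ~1e-5 on GAM itself.

## Nutrient omission

The canonical panel is the 20 proteinogenic amino acids plus thiamin (B1),
nicotinate (B3), pantothenate (B5), pyridoxamine (B6) and biotin (B7).
Essentiality is operationalized as LP infeasibility *or* optimal growth
below 1e-9 h⁻¹, because a medium missing a biomass precursor typically
yields an optimum of exactly zero rather than an infeasible LP. Preferable
means growth in (0, 0.005) h⁻¹, strict at the threshold: growth of exactly
0.005 classifies non-essential/preferable on the strict `<` side
(preferable requires `< 0.005`).

`omission_factor` scales the withdrawn nutrient's uptake; the default 0 is
a true omission. A fractional factor (e.g. 0.5) is available for
sensitivity-style scans but cannot reveal substitutable-nutrient structure:
halving an uptake never makes the loss of a substitutable nutrient lethal,
so essentiality classification is defined for the true-omission limit.

Double omission by default scans only pairs of single-omission-viable
nutrients (the informative search space — pairs containing a
single-essential nutrient are trivially lethal); the full pair scan is
available via `restrict_to`. A pair is flagged synthetic-essential when
both singles are viable and the joint omission is lethal.

## Carbon scanning

One FBA per (carbon, level) over the default grid 0, 1, 2, 4, 8, 16, 20,
24 mmol gDCW⁻¹ h⁻¹, with all other scanned carbons closed and the
`carbon_scan` background applied. Row monotonicity in uptake and a constant
zero-uptake column are asserted invariants. The scanned carbon list is an
explicit input (the mini-LAB default is its six generated sugars); ranking
breaks ties lexicographically and documents them by construction.

## Reporter metabolites

Gene p-values become inverse-normal scores `z_g = Φ⁻¹(1 − p_g)` (p clamped
to [1e-15, 1 − 1e-15] with a warning when degenerate). A metabolite's
neighborhood is the set of genes in the GPRs of reactions touching it,
with currency metabolites (ATP/ADP/AMP, NAD(P)(H), H⁺, H₂O, phosphate,
CO₂, ammonium, CoA) excluded via a configurable list — they would
otherwise neighbor nearly every gene. The raw score `Σ z_g / √k` is
corrected to a z-score against the mean and SD of the same statistic over
10,000 random size-k draws (with replacement) from the scored gene
universe, seeded; `p = 1 − Φ(z_corr)`. Scores are deterministic given
inputs and seed; changing the seed moves corrected scores only within
Monte-Carlo error of the background (tested). The optional direction map
signs gene scores so coordinated up- and down-regulation separate, the
up/down split the CLI exposes; the default is non-directional.

The DEG filter keeps records with FPKM ≥ 1, |log2FC| ≥ 1.5 and FDR < 0.05
(strict). When a table carries two condition FPKM columns the filter uses
the per-gene maximum; when only FDR is available as a significance column
it stands in for p with the caveat that scores are then conservative.

## The synthetic mini-LAB fixture

The generator emulates the metabolic logic of a fastidious homolactic LAB,
not its scale: ~100 reactions, 81 metabolites, 70 genes. Carbon routes
share a hexose-phosphate pool; a lumped glycolysis yields 3 ATP per hexose
phosphate with lactate secreted. Hexoses cost 1 ATP to enter the pool,
disaccharides hydrolyze to two hexoses (net 4 ATP), sucrose can instead be
cleaved by the ATP-free phosphorylase (net 5 ATP — the energy-saving
phosphorolysis mechanism), and raffinose hydrolyzes to sucrose + galactose
(net 7 ATP with the phosphorylase route). Net ATP yield per mole therefore
strictly orders the carbons, and that order is the planted ground truth
for the scan; it holds at moderate uptakes where carbon/energy supply is
the binding constraint (at the top of the grid the best route can hit the
background amino-acid supply instead, which preserves but compresses the
ordering).

Auxotrophies are planted by omitting biosynthesis routes (default: the 10
amino acids and 4 vitamins that lack synthesis); substitutable pairs are
linked by deamidation/synthetase interconversions only, with no de novo
route, so exactly the planted pairs are synthetic-essential. Biomass mass
fractions (protein 0.45, carbohydrate 0.25, nucleotide 0.1949, lipid
0.105, vitamin 1e-4 g/gDCW) and amino-acid mole fractions are typical LAB
values; the trace vitamin fraction couples vitamin auxotrophies to growth
without making vitamins the binding substrate under the 1e-4 preset
uptake. Default GAM 40 mmol ATP gDCW⁻¹ and NGAM 0.37 mmol ATP gDCW⁻¹ h⁻¹
put glucose-limited growth near 0.26 h⁻¹ at an uptake of 6.634 — a
realistic LAB operating point. Construction is fully deterministic:
the same spec yields byte-identical SBML.

DEG simulation draws perturbed-gene log2FC from N(effect, 0.3) with
effect 2.5 and null genes from N(0, 0.3); p-values are the two-sided tail
of the observed fold change under the null spread (null p-values are
exactly uniform), FDR is Benjamini-Hochberg, and FPKM is log-normal with
~1% of genes under the expression cutoff. The planted reporter answer is
the set of metabolites whose scored neighborhood is majority-perturbed.

What the fixture does *not* emulate — and hence what passing tests do not
show about real data: genome-scale redundancy and alternative pathways,
elemental/charge balancing (a separate mass-balance checker covers models
that carry formulas), redox and proton-motive bookkeeping, condition-
dependent expression noise structure, and the many-to-many GPR complexity
of real annotations. Results on the fixture validate the algorithms, not
any particular organism's biology.

## Problem sizes and numerical choices

Acceptance runs 200 oracle networks (≤ 6 reactions — the size where
exhaustive enumeration is exact), 100 random compositions, 20 GAM fits, 3
planting variants of the essentiality scan, and 20 DEG seeds plus 20 label
permutations for the reporter; the whole script completes in a few seconds
on one CPU, and the sizes were chosen as the smallest that exercise each
property convincingly. Ties in carbon ranking are broken lexicographically;
degenerate background SD (all equal gene scores) maps to a corrected score
of 0; exchanges are written with the `met_e →` orientation so uptake is a
negative lower bound.

## Known limitations

* No flux variability, parsimonious or dynamic FBA; alternate optima are
  not characterized beyond the objective value.
* Gene-knockout essentiality is out of scope (nutrient omission only).
* The reporter scheme is the classical inverse-normal/√k formulation; other
  gene-set statistics (mean, median, tail strength) are not implemented.
* SBML support targets the Level 3 + FBC v2 subset the package writes;
  exotic constructs (species references with math, non-FBC bounds) are not
  preserved.
* Biomass assembly treats monomers as free species (no polymerization
  water accounting) and vitamins as direct biomass precursors.
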