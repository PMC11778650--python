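# Methods

This note records the models, conventions and design choices behind
sulfurflux, in the spirit of a package's statistical/numerical appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The constraint-based model and its assumptions

A model is metabolites (with bracketed one-letter compartment suffixes,
optional Hill-style formulas and charges), reactions (signed stoichiometry
maps, flux bounds in mmol·gDW⁻¹·h⁻¹, a boolean gene rule, and a kind:
metabolic / transport / exchange / biomass), genes, and one biomass
objective. Flux balance analysis assumes pseudo-steady state (S·v = 0),
a cellular objective of growth maximization, and no kinetic, regulatory
or toxicity constraints — in particular, high substrate levels never
inhibit: a DBT titration simply saturates, because substrate toxicity is
deliberately out of scope.

The LP is solved by HiGHS through `scipy.optimize.linprog` with primal and
dual feasibility tolerances of 1e-9 and no randomized components, so
repeated solves are bit-identical. Infeasible and unbounded problems are
reported as such, never coerced to zeros.

## Dual values: orientation, degeneracy

Shadow prices are oriented so that price_i = dZ*/db_i with b_i > 0 forcing
net production of i (a drain); costly metabolites price negative. Because
LP backends disagree on dual sign conventions, each solve can verify the
orientation with one finite-difference probe on the largest-price
metabolite (on by default; `check_orientation=False` skips it in inner
loops). Reduced costs are the bound duals, oriented as dZ*/d(active bound
value), zero for interior reactions.

Two caveats the API surfaces rather than hides:

* **Degenerate optima.** Dual values are not unique at degenerate optima;
  `price_subgradient_interval` returns the two one-sided finite
  differences, and `shadow_prices(..., flag_degenerate=True)` marks
  metabolites whose interval width exceeds 1e-4. Comparisons of printed
  prices across solvers should be restricted to non-degenerate rows.
* **Conserved moieties.** For pool species (NAD(H), adenylates, flavins)
  the mass-balance rows are linearly dependent through moiety
  conservation, so their individual row duals are determined only up to a
  moiety shift; differences along reactions (e.g. the NADH−NAD redox
  value) are well defined. Pathway metabolites like the 4S intermediates
  are unaffected.
* **Alternate optima.** Only the objective value, duals, and explicitly
  tracked fluxes are contract-level outputs. Internal flux distributions
  may differ between runs or backends; where a tracked flux is not unique
  (2-HBP secretion among alternate optima), a lexicographic second stage
  re-maximizes it at growth pinned to its optimum (slack 1e-8·max(1,|Z*|)),
  and both reported fluxes are read from the second-stage solution.

## Biomass assembly

Coefficients follow in closed form from mass fractions: precursor p in
class k with molar mass M_p (g/mmol) and relative molar abundance a_p gets
mass share m_p = f_k·a_p·M_p / Σ_q a_q·M_q, and coefficient
(target_mw/1000)·m_p/M_p mmol·gDW⁻¹. This deterministic proportional
rescaling replaces the spreadsheet-solver step sometimes used for the same
normalization; for this linear objective the two are exactly equivalent,
and the normalization identity (assemble → weigh = target) is property-
tested over random compositions. Growth-associated ATP hydrolysis (default
30 mmol·gDW⁻¹) is part of the reaction but excluded from the molecular
weight — it is turnover, not mass; otherwise the "molecular weight" would
depend on the maintenance figure. The sulfur-enrichment factor multiplies
the relative abundance of every precursor whose formula contains S, then
the whole composition is re-normalized, so raising it strictly increases
sulfur atoms per gram of biomass (tested).

## Quality control

Balance checking parses formulas, sums coefficient-weighted element maps
and charges, and reports balanced / imbalanced / unverifiable. Exchange
and biomass reactions are exempt (inherently unbalanced boundary drains);
a missing formula or charge makes a reaction *unverifiable*, never
balanced by default; proton and water imbalances are reported like any
other element, with no silent auto-balancing. Connectivity is the number
of reactions in which a metabolite participates, by default over metabolic
reactions only (whether transports belong in that count is genuinely
ambiguous; the scope is an argument). Dead-end detection is bounds-aware:
a reversible reaction produces and consumes everything it touches, a
fixed-zero reaction neither. Gap filling is a MILP — one binary indicator
per pool reaction gating its bounds, a growth floor (default
0.05 h⁻¹), minimize the indicator sum — solved with HiGHS via
`scipy.optimize.milp`; its minimality is tested against exhaustive subset
search on pools up to 12 reactions.

## Media and essentiality conventions

A medium is a set of exchange-bound overrides; metabolites declared
"present" get the standard (−1, 1) mmol·gDW⁻¹·h⁻¹ window, unlisted
exchanges become secretion-only (0, 1000). Rich media opens every exchange
to (−1000, 1000), mimicking knockout experiments in broth. "Growth rate of
zero" is implemented as knockout/wild-type ratio < 1e-3 (configurable),
since LP optima return ~1e-12 noise rather than exact zeros. In ortholog
mapping (rows filtered at E-value ≤ 1e-6), a model gene with several
reference orthologs takes class Essential if any ortholog is essential —
the conservative resolution. Accuracy is computed over all shared genes;
shared genes whose orthologs lack a reference class are counted in the
denominator and reported as unmatched, which is what reconciles a
four-cell confusion table that sums to less than the shared-gene total.

## What the synthetic model emulates — and what it does not

The generator emits a ~60-reaction, two-compartment fungal-style network:
four carbon sources (glucose/ethanol/glycerol/succinate, 6/2/3/4 carbons)
lumped into pyruvate + NAD(P)H + ATP metabolism (P/O ratio 2, glycolytic
substrate-level ATP), assimilatory sulfate activation (sulfate → APS →
PAPS → sulfite → sulfide → cysteine → methionine / glutathione, choline
sulfate from PAPS, PAP recycled to AMP by a 3'-nucleotidase), the 4S chain
with a per-step FMNH2 cost of 1 (configurable) regenerated from NADH by a
flavin reductase, a biomass reaction assembled from the bundled synthetic
composition at 1,000 g/mol, and seeded decoy isozyme duplicates that give
the essentiality scan a nontrivial non-essential class.

Modelling assumptions worth knowing (the toy's manifest):

* **Formulas are simplified but self-consistent** (DBT = C12H8S, each
  oxidation adds one O; NADH = NAD + H2 bookkeeping), so balance checks
  are meaningful without real thermodynamics. Every non-exchange reaction
  is asserted balanced at generation time. O2 participation in the
  oxidation steps is included for realism but is an assumption; the
  surplus hydrogens of configurable flavin costs leave as water.
* **2-HBP is catabolized onward by default.** The organism class this toy
  emulates degrades aromatic compounds; the toy's only disposal route for
  2-HBP is an NADH-consuming ring monooxygenase whose product is
  secreted, and free 2-HBP secretion is closed. This is what gives the
  pathway end product its *positive* shadow price: LP duality makes the
  price of any freely-secreted interior-flux metabolite exactly zero, so
  a positive end-product price and free secretion are mutually exclusive
  in one network. The titration procedure therefore blocks the downstream
  oxidation and opens secretion (`block_product_oxidation=True`),
  mirroring assays in which 2-HBP accumulates in the medium; the
  shadow-price analyses run the default network. Both behaviours are
  contract-tested.
* **PAP demand.** Biomass includes PAP and choline sulfate (gated together
  by `pap_in_biomass`), making PAP the essential product of the sulfate
  activation branch; PAPS reductase is modeled reversible so that supplied
  PAP plus DBT-derived sulfite can regenerate PAPS. Feeding PAP also has
  genuine salvage value (PAP → AMP), so the bypass design can exceed
  wild-type growth — the engineering hypothesis the scenario encodes.
* **Not emulated:** real metabolite panels or compartmentalization beyond
  c/e, kinetic regulation, substrate toxicity, melanin/carotenoid
  chemistry beyond a named pigment precursor, and any numeric fidelity to
  a published organism-scale reconstruction. Passing tests on the toy
  demonstrate correctness of the *methods* under the toy's structure, not
  biological claims about any real strain; real-model analyses should go
  through the workbook parser.

The bundled composition (45% protein, 25% carbohydrate, 12% lipid, 10%
nucleic acid, 5% cofactor pool, 3% pigment; sulfur enrichment 1.2) is an
illustrative fungal-like composition, chosen once for realism, not a
measured composition of any organism.

## Numerical choices and degenerate inputs

Solver tolerances 1e-9; balance tolerance 1e-9; essentiality ratio
threshold 1e-3; gap-fill growth floor 0.05 h⁻¹; degeneracy flag threshold
1e-4; lexicographic pinning slack 1e-8·max(1,|Z*|). Empty GPR = always
active. Empty medium = everything secretion-only (growth 0). Reactions
with coefficients that cancel to zero are dropped from parsed equations.
Ties in gap filling (several minimum sets) resolve to whichever optimal
MILP vertex HiGHS reports; only cardinality is contractual. Problem sizes
in the tests (≤8-reaction random LPs for vertex-enumeration oracles,
≤12-reaction gap-fill pools, a ~60-reaction toy, a 1,215-gene synthetic
reference) were chosen so each oracle is exhaustive and the whole suite
runs in seconds on one core.

## Known limitations

No FVA, pFBA, MOMA or dynamic FBA; no thermodynamic or flux-coupling
analysis; no automated reconstruction from annotation; no formula
inference. Dual-based rankings (e.g. most-expensive sulfur metabolites)
inherit the degeneracy caveat above and should be read with the interval
diagnostics when applied to large real models.
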