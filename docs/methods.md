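# Methods

## Network model and conventions

A network is an ordered collection of metabolites and reactions over a
compartment registry. Twelve compartment codes are pre-registered —
c (cytosol), d (stroma), g (Golgi), v (vacuole), w (cell wall),
x (peroxisome), m (mitochondria), n (nucleus), r (endoplasmic reticulum),
u (unknown), plus e and j with placeholder names (both codes appear in
published plant-GEM compartment lists without a stated definition).
Additional codes may be declared in a `compartments.tsv` header file.

The metabolite id's `_<code>` suffix is authoritative for compartment
assignment; a conflicting declared compartment is a validation error rather
than being silently reconciled. Stoichiometric coefficients are stored as
exact rationals (`fractions.Fraction`) so that write→read round trips are
identities coefficient-by-coefficient; the stoichiometric matrix used by
the LP layer is a float sparse matrix built from those rationals.

Structural conventions:

- *exchange reaction*: exactly one metabolite in the stoichiometry
  (boundary uptake/secretion);
- *transport reaction*: participating metabolites span ≥ 2 compartment
  codes;
- *reversible*: `lower_bound < 0 < upper_bound`; unspecified bounds default
  to ±1000 (reversible) or 0..1000 (forward-only) flux units;
- `sparsity_percent` is **truncated** (not rounded) to 3 decimals; this
  matches how published genome-scale sparsity figures are conventionally
  printed (e.g. a matrix with 8361 non-zeros among 2,760,714 entries, i.e.
  0.302857%, reports as 0.302).

SBML (Level 3) ingestion is read-only: species map to metabolites
(`M_`/`R_` prefixes stripped), fbc flux-bound parameters are honored when
present, otherwise the reversibility flag selects the default bounds.

## Gap classification

All flux questions are answered by linear programs over the steady-state
polytope `{v : S·v = 0, lb ≤ v ≤ ub}`, solved with HiGHS via
`scipy.optimize.linprog`.

*Producibility* of metabolite m adds a temporary sink column (capacity
capped at 1 so the LP is always bounded) and asks whether the maximum sink
flux exceeds the tolerance. The implementation batches this: one sink per
undecided metabolite, maximizing the summed sink flux and settling every
metabolite whose sink is active, iterating until the optimum stalls. If a
degenerate optimum spreads flux below the per-sink tolerance while the
total is positive, the remaining metabolites are settled with individual
LPs, so the batched result equals the one-LP-per-metabolite definition.

Classes:

- **root no-production** — no reaction can produce the metabolite in any
  direction its bounds permit (purely topological; reversible reactions
  count as producers on either side, gated by their bounds);
- **downstream no-production** — topologically producible but failing the
  producibility LP;
- **root / upstream no-consumption** — the mirror classes with the sink
  replaced by a source (upstream no-consumption is implemented as the exact
  consumption-side analogue of downstream no-production, which published
  gap-find discussions name but do not define);
- **blocked reaction** — both FVA extrema have |value| ≤ tol, computed with
  every exchange opened to symmetric ±1000 bounds so that medium choices do
  not masquerade as structural blocks. An LP failure flags the reaction
  indeterminate instead of silently blocked.

A boolean reachability fixpoint from exchange-touched seed metabolites is
available as a fast pre-filter; metabolites it cannot reach are guaranteed
non-producible, but the converse does not hold (reachability ignores flux
balance), so it never replaces the LP.

Default tolerance: 1e-9 on LP optima, chosen an order of magnitude above
HiGHS' default feasibility tolerances so solver noise cannot flip a
classification on the integer-valued test networks.

## Gap filling

Candidates are first translated into the network nomenclature through an
alias table ((namespace, external id) → internal id, functional by
construction); the internal compound id then gains the candidate's target
compartment suffix. Unmapped candidates are skipped with a log entry by
default (`policy="fail"` raises listing every unmapped key), since
literature-derived candidates often lack database identifiers.

Integration is a greedy loop: every remaining candidate is tentatively
added and scored by the resulting production-gap count (the cheap
production-side classification only; the blocked-reaction scan runs once
per accepted iteration). The best candidate is accepted when it strictly
reduces the gap count — ties broken lexicographically on reaction id, so
the loop is deterministic — and the loop ends at zero gaps, no improving
candidate, or `max_iter`. A best candidate that would *increase* the count
is recorded under `rejected_candidates`. This deliberately approximates a
manual curation cycle; it makes no claim of minimality (no parsimony/ILP
objective), and a candidate set whose benefit only appears in combination
will not be found.

Delta accounting defines "active reactions" as non-blocked under the FVA
scan, so closing a gap typically adds 2 to the active count per planted
gap: the accepted candidate itself plus the demand reaction it unblocks.

## EC coverage and KO summaries

EC matching compares the four dot-separated fields with `-` as a wildcard
on either side (`2.3.1.-` matches `2.3.1.16`); malformed EC strings are
validation errors naming the offending entry. Coverage output preserves
pathway-spec order, one row per entry. KO summaries count distinct genes
per functional category; a gene whose KOs span several categories counts
once in each, malformed KO tokens are skipped with a warning.

## FBA and FVA

`fba_optimize` maximizes one reaction's flux; only the objective value is
canonical (LP degeneracy makes the flux vector non-unique, so tests never
assert fluxes beyond feasibility). The result records the steady-state
residual `max |S·v|` and the solver identity. Scenarios are pure bound
overrides (e.g. photon/CO2/O2 exchange limits for photosynthesis-style
simulations), never structural edits. Biomass objectives are attached as
an irreversible reaction from a user-supplied component table; no default
biomass composition ships with the package, because plant biomass
coefficients are tissue-specific and inventing them would be worse than
requiring them.

## Mass spectrometry arithmetic

Element monoisotopic masses are fixed in code (C 12 exactly, H 1.00782503,
N 14.00307401, O 15.99491462, P 30.97376200, S 31.97207069, plus Na, Cl, K,
F), with the proton at 1.00727646 Da. These values reproduce published
4-decimal neutral-mass tables; the packaged 79-row leaf-extract table
agrees to the printed digit on 77 rows, and the two exceptions
(C17H20O3 printed 272.1413 vs computed 272.1412; C14H31N printed 213.2457
vs computed 213.2456) are one-unit printing discrepancies kept as printed
and asserted as such in the tests.

Adducts are singly charged; m/z = (M + Δ)/|z| with registry deltas derived
from the element table (e.g. [M+Na]+ uses Na − H + proton, identical to
Na − electron within 1e-8 Da). Electron mass on the chloride anion is
behind an off-by-default flag, matching the neutral-mass convention of
printed tables. ppm errors are signed: `1e6·(obs − theo)/theo`.

Annotation returns, per feature, every polarity-compatible
(library entry, adduct) pair within the ppm tolerance (default 10 ppm, a
standard Q-TOF setting), ranked by |ppm| with ties in library order.
Feature extraction/deconvolution from raw spectra and MS/MS interpretation
are out of scope; features enter as a table.

## Cytotoxicity

Two viability conventions are implemented and reported in the output
metadata, never silently corrected, because the printed form of the MTT
equation in some protocols is the complement of the ratio reading:
`ratio` (100·Abs_sample/Abs_control, the default — the only reading under
which "cytotoxicity = 100 − viability" produces high cytotoxicity at high
dose) and `printed_difference` (100·(Abs_control − Abs_sample)/Abs_control).
They sum to exactly 100 for any input. Controls aggregate by the mean of
the control wells of the (cell line, time) stratum; replicate spread is the
sample standard deviation (0 for a single replicate); no blank subtraction
by default (a `blank` hook exists). No IC50 fitting: the module summarizes
ranges, it does not fit curves.

## Synthetic generators

All generators run from `numpy.random.default_rng(seed)` and are
bit-reproducible per seed; emitted files are read back unchanged by the
corresponding loaders.

*Networks.* A connected uptake→chain→sink backbone (12 metabolites,
18 reactions, 3 exchanges by default) with forward shortcut reactions and
compartment switches controlling the transport fraction. Planted
pathologies sit on top of the backbone: a planted gap adds one branch
metabolite, a demand reaction, and a producing reaction that is removed
and emitted as the closing candidate — making the branch metabolite a root
no-production gap and the demand reaction blocked; a planted dead end adds
a reaction whose product nothing consumes (blocked by construction, no
production gap). What this does **not** emulate: mass-imbalanced reactions,
cofactor coupling, duplicated pathways, or thermodynamically infeasible
loops — so passing tests demonstrate correctness of the classification
machinery, not realism of any particular biological reconstruction.

*Features.* Planted features apply a registered adduct to a library
formula and perturb m/z by a relative Normal(0, ppm_noise_sd·1e-6) error,
with retention times uniform over the run and areas log-uniform; decoys are
uniform over the 70–1100 m/z acquisition window, rejected within 10 ppm of
any library adduct mass. To keep truth labels unambiguous, the planting
pool also collapses duplicate (formula, adduct) pairs and excludes pairs
lying within 10 ppm of a different polarity-matched pair — the packaged
library contains duplicate formulas and one formate-adduct degeneracy where
two distinct compounds differ by exactly the elements of formic acid.
Isotope patterns, in-source fragments, and intensity-dependent mass error
are not simulated.

*Plates.* Wells follow `Abs = control_abs / (1 + (c/EC50)^h)` plus
Gaussian noise (clipped at 0), over a geometric dilution series
(0.05 mg/mL, factor 2, 8 points by default, floor 0.000390625 mg/mL),
two exposure times, and configurable replicates. Defaults (EC50 0.02 mg/mL,
Hill slope 2, control absorbance 1.0) place the transition inside the
dilution window, consistent with extracts showing 50–90% cytotoxicity over
0.0125–0.05 mg/mL. Plate-position effects and edge evaporation are not
modelled.

## Verification strategy and problem sizes

- Producibility and FBA are checked against an exact rational two-phase
  simplex (Bland's rule, `fractions.Fraction`) implemented in the test
  suite with no shared code or solver, and against COBRApy/GLPK as a third
  formulation. The standing benchmark: 200 random ≤8-reaction networks,
  every metabolite, 100% decision agreement; 100 random networks for
  dual-solver FBA optima within 1e-6.
- Gap-filling recovery runs 50 seeded networks (8-metabolite backbone,
  1–5 planted gaps) and requires exact closure counts and delta
  accounting.
- Annotation recovery plants 1000 features at 3 ppm noise against the
  packaged 79-compound library with a 10 ppm tolerance (>99% top-hit
  recovery; exact recovery with zero ppm error at zero noise).
- Topology arithmetic is exercised on a deterministically constructed
  1314×2101 network with exactly 8361 non-zeros.

These sizes are the package's benchmark conditions; anything larger is a
matter of solver throughput, not algorithmic change.

## Known limitations

- No MILP formulation of gap finding, no loopless/thermodynamic
  constraints, no parsimonious FBA, no gene-deletion scans.
- Greedy gap filling is order-dependent in principle (determinism comes
  from the tie-break, not from optimality).
- Charge/mass balance of reactions is not validated.
- Annotation is m/z-only (identification confidence level 3 at best);
  MS/MS confirmation is upstream tooling.
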