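# gemcurate

Curation and contextualization toolkit for compartmentalized genome-scale
metabolic reconstructions (GEMs), aimed at plant systems-biology workflows
that combine a draft reconstruction with untargeted LC-QTOF-MS metabolomics
and cell-based cytotoxicity assays.

A draft GEM assembled from automated annotation pipelines is rarely usable
as-is: it contains metabolites that cannot be produced or consumed at steady
state and reactions that can never carry flux. `gemcurate` provides the
machinery to diagnose those pathologies, close them iteratively with
candidate reactions mapped into a unified (ModelSEED-style) nomenclature,
and evaluate the result — plus the two experimental contextualization
stages that typically accompany such a reconstruction: annotation of LC-MS
molecular features by accurate mass, and dose–response viability summaries
from MTT plates.

## What it computes

**Network core.** A network is a set of metabolites `m` (id suffixed with a
one-letter compartment code, e.g. `cpd00001_c`) and reactions with signed
stoichiometric coefficients, flux bounds and optional GPR/EC annotations.
The stoichiometric matrix *S* (metabolites × reactions) yields topology
metrics: dimensions, non-zero count, sparsity, transport-reaction count
(reactions spanning ≥ 2 compartments).

**Gap finding.** A metabolite is *producible* when the LP

maximize s  s.t.  S·v − s·e_m = 0,  lb ≤ v ≤ ub,  0 ≤ s ≤ 1

attains an optimum above tolerance (production routed into a temporary
sink). Metabolites no reaction can produce in any bound-permitted direction
are *root no-production* gaps; producible-in-topology but LP-infeasible
metabolites are *downstream no-production* gaps; the consumption-side
classes are defined symmetrically. A reaction is *blocked* when its
flux-variability range over the steady-state polytope (all exchanges
opened) is {0}.

**Gap filling.** Candidate reactions from external databases or literature
are alias-mapped into the network's namespace, then integrated greedily:
each iteration adds the candidate that most reduces the production-gap
count (ties broken lexicographically), re-classifies, and stops when gaps
reach zero, no candidate helps, or an iteration cap is hit. Candidates
that would increase the gap count are rejected and logged.

**FBA / FVA.** Classical flux balance analysis — maximize an objective
flux (e.g. a biomass drain) subject to `S·v = 0` and bounds — with scenario
bound-overrides, plus per-reaction flux variability and active/blocked
percentages.

**LC-MS annotation.** Neutral monoisotopic masses from elemental formulas
(fixed isotope mass table), adduct m/z transforms ([M+H]+, [M−H]−, [M+Na]+,
[M+HCOOH−H]−, [M+Cl]−, and water-loss variants), signed ppm errors
`1e6·(obs − theo)/theo`, tolerance-bounded feature annotation ranked by
|ppm|, relative-area filtering, and the collision-energy ramp
`CE = 3.6·(m/z)/100 + 4.8`.

**Cytotoxicity.** MTT viability per (cell line, concentration, exposure
time) stratum from 595 nm absorbances, under two conventions
(`ratio` = 100·Abs_sample/Abs_control, default, and its exact complement
`printed_difference`), with cytotoxicity = 100 − viability and geometric
dilution-series helpers.

**Synthetic data.** Seeded generators produce networks with planted gaps
and dead ends (with the closing reactions as ground truth), feature tables
built by applying adduct transforms plus ppm-scale Gaussian noise to a
compound library, and MTT plates following a Hill dose–response — enough to
score every pipeline stage without external data.

A 79-compound C. sativa leaf-extract annotation table (name, formula,
printed neutral mass, adduct, polarity, confidence level, relative area) is
packaged as a reference fixture and compound library.

## Worked example

Generate a 12-metabolite backbone network with two planted production gaps,
inspect it, and close the gaps with the generator's own candidate pool:

```
$ gem-curate simulate network --spec netspec.json --out net --seed 7   # {"planted_gaps": 2}
$ gem-curate gapfind --network net
{ ... "counts": {"allGaps": 2, "rootGaps": 2, "downstreamGaps": 0} }
$ gem-curate gapfill --network net --candidates candidates.tsv --out net_curated
{
  "iterations": [
    {"added": ["rxn90000"], "gaps_before": 2, "gaps_after": 1,
     "blocked_before": 2, "blocked_after": 1},
    {"added": ["rxn90001"], "gaps_before": 1, "gaps_after": 0,
     "blocked_before": 1, "blocked_after": 0}
  ],
  "delta_active_reactions": 4,
  "delta_metabolites": 0,
  ...
}
```

Both planted gaps are root no-production metabolites (`rootGaps: 2`); each
accepted candidate closes one gap and unblocks the demand reaction behind
it, so four reactions in total become active while no new metabolites are
introduced.

Mass arithmetic on the library side:

```python
>>> from gemcurate.metabolomics import monoisotopic_mass, adduct_mz, collision_energy
>>> m = monoisotopic_mass("C26H28O6")          # cannflavin A
>>> print(f"{m:.4f}")
436.1886
>>> print(f"{adduct_mz(m, '[M+H]+'):.4f}")     # protonated ion
437.1959
>>> print(f"{collision_energy(437.1959):.1f}") # ramped MS/MS energy, eV
20.5
```

436.1886 Da is the neutral monoisotopic mass of the flavonoid; its
protonated ion is targeted for MS/MS at ~20.5 eV under the linear
collision-energy ramp.

## Layout

- `src/gemcurate/network.py` — network types, tabular/SBML I/O, *S* matrix,
  topology metrics
- `src/gemcurate/gaps.py` — producibility LPs, gap classes, blocked scan
- `src/gemcurate/curation.py` — alias tables, gap filling, EC coverage, KO
  summaries
- `src/gemcurate/fba.py` — FBA, FVA, biomass attachment, scenarios
- `src/gemcurate/metabolomics.py` — masses, adducts, ppm annotation
- `src/gemcurate/cytotox.py` — MTT viability and dilution series
- `src/gemcurate/synthetic.py` — seeded generators with ground truth
- `src/gemcurate/pipeline.py`, `cli.py` — end-to-end `gem-curate` driver
- `docs/methods.md` — modelling assumptions, conventions, limitations
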