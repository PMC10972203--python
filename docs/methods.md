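# Methods

## Model representation and solving

A GEM is an ordered reaction list over an ordered metabolite list with
flux bounds (mmol·gDW⁻¹·h⁻¹), boolean GPR rules over gene identifiers,
declared compartments and one biomass objective reaction. Conventions
fixed once and enforced everywhere:

* reversibility is encoded purely by bounds (`lb < 0`), never a flag;
* an exchange reaction is a boundary reaction with exactly one
  metabolite; uptake is negative flux, secretion positive;
* a transport reaction is one whose metabolites span compartments.

FBA solves `max/min v_obj  s.t.  S·v = 0, lb ≤ v ≤ ub` with HiGHS via
scipy. Returned solutions are checked to a mass-balance residual of
1e−6 and bound violations of 1e−9 (both configurable); solver failures
propagate as explicit statuses, never as silent zeros. GPR parsing and
evaluation use cobrapy's GPR machinery; cobrapy also backs SBML-FBC
reading/writing and serves as an independent FBA cross-check in the
test suite. SBML without explicit FBC bounds is rejected (naming the
reaction) rather than silently defaulted. The JSON dialect mirrors the
GEM type field-for-field and stores no derived structure.

## Reference GEM integration

Catalogue validation collapses duplicate gene ids by KO-set union and
drops malformed KO tokens, reporting both. KO→reaction translation uses
an offline two-column table; unmapped KOs are reported, not fatal (a
live-API fetch is deliberately out of the core for deterministic
builds). Integration attaches, to each model reaction whose KEGG
reaction id is hit by catalogue genes, the OR-join of those genes —
isozyme semantics, since catalogue genes are non-redundant
representatives rather than complex subunits. Pre-existing GPRs are
replaced (originals preserved in the report); stoichiometry, bounds and
metabolites are never touched; integration is idempotent.

## Scoring

Reaction state per MSP: the GPR evaluated with the MSP's genes present
(`boolean`, default — an AND complex needs all subunits) or presence of
any GPR gene (`any_gene`). Reactions without a GPR have state 0.

Frequencies average states over MSPs sharing a taxon at each of genus,
family, order, class, phylum. `unclassified` lineage entries never
pool — each such MSP is a singleton group per level — to avoid
artefactual frequency inflation. The score adds the state to the
across-level mean of the five frequencies by default; a single-level
mode is first-class (`freq_mode="genus"`, etc.) because either reading
of "frequency" is defensible. Per level, the threshold is the lowest
non-zero frequency; an all-zero level is an error (threshold
undefined).

## Species-GEM generation

Diet constraining sets exchange lower bounds to −uptake for diet
entries (addressable by exchange id, metabolite id with or without
compartment suffix, or KEGG compound id), closes all other uptakes,
leaves secretion untouched, and always opens acetate and lactate at
`default_carbon_uptake` (10 mmol·gDW⁻¹·h⁻¹, configurable) as universal
bacterial carbon sources. Unmatched diet entries warn.

Generation, for MSP *m* with biomass fraction *f* (default 0.5 of the
reference optimum *Z\** under the generation diet; the threshold is a
free parameter of the method, recorded in provenance):

1. target = *f·Z\**; candidates are all reactions except biomass and
   exchanges (exchanges are boundary/diet conditions, not gene-encoded
   content; unused ones are removed later, in tuning);
2. candidates are visited in ascending (score, frequency, reaction id).
   State-0 candidates — reactions the species' genes do not support —
   are removed outright. State-1 candidates at or below the genus
   threshold are removed only if biomass stays at target; state-1
   candidates above it are never removable;
3. if the model is below target, removed reactions are re-added in
   gap-fill order: genus first and then outward (within a level only
   reactions whose level frequency clears that level's threshold,
   descending frequency), GPR-less reactions next, and finally a
   last-resort *fallback* tier for reactions with no taxonomic support
   at any level — without it a target reachable by the full reference
   could be unreachable, because a reaction absent from the species'
   whole lineage is gated out of every taxonomy tier. A backward pass
   then discards re-additions that turned out unnecessary;
4. every retained re-addition is recorded with its category
   (closest_level / further_level(L) / no_gpr / fallback) and the
   percentages are reported against the final reaction count.

All tie-breaks are lexicographic, making generation deterministic:
identical inputs give byte-identical model files. Pruning is a single
pass with post-hoc gap-fill, not iterated to convergence.

Tuning iterates to a fixed point: exchanges whose metabolite no other
reaction uses are dropped; dead-end metabolites (cannot be both
produced and consumed given bound directions) are dropped together
with their adjacent reactions — such reactions are provably flux-zero
at steady state, so the optimum cannot decrease. Compartment
annotations are completed, gap-fill percentages recomputed, and
biomass feasibility re-verified; a tuning pass that breaks the target
raises instead of returning a degraded model.

## Microbiome metrics

Detection is abundance strictly above 0 (configurable). Abundances are
renormalized per sample over detected MSPs, making the reactobiome a
proper expectation: `CPF(r, s) = 500·Σᵢ a′(i, s)·member(i, r)` — the
expected number of carriers of r among 500 cells drawn by abundance —
bounded by 500 and attaining it exactly when every detected MSP carries
r. Relative reaction abundance renormalizes the same weighted profile
to column sum 1. Richness counts pool reactions carried by at least one
detected MSP; it is scale-invariant and monotone under added MSPs.

iRSE uses the one-sided upper-tail hypergeometric p-value (`P(X ≥ k)`,
overrepresentation) per pathway against the pool universe, BH-adjusted;
pathways with no pool overlap are skipped and reported. Group testing
defaults to the unpaired two-sample rank-sum (Mann–Whitney) comparison
between independent case and control samples with BH FDR; a paired
signed-rank mode (`paired=True`) exists for matched designs. Reactions
constant across all samples are flagged with p = 1 rather than tested.

## Community assembly

Members with zero abundance are dropped; the rest renormalize to sum 1.
Member reactions and non-extracellular metabolites are prefixed with
the species name, so the community S-matrix is block-diagonal across
species except for shared rows. Extracellular metabolites map to
species-neutral lumen `[lu]` metabolites keyed by KEGG compound id
(falling back to the metabolite id without its compartment suffix;
conflicting formulas under one key are an error). Member exchange
reactions are rewired into transports between the member's private
extracellular metabolite and the shared lumen metabolite — keeping them
as per-member exchanges would let uptake bypass the dietary bounds.
One reversible boundary exchange per lumen metabolite represents the
`[lu]`↔`[fe]` connection, with `[fe]` the declared fecal/dietary
boundary pool; diets constrain these exactly as for a single model.
The community biomass reaction consumes each member's biomass product
(added explicitly if the member's biomass reaction has no product) with
the renormalized abundance as coefficient, and is the objective — so a
single-member community is FBA-equivalent to the member itself, a
property asserted in the tests.

## Synthetic study conditions

The generator emulates, at desk scale, the inputs of a gut-metagenomics
GEM workflow. Defaults (the "demo community", seed 42): 2 phyla, 4
genera, 3 MSPs per genus (12 MSPs), 40 samples (20 control / 20 case),
five toy diets named after common dietary patterns (high-protein/
high-fiber × plant-based/omnivorous, average UK; compositions are
synthetic — each opens the six fixture nutrients at 5/10/15
mmol·gDW⁻¹·h⁻¹ in diet-specific patterns at a nominal 2000 kCal basis).

The generic model (≈45 reactions) has exchangeable nutrients with
transports, two-step parallel biosynthesis routes to three biomass
precursors (the last precursor has a single route, making its nutrient
transport a documented essential reaction), acetate/lactate salvage,
byproduct secretion, and self-contained alternative-assimilation (ALT)
reactions from core nutrients into core intermediates. Every
GPR-eligible reaction gets one KO and two isozyme genes; a few orphan
genes carry no KO. MSPs carry all core-reaction genes (probability 1)
and accessory reactions with genus structure: each accessory reaction
has one home genus (round-robin so every genus gets a share, ALTs
allotted separately), carried with probability 0.8 in the home genus
and 0.1 (= 0.8/8) elsewhere. Abundances are lognormal (per-MSP baseline
N(0,1), per-sample noise σ = 1.0 on the log scale), column-normalized;
in case samples the effect genus's MSPs are boosted 4-fold before
normalization. The pre-registered effect reactions are the effect
genus's ALT signature — ALTs are used because a species model always
retains them, so the genome-level contrast survives model
contextualization. All draws come from NumPy's PCG64 generator seeded
from `FixtureParams.seed`; outputs are byte-identical across runs and
platforms.

What the generator does *not* emulate: real pangenome incompleteness
(core genes are present in every MSP by construction, so the demo
rarely needs gap-filling — the gap-fill path is exercised by dedicated
toy fixtures), zero-inflated abundance profiles (every MSP is detected
in every sample, so richness is saturated in the demo), compositional
ecology, strain variation, and realistic network size. Passing tests
therefore certify the algorithms' contracts and calibration, not
biological conclusions about real communities.

## Numerical choices and degenerate inputs

Feasibility tolerance 1e−6, bound tolerance 1e−9, biomass-target slack
1e−9 (relative). Pruning/gap-fill tie-breaks as above. Empty samples
(no detected MSP) yield flagged all-zero metric columns with a warning.
An MSP gene outside the catalogue, a duplicate model id in a pool, a
non-positive reference optimum, and a lumen formula clash are all
explicit errors. Problem sizes throughout (demo pipeline, 200-fixture
scoring oracle, exhaustive N ≤ 25 enrichment enumeration, 200-label
permutation null, ≤ 12-reaction exhaustive minimality searches) were
chosen so the full test suite and the acceptance script each complete
in well under a minute on a single CPU.

## Known limitations

Biomass objectives for uncultured species are approximations borrowed
from the generic model rather than measured compositions. The pruning
order is greedy on scores; it guarantees feasibility and single-removal
local minimality (verified exhaustively on toys), not global minimality.
The scoring's `mean_over_levels` default is one of two defensible
readings of taxonomy-frequency aggregation; both are implemented and
the choice is logged per run. Thermodynamic constraints, flux
variability, and dynamic or spatial community simulation are out of
scope.
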