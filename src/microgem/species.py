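"""Diet constraining and species-specific GEM generation.

A species model is carved out of the diet-constrained reference GEM for
one MSP: reactions the species' genes do not support are pruned in
ascending reaction-score order, and biomass feasibility (a configurable
fraction of the reference optimum) is restored by gap-filling absent
reactions in taxonomy-proximity order — the closest level (genus) first,
highest frequency first within a level, reactions without any
gene-protein-reaction rule last. A tuning pass then strips unused
exchanges/transports and dead-end metabolites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .fba import max_objective, solve_fba
from .model import GEM, find_dead_end_metabolites
from .tables import TAXONOMY_LEVELS

#: Default uptake magnitude opened for the universal bacterial carbon
#: sources (acetate, lactate) under every diet, mmol/gDW/h.
DEFAULT_CARBON_UPTAKE = 10.0

#: KEGG compound ids for acetate and lactate.
CARBON_SOURCE_KEGG_IDS = ("C00033", "C00186")

#: Numerical slack when comparing biomass flux against the target.
TARGET_TOL = 1e-9

CLOSEST_LEVEL = TAXONOMY_LEVELS[0]  # genus


@dataclass(frozen=True)
class Diet:
    """Named uptake-bound set (positive magnitudes, mmol/gDW/h)."""

    name: str
    uptake_bounds: dict[str, float]
    kcal_basis: float = 2000.0

    def __post_init__(self) -> None:
        bad = [k for k, v in self.uptake_bounds.items() if v <= 0]
        if bad:
            raise ValueError(f"diet {self.name!r}: non-positive uptake magnitudes for {bad}")


@dataclass
class GapfillEntry:
    rxn_id: str
    category: str  # "closest_level" | "further_level(<L>)" | "no_gpr" | "fallback"
    frequency: float


@dataclass
class GapfillReport:
    """Per-reaction gap-fill record plus percentages of the final model."""

    entries: list[GapfillEntry] = field(default_factory=list)
    final_reaction_count: int = 0

    def _pct(self, predicate) -> float:
        if not self.final_reaction_count:
            return 0.0
        n = sum(1 for e in self.entries if predicate(e))
        return 100.0 * n / self.final_reaction_count

    @property
    def percent_closest_level(self) -> float:
        return self._pct(lambda e: e.category == "closest_level")

    @property
    def percent_further_levels(self) -> float:
        return self._pct(lambda e: e.category.startswith("further_level"))

    @property
    def percent_no_gpr(self) -> float:
        return self._pct(lambda e: e.category == "no_gpr")

    @property
    def percent_fallback(self) -> float:
        return self._pct(lambda e: e.category == "fallback")

    @property
    def percent_total(self) -> float:
        return self._pct(lambda e: True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.rxn_id, e.category, e.frequency) for e in self.entries],
            columns=["rxn_id", "category", "frequency"],
        )


@dataclass
class SpeciesGEM:
    """A pruned, gap-filled GEM for one MSP, with provenance."""

    gem: GEM
    msp_id: str
    source_model_id: str
    diet_name: str
    biomass_fraction: float
    reference_optimum: float
    gapfill: GapfillReport
    growth: float = 0.0

    @property
    def biomass_target(self) -> float:
        return self.biomass_fraction * self.reference_optimum


class InfeasibleSpeciesError(RuntimeError):
    """The biomass target is unreachable even with every reference reaction."""


# ---------------------------------------------------------------------------
# diet constraining
# ---------------------------------------------------------------------------

def _exchange_lookup(gem: GEM) -> dict[str, str]:
    """Keys under which each exchange reaction can be addressed by a diet."""
    lookup: dict[str, str] = {}
    for rxn in gem.exchange_reactions:
        met_id = next(iter(rxn.stoichiometry))
        met = gem.metabolite(met_id)
        keys = [rxn.rxn_id, met_id]
        base = met_id
        for suffix in (f"_{met.compartment}", f"[{met.compartment}]"):
            if base.endswith(suffix):
                base = base[: -len(suffix)]
        keys.append(base)
        if met.kegg_met_id:
            keys.append(met.kegg_met_id)
        for key in keys:
            lookup.setdefault(key, rxn.rxn_id)
    return lookup


def apply_diet(
    gem: GEM,
    diet: Diet,
    default_carbon_uptake: float = DEFAULT_CARBON_UPTAKE,
    carbon_source_ids: tuple[str, ...] = CARBON_SOURCE_KEGG_IDS,
) -> GEM:
    """Constrain exchange uptakes to a diet, returning a new model.

    Diet entries may address exchanges by reaction id, metabolite id
    (with or without compartment suffix) or KEGG compound id. All
    non-diet uptakes are closed (lower bound 0); secretion bounds are
    untouched. Acetate and lactate uptake is opened at
    ``default_carbon_uptake`` regardless of the diet, as universal
    bacterial carbon sources. Unmatched diet entries trigger a warning,
    never an error.
    """
    out = gem.copy()
    lookup = _exchange_lookup(out)
    uptake: dict[str, float] = {}
    unmatched = []
    for key, bound in diet.uptake_bounds.items():
        rxn_id = lookup.get(key)
        if rxn_id is None:
            unmatched.append(key)
        else:
            uptake[rxn_id] = max(uptake.get(rxn_id, 0.0), bound)
    for key in carbon_source_ids:
        rxn_id = lookup.get(key)
        if rxn_id is not None:
            uptake[rxn_id] = max(uptake.get(rxn_id, 0.0), default_carbon_uptake)
    for rxn in out.exchange_reactions:
        rxn.lower_bound = -uptake.get(rxn.rxn_id, 0.0)
    if unmatched:
        warnings.warn(
            f"diet {diet.name!r}: no matching exchange for {sorted(unmatched)}",
            stacklevel=2,
        )
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _biomass_with_disabled(gem: GEM, disabled: set[str]) -> float:
    """Biomass optimum with the given reactions' bounds closed to zero."""
    saved = {}
    for rid in disabled:
        rxn = gem.reaction(rid)
        saved[rid] = (rxn.lower_bound, rxn.upper_bound)
        rxn.lower_bound = rxn.upper_bound = 0.0
    try:
        return max_objective(gem)
    finally:
        for rid, (lb, ub) in saved.items():
            rxn = gem.reaction(rid)
            rxn.lower_bound, rxn.upper_bound = lb, ub


def generate_species_gem(
    ref_constrained: GEM,
    scores: pd.DataFrame,
    states: pd.DataFrame,
    freqs: dict[str, pd.DataFrame],
    thresholds: dict[str, float],
    tax: pd.DataFrame,
    msp_id: str,
    biomass_fraction: float = 0.5,
    diet_name: str = "",
) -> SpeciesGEM:
    """Prune the constrained reference down to one MSP's metabolism.

    Contract: (1) the biomass target is ``biomass_fraction`` times the
    reference optimum under the generation diet; (2) candidate reactions
    (all but biomass and exchange reactions) are visited in ascending
    (score, frequency, rxn_id) order — reactions the MSP's genes do not
    support (state 0) are removed outright, reactions with state 1 whose
    score does not clear the MSP's closest-level (genus) threshold are
    removed only if biomass stays at target, and state-1 reactions above
    that threshold are never candidates; (3) if pruning left the model
    below target, removed reactions are re-added in gap-fill order:
    closest taxonomy level first (descending frequency, eligibility gated
    by that level's threshold), then further levels, reactions without a
    GPR last; a backward pass then drops re-added reactions that turned
    out not to be needed. Ties break deterministically.
    """
    if not 0 < biomass_fraction <= 1:
        raise ValueError("biomass_fraction must be in (0, 1]")
    if msp_id not in scores.columns:
        raise KeyError(f"MSP {msp_id!r} not in score matrix")
    gem = ref_constrained.copy(model_id=f"{ref_constrained.model_id}__{msp_id}")
    biomass_id = gem.biomass_reaction_id
    zstar = max_objective(gem)
    if zstar <= 0:
        raise InfeasibleSpeciesError(
            f"reference optimum is non-positive under diet {diet_name!r}"
        )
    target = biomass_fraction * zstar
    tol = TARGET_TOL * max(1.0, abs(target))

    msp_scores = scores[msp_id]
    msp_states = states[msp_id]
    from .scoring import combined_frequency

    msp_freq = combined_frequency(freqs)[msp_id]
    closest_thr = thresholds[CLOSEST_LEVEL]

    candidates = []
    for rxn in gem.reactions:
        rid = rxn.rxn_id
        if rid == biomass_id or rxn.is_exchange or rid not in msp_scores.index:
            continue
        state = int(msp_states[rid])
        score = float(msp_scores[rid])
        if state == 1 and score > closest_thr:
            continue  # never a removal candidate
        candidates.append((score, float(msp_freq[rid]), rid, state))
    candidates.sort()

    disabled: set[str] = set()
    removed_order: list[str] = []
    for score, freq, rid, state in candidates:
        if state == 0:
            disabled.add(rid)
            removed_order.append(rid)
        else:
            disabled.add(rid)
            if _biomass_with_disabled(gem, disabled) >= target - tol:
                removed_order.append(rid)
            else:
                disabled.discard(rid)

    report = GapfillReport()
    if _biomass_with_disabled(gem, disabled) < target - tol:
        added = _gap_fill(
            gem, disabled, removed_order, freqs, thresholds, msp_id, target, tol
        )
        report.entries = added
        if _biomass_with_disabled(gem, disabled) < target - tol:
            raise InfeasibleSpeciesError(
                f"MSP {msp_id}: biomass target {target:.4g} unreachable even "
                f"after restoring all pruned reactions"
            )

    gem.remove_reactions(disabled, prune_metabolites=True)
    report.final_reaction_count = len(gem.reactions)
    sg = SpeciesGEM(
        gem=gem,
        msp_id=msp_id,
        source_model_id=ref_constrained.model_id,
        diet_name=diet_name,
        biomass_fraction=biomass_fraction,
        reference_optimum=zstar,
        gapfill=report,
    )
    sg.growth = max_objective(gem)
    assert sg.growth >= target - tol, "generation contract violated"
    return sg


def _gap_fill(
    gem: GEM,
    disabled: set[str],
    removed_order: list[str],
    freqs: dict[str, pd.DataFrame],
    thresholds: dict[str, float],
    msp_id: str,
    target: float,
    tol: float,
) -> list[GapfillEntry]:
    """Re-enable pruned reactions until the biomass target is met.

    Candidates are walked level by level outward from genus; within a
    level, only reactions whose level frequency clears that level's
    threshold are eligible, in descending frequency (ties by rxn_id).
    Reactions without a GPR come next, and a last-resort "fallback" tier
    admits removed reactions with no taxonomic support at any level (the
    MSP's whole lineage lacks them) so that the target is reachable
    whenever the full reference can reach it. After the target is
    reached, a backward pass over the additions (lowest priority first)
    drops any whose removal keeps the model at target.
    """
    sequence: list[tuple[str, str, float]] = []
    queued: set[str] = set()
    has_gpr = {rid: bool(gem.reaction(rid).gpr_rule) for rid in removed_order}
    for i, level in enumerate(TAXONOMY_LEVELS):
        level_freq = freqs[level][msp_id]
        cands = [
            (float(level_freq[rid]), rid)
            for rid in removed_order
            if has_gpr[rid]
            and rid not in queued
            and rid in level_freq.index
            and float(level_freq[rid]) >= thresholds[level]
        ]
        cands.sort(key=lambda t: (-t[0], t[1]))
        category = "closest_level" if i == 0 else f"further_level({level})"
        for freq, rid in cands:
            sequence.append((rid, category, freq))
            queued.add(rid)
    for rid in sorted(r for r in removed_order if not has_gpr[r] and r not in queued):
        sequence.append((rid, "no_gpr", 0.0))
        queued.add(rid)
    leftovers = [
        (max(float(freqs[level][msp_id].get(rid, 0.0)) for level in TAXONOMY_LEVELS), rid)
        for rid in removed_order
        if rid not in queued
    ]
    for freq, rid in sorted(leftovers, key=lambda t: (-t[0], t[1])):
        sequence.append((rid, "fallback", freq))

    added: list[tuple[str, str, float]] = []
    for rid, category, freq in sequence:
        disabled.discard(rid)
        added.append((rid, category, freq))
        if _biomass_with_disabled(gem, disabled) >= target - tol:
            break

    # backward pass: drop re-additions that are not actually needed
    kept: list[tuple[str, str, float]] = []
    for rid, category, freq in reversed(added):
        disabled.add(rid)
        if _biomass_with_disabled(gem, disabled) >= target - tol:
            continue  # not needed after all
        disabled.discard(rid)
        kept.append((rid, category, freq))
    kept.reverse()
    return [GapfillEntry(rid, category, freq) for rid, category, freq in kept]


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------

def tune_species_gem(sg: SpeciesGEM) -> SpeciesGEM:
    """Strip structurally unusable parts of a generated species model.

    Iterates to a fixed point: exchange reactions whose metabolite is
    used by no other reaction are removed, then dead-end metabolites
    (which force every adjacent reaction to zero flux) are removed along
    with those adjacent reactions. Compartment annotations are completed,
    gap-fill percentages are recomputed on the final reaction count, and
    biomass feasibility is re-verified — a tuning pass that breaks the
    target is a contract bug and raises.
    """
    gem = sg.gem.copy()
    biomass_id = gem.biomass_reaction_id
    changed = True
    while changed:
        changed = False
        usage: dict[str, int] = {}
        for rxn in gem.reactions:
            if rxn.is_exchange:
                continue
            for met in rxn.stoichiometry:
                usage[met] = usage.get(met, 0) + 1
        orphan_exchanges = [
            r.rxn_id
            for r in gem.exchange_reactions
            if r.rxn_id != biomass_id and not usage.get(next(iter(r.stoichiometry)), 0)
        ]
        if orphan_exchanges:
            gem.remove_reactions(orphan_exchanges, prune_metabolites=True)
            changed = True
            continue
        dead = set(find_dead_end_metabolites(gem))
        if dead:
            doomed = [
                r.rxn_id
                for r in gem.reactions
                if r.rxn_id != biomass_id and dead & set(r.stoichiometry)
            ]
            used = {m for r in gem.reactions if r.rxn_id not in doomed for m in r.stoichiometry}
            if doomed:
                gem.remove_reactions(doomed, prune_metabolites=True)
                changed = True
            elif dead - used:
                gem.metabolites = [m for m in gem.metabolites if m.met_id not in dead]
                gem.refresh()
                changed = True

    used_comps = {gem.metabolite(m).compartment for r in gem.reactions for m in r.stoichiometry}
    for comp in used_comps:
        gem.compartments.setdefault(comp, comp)
    gem.validate()

    target = sg.biomass_target
    growth = max_objective(gem)
    if growth < target - TARGET_TOL * max(1.0, abs(target)):
        raise RuntimeError(
            f"tuning broke biomass feasibility for {sg.msp_id}: "
            f"{growth:.6g} < target {target:.6g}"
        )
    final_ids = set(gem.reaction_ids)
    report = GapfillReport(
        entries=[e for e in sg.gapfill.entries if e.rxn_id in final_ids],
        final_reaction_count=len(gem.reactions),
    )
    return SpeciesGEM(
        gem=gem,
        msp_id=sg.msp_id,
        source_model_id=sg.source_model_id,
        diet_name=sg.diet_name,
        biomass_fraction=sg.biomass_fraction,
        reference_optimum=sg.reference_optimum,
        gapfill=report,
        growth=growth,
    )


def assess_growth(
    sg: SpeciesGEM,
    diets: list[Diet],
    default_carbon_uptake: float = DEFAULT_CARBON_UPTAKE,
) -> pd.DataFrame:
    """Biomass optimum of a species model under each diet.

    Returns a table indexed by diet name with ``growth_rate`` (>= 0,
    zero when infeasible) and a ``feasible`` flag carrying the solver
    verdict.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for diet in diets:
            constrained = apply_diet(sg.gem, diet, default_carbon_uptake)
            sol = solve_fba(constrained)
            rate = sol.objective_value if sol.optimal else 0.0
            rows.append((diet.name, max(rate, 0.0), sol.optimal))
    return pd.DataFrame(rows, columns=["diet", "growth_rate", "feasible"]).set_index("diet")
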