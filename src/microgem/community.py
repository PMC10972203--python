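"""Per-sample community GEM assembly.

Member species models are merged into one stoichiometric system: every
member reaction and intracellular/periplasmic metabolite is prefixed
with the species name (block-diagonal S across species), while each
member's extracellular metabolites connect through rewired exchange
reactions to shared, species-neutral metabolites in the intestinal
lumen compartment ``lu``. One boundary exchange per lumen metabolite
links ``lu`` to the fecal/dietary pool compartment ``fe``; diets
constrain uptake there exactly as for single models. The community
biomass reaction consumes each member's biomass product with the
member's renormalized abundance as stoichiometric coefficient and is
the community objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GEM, Metabolite, Reaction
from .species import DEFAULT_CARBON_UPTAKE, Diet, SpeciesGEM, apply_diet

LUMEN = "lu"
FECAL = "fe"

#: Compartment codes treated as extracellular when mapping member
#: metabolites to the shared lumen.
EXTRACELLULAR_CODES = ("e", "ext", "extracellular")


@dataclass
class CommunityGEM:
    """A merged per-sample model with shared [lu]/[fe] compartments."""

    gem: GEM
    sample_id: str
    members: list[str]
    abundances: dict[str, float]
    lumen_metabolites: list[str] = field(default_factory=list)
    biomass_metabolites: dict[str, str] = field(default_factory=dict)


def _lumen_key(met: Metabolite) -> str:
    """Species-neutral join key: KEGG compound id, else id sans compartment."""
    if met.kegg_met_id:
        return met.kegg_met_id
    base = met.met_id
    for suffix in (f"_{met.compartment}", f"[{met.compartment}]"):
        if base.endswith(suffix):
            return base[: -len(suffix)]
    return base


def build_community(
    members: list[SpeciesGEM | GEM],
    abundances: dict[str, float] | list[float],
    sample_id: str = "community",
) -> CommunityGEM:
    """Merge species models into one community model for a sample.

    Zero-abundance members are dropped and the rest renormalized to sum
    1. Each member's biomass reaction must (or is made to) produce a
    member biomass metabolite, which the community biomass reaction
    consumes with the renormalized abundance as coefficient.
    """
    gems: list[tuple[str, GEM]] = []
    for m in members:
        gem: GEM = getattr(m, "gem", m)
        name = getattr(m, "msp_id", None) or gem.model_id
        gems.append((name, gem))
    if isinstance(abundances, dict):
        ab = {name: float(abundances.get(name, 0.0)) for name, _ in gems}
    else:
        if len(abundances) != len(gems):
            raise ValueError("abundance list length must match member count")
        ab = {name: float(a) for (name, _), a in zip(gems, abundances)}
    if any(v < 0 for v in ab.values()):
        raise ValueError("negative abundances")
    gems = [(n, g) for n, g in gems if ab[n] > 0]
    if not gems:
        raise ValueError("no member with positive abundance")
    names = [n for n, _ in gems]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate member ids: {names}")
    total = sum(ab[n] for n in names)
    weights = {n: ab[n] / total for n in names}

    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    lumen_mets: dict[str, Metabolite] = {}  # key -> shared metabolite
    lumen_formula: dict[str, str] = {}
    biomass_mets: dict[str, str] = {}
    compartments = {LUMEN: "intestinal lumen", FECAL: "secreted bacterial and food-derived metabolites"}

    for name, gem in gems:
        rename: dict[str, str] = {}
        for met in gem.metabolites:
            if met.compartment in EXTRACELLULAR_CODES:
                # register the species-neutral lumen counterpart; the
                # member's own extracellular metabolite stays private and
                # is connected through its rewired exchange reaction
                key = _lumen_key(met)
                if key in lumen_formula:
                    if met.formula and lumen_formula[key] and met.formula != lumen_formula[key]:
                        raise ValueError(
                            f"lumen metabolite clash for key {key!r}: formula "
                            f"{met.formula!r} vs {lumen_formula[key]!r}"
                        )
                    if met.formula and not lumen_formula[key]:
                        lumen_formula[key] = met.formula
                else:
                    shared = Metabolite(
                        met_id=f"{key}_{LUMEN}",
                        formula=met.formula,
                        kegg_met_id=met.kegg_met_id,
                        compartment=LUMEN,
                    )
                    lumen_mets[key] = shared
                    lumen_formula[key] = met.formula
                    metabolites.append(shared)
            new_id = f"{name}_{met.met_id}"
            comp = f"{name}_{met.compartment}"
            compartments.setdefault(comp, f"{met.compartment} of {name}")
            metabolites.append(
                Metabolite(new_id, met.formula, met.kegg_met_id, comp)
            )
            rename[met.met_id] = new_id

        biomass_product = None
        biomass_rxn = gem.reaction(gem.biomass_reaction_id) if gem.biomass_reaction_id else None
        for rxn in gem.reactions:
            stoich = {rename[m]: c for m, c in rxn.stoichiometry.items()}
            lb, ub = rxn.lower_bound, rxn.upper_bound
            if rxn.is_exchange:
                met_id = next(iter(rxn.stoichiometry))
                if gem.metabolite(met_id).compartment in EXTRACELLULAR_CODES:
                    # rewire: boundary exchange -> transport with the lumen.
                    # Uptake (negative exchange flux) becomes drawing the
                    # shared lumen metabolite into the member's pool.
                    key = _lumen_key(gem.metabolite(met_id))
                    lu_id = lumen_mets[key].met_id
                    # original: {e_met: -1}; rewired: e_met <- lu_met
                    coef = rxn.stoichiometry[met_id]
                    stoich = {rename[met_id]: coef, lu_id: -coef}
                    lb, ub = -1000.0, 1000.0
            new_rxn = Reaction(
                rxn_id=f"{name}_{rxn.rxn_id}",
                name=rxn.name or rxn.rxn_id,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr_rule="",
                kegg_rxn_id=rxn.kegg_rxn_id,
                subsystem=rxn.subsystem,
            )
            reactions.append(new_rxn)
            if biomass_rxn is not None and rxn.rxn_id == biomass_rxn.rxn_id:
                products = [m for m, c in new_rxn.stoichiometry.items() if c > 0]
                biomass_product = products[0] if products else None
        if biomass_product is None:
            # give the member biomass reaction an explicit biomass product
            bm = Metabolite(f"{name}_biomass", compartment=f"{name}_c")
            compartments.setdefault(f"{name}_c", f"c of {name}")
            metabolites.append(bm)
            for rxn in reactions:
                if rxn.rxn_id == f"{name}_{gem.biomass_reaction_id}":
                    rxn.stoichiometry[bm.met_id] = 1.0
            biomass_product = bm.met_id
        biomass_mets[name] = biomass_product

    # lumen <-> fecal boundary exchanges, one per lumen metabolite
    for key in sorted(lumen_mets):
        met = lumen_mets[key]
        reactions.append(
            Reaction(
                rxn_id=f"EX_{key}_{FECAL}",
                name=f"{key} lumen-fecal exchange",
                stoichiometry={met.met_id: -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
            )
        )

    community_biomass = Reaction(
        rxn_id="community_biomass",
        name="community biomass",
        stoichiometry={biomass_mets[n]: -weights[n] for n in names},
        lower_bound=0.0,
        upper_bound=1000.0,
    )
    reactions.append(community_biomass)

    gem = GEM(
        model_id=f"community_{sample_id}",
        reactions=reactions,
        metabolites=metabolites,
        genes=[],
        biomass_reaction_id="community_biomass",
        compartments=compartments,
    )
    gem.validate()
    return CommunityGEM(
        gem=gem,
        sample_id=sample_id,
        members=names,
        abundances=weights,
        lumen_metabolites=[m.met_id for m in lumen_mets.values()],
        biomass_metabolites=biomass_mets,
    )


def apply_diet_to_community(
    cm: CommunityGEM,
    diet: Diet,
    default_carbon_uptake: float = DEFAULT_CARBON_UPTAKE,
) -> CommunityGEM:
    """Constrain the community's [lu]/[fe] boundary exchanges to a diet.

    Dietary uptake bounds are applied to the lumen-fecal exchanges
    exactly as :func:`~microgem.species.apply_diet` applies them to a
    single model's exchanges (non-diet uptake closed, acetate/lactate
    open at the default carbon uptake).
    """
    constrained = apply_diet(cm.gem, diet, default_carbon_uptake)
    return CommunityGEM(
        gem=constrained,
        sample_id=cm.sample_id,
        members=list(cm.members),
        abundances=dict(cm.abundances),
        lumen_metabolites=list(cm.lumen_metabolites),
        biomass_metabolites=dict(cm.biomass_metabolites),
    )
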