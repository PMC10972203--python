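"""Deterministic generators for every input the pipeline consumes.

These emulate, at toy scale, the inputs of a gut-metagenomics GEM
workflow: a generic metabolic model with KEGG-style identifiers, a
non-redundant gene catalogue with KO annotations, MSP gene sets with
planted taxonomic structure (genera share accessory reactions), diets,
and an MSP x sample abundance table with an optional planted
case/control contrast. All draws come from ``numpy.random.default_rng``
(PCG64) seeded from ``FixtureParams.seed``, so outputs are byte-identical
across runs and platforms.

The default parameters define the canonical "demo community" test bed:
2 phyla, 4 genera, 12 MSPs, 40 samples (20 case / 20 control), five toy
diets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, KoReactionMap
from .model import GEM, Metabolite, Reaction
from .species import Diet
from .tables import TAXONOMY_LEVELS


@dataclass(frozen=True)
class FixtureParams:
    """Knobs of the synthetic study; defaults are the demo community."""

    seed: int = 42
    n_phyla: int = 2
    n_genera: int = 4
    msps_per_genus: int = 3
    n_nutrients: int = 6
    n_precursors: int = 3
    routes_per_precursor: int = 2
    n_byproducts: int = 2
    n_extra_accessory: int = 12
    n_orphan_genes: int = 5
    #: minimum fraction of GPR-eligible reactions treated as core
    #: (present in every MSP); the structural core (sole-route chains and
    #: their transports) is never demoted.
    core_reaction_fraction: float = 0.4
    #: probability an MSP carries an accessory reaction in its genus
    #: signature; out-of-signature carriage probability is 1/8 of this.
    accessory_presence_prob: float = 0.8
    n_samples: int = 40
    #: sd of the per-sample lognormal noise on log-abundance
    lognormal_sigma: float = 1.0
    #: multiplicative abundance boost of the effect genus in case samples
    effect_size: float = 4.0
    effect_genus: str = "genus_1"

    def __post_init__(self) -> None:
        if not 0 <= self.accessory_presence_prob <= 1:
            raise ValueError("accessory_presence_prob must be in [0, 1]")
        if not 0 <= self.core_reaction_fraction <= 1:
            raise ValueError("core_reaction_fraction must be in [0, 1]")
        for name in ("n_phyla", "n_genera", "msps_per_genus", "n_samples", "n_nutrients", "n_precursors"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEMO_PARAMS = FixtureParams()

ACETATE = "C00033"
LACTATE = "C00186"


def _nutrient_kegg(i: int) -> str:
    return f"C9{i + 1:04d}"


def sole_route_transport(params: FixtureParams) -> str:
    """The documented essential transport: the last precursor has a single
    synthesis route, so the transport of that route's nutrient is
    essential for biomass."""
    nut = _nutrient_kegg((params.n_precursors - 1) * params.routes_per_precursor % params.n_nutrients)
    return f"T_{nut}"


def make_generic_model(params: FixtureParams = DEMO_PARAMS) -> GEM:
    """A small, FBA-feasible generic model with KEGG-style identifiers.

    Topology: ``n_nutrients`` exchangeable nutrients with transports;
    each of ``n_precursors`` biomass precursors is reachable through
    ``routes_per_precursor`` parallel two-step routes from distinct
    nutrients (the last precursor has a single route, giving a documented
    essential transport); acetate and lactate with salvage routes;
    byproduct secretion; random extra accessory conversions; a biomass
    reaction consuming all precursors and a biomass sink.
    """
    rng = np.random.default_rng(params.seed)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def add_pair(kegg: str, formula: str = "") -> None:
        mets.append(Metabolite(f"{kegg}_e", formula, kegg, "e"))
        mets.append(Metabolite(f"{kegg}_c", formula, kegg, "c"))

    nutrient_ids = [_nutrient_kegg(i) for i in range(params.n_nutrients)]
    for kegg in nutrient_ids:
        add_pair(kegg, "C6H12O6")
    add_pair(ACETATE, "C2H4O2")
    add_pair(LACTATE, "C3H6O3")
    byproduct_ids = [f"C97{i + 1:03d}" for i in range(params.n_byproducts)]
    for kegg in byproduct_ids:
        add_pair(kegg, "CH2O2")

    exchangeable = nutrient_ids + [ACETATE, LACTATE] + byproduct_ids
    for n, kegg in enumerate(exchangeable):
        rxns.append(
            Reaction(
                f"EX_{kegg}", {f"{kegg}_e": -1.0}, name=f"{kegg} exchange",
                lower_bound=-1000.0, upper_bound=1000.0,
            )
        )
        rxns.append(
            Reaction(
                f"T_{kegg}", {f"{kegg}_e": -1.0, f"{kegg}_c": 1.0},
                name=f"{kegg} transport", lower_bound=-1000.0, upper_bound=1000.0,
                kegg_rxn_id=f"R96{n + 1:03d}", subsystem="transport",
            )
        )

    precursor_ids = []
    intermediates: list[str] = []
    rxn_counter = 0
    for j in range(params.n_precursors):
        prec = f"C95{j + 1:03d}_c"
        precursor_ids.append(prec)
        mets.append(Metabolite(prec, "C5H9NO4", f"C95{j + 1:03d}", "c"))
        n_routes = params.routes_per_precursor if j < params.n_precursors - 1 else 1
        for k in range(n_routes):
            nut = nutrient_ids[(j * params.routes_per_precursor + k) % params.n_nutrients]
            inter = f"C92{j + 1:02d}{k + 1}_c"
            mets.append(Metabolite(inter, "", f"C92{j + 1:02d}{k + 1}", "c"))
            intermediates.append(inter)
            subsystem = f"precursor_{j + 1}_biosynthesis"
            stoich2 = {inter: -1.0, prec: 1.0}
            if k > 0:  # secondary routes also shed a byproduct
                stoich2[f"{byproduct_ids[k % params.n_byproducts]}_c"] = 1.0
            for step, stoich in enumerate(({f"{nut}_c": -1.0, inter: 1.0}, stoich2)):
                rxn_counter += 1
                rxns.append(
                    Reaction(
                        f"R9{j + 1}{k + 1}{step + 1}", dict(stoich),
                        name=f"precursor {j + 1} route {k + 1} step {step + 1}",
                        lower_bound=0.0, upper_bound=1000.0,
                        kegg_rxn_id=f"R90{rxn_counter:03d}", subsystem=subsystem,
                    )
                )

    # acetate / lactate salvage into the first intermediates
    for idx, (kegg, inter) in enumerate(
        ((ACETATE, intermediates[0]), (LACTATE, intermediates[min(2, len(intermediates) - 1)]))
    ):
        rxn_counter += 1
        rxns.append(
            Reaction(
                f"SALV_{kegg}", {f"{kegg}_c": -1.0, inter: 1.0},
                name=f"{kegg} salvage", lower_bound=0.0, upper_bound=1000.0,
                kegg_rxn_id=f"R90{rxn_counter:03d}", subsystem="carbon_salvage",
            )
        )

    # random extra accessory conversions: alternative nutrient feeds.
    # Sources are route-1 (core) nutrients and targets are route-1
    # intermediates, so a carrier model can always run them; the last
    # precursor's sole intermediate is never a target, keeping its route
    # transport the documented essential reaction.
    core_nutrients = [
        nutrient_ids[(j * params.routes_per_precursor) % params.n_nutrients]
        for j in range(params.n_precursors)
    ]
    alt_targets = [
        f"C92{j + 1:02d}1_c" for j in range(params.n_precursors - 1)
    ]
    for i in range(params.n_extra_accessory):
        nut = core_nutrients[int(rng.integers(len(core_nutrients)))]
        inter = alt_targets[int(rng.integers(len(alt_targets)))]
        rxn_counter += 1
        rxns.append(
            Reaction(
                f"ALT_{i + 1:02d}", {f"{nut}_c": -1.0, inter: 1.0},
                name=f"alternative feed {i + 1}", lower_bound=0.0, upper_bound=1000.0,
                kegg_rxn_id=f"R90{rxn_counter:03d}", subsystem="accessory_conversions",
            )
        )

    mets.append(Metabolite("biomass_c", "", "", "c"))
    rxns.append(
        Reaction(
            "BIOMASS", {**{p: -1.0 for p in precursor_ids}, "biomass_c": 1.0},
            name="biomass", lower_bound=0.0, upper_bound=1000.0,
            subsystem="biomass",
        )
    )
    rxns.append(
        Reaction("EX_biomass", {"biomass_c": -1.0}, name="biomass sink",
                 lower_bound=0.0, upper_bound=1000.0)
    )

    gem = GEM(
        model_id=f"generic_model_seed{params.seed}",
        reactions=rxns,
        metabolites=mets,
        genes=[],
        biomass_reaction_id="BIOMASS",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    gem.validate()
    return gem


def _core_accessory_split(params: FixtureParams, model: GEM) -> tuple[list[str], list[str]]:
    """GPR-eligible reactions split into core and accessory sets."""
    eligible = [r.rxn_id for r in model.reactions if r.kegg_rxn_id]
    core: set[str] = set()
    for j in range(params.n_precursors):
        n_routes = params.routes_per_precursor if j < params.n_precursors - 1 else 1
        k = 0  # first (or sole) route is core, transports included
        nut = _nutrient_kegg((j * params.routes_per_precursor + k) % params.n_nutrients)
        core.update({f"T_{nut}", f"R9{j + 1}{k + 1}1", f"R9{j + 1}{k + 1}2"})
    core &= set(eligible)
    accessory = sorted(set(eligible) - core)
    want_core = int(np.ceil(params.core_reaction_fraction * len(eligible)))
    for rid in accessory:
        if len(core) >= want_core:
            break
        core.add(rid)
    accessory = [r for r in eligible if r not in core]
    return [r for r in eligible if r in core], accessory


def make_catalog_and_msps(
    params: FixtureParams, model: GEM, return_details: bool = False
):
    """Gene catalogue, KO map, MSP gene sets and taxonomy for a model.

    Every GPR-eligible reaction gets one KO and two isozyme genes; a few
    orphan genes carry no KO. MSPs carry all core-reaction genes and
    sample accessory reactions with genus-structured probabilities, so
    taxonomy-level reaction frequencies have planted structure. With
    ``return_details=True`` a dict with the core/accessory split, genus
    signatures and the planted effect reactions (accessory reactions
    unique to the effect genus's signature) is appended.
    """
    rng = np.random.default_rng(params.seed + 1)
    eligible = [r for r in model.reactions if r.kegg_rxn_id]
    ko_of: dict[str, str] = {}
    genes_of: dict[str, list[str]] = {}
    catalog_entries: dict[str, frozenset[str]] = {}
    ko_map: dict[str, frozenset[str]] = {}
    gc = 0
    for i, rxn in enumerate(eligible):
        ko = f"K9{i + 1:04d}"
        ko_of[rxn.rxn_id] = ko
        ko_map[ko] = frozenset({rxn.kegg_rxn_id})
        pair = []
        for _ in range(2):
            gc += 1
            gid = f"gene_{gc:05d}"
            catalog_entries[gid] = frozenset({ko})
            pair.append(gid)
        genes_of[rxn.rxn_id] = pair
    for _ in range(params.n_orphan_genes):
        gc += 1
        catalog_entries[f"gene_{gc:05d}"] = frozenset()
    catalog = GeneCatalog(catalog_entries)
    komap = KoReactionMap(ko_map)

    core, accessory = _core_accessory_split(params, model)
    genera = [f"genus_{g + 1}" for g in range(params.n_genera)]
    # each accessory reaction belongs to one "home" genus signature
    # (round-robin over shuffled orders, so every genus gets some);
    # carriage probability is high within the home genus, low elsewhere.
    # Self-contained alternative-assimilation (ALT) reactions are dealt
    # separately so each genus is guaranteed a share of them: they are
    # the reactions a species model always retains, hence the planted
    # case/control effect is evaluated on the effect genus's ALT set.
    signatures: dict[str, set[str]] = {g: set() for g in genera}
    for group in (
        [r for r in accessory if r.startswith("ALT_")],
        [r for r in accessory if not r.startswith("ALT_")],
    ):
        order = list(group)
        rng.shuffle(order)
        for i, rid in enumerate(order):
            signatures[genera[i % params.n_genera]].add(rid)
    p_in = params.accessory_presence_prob
    p_out = p_in / 8.0

    msps: dict[str, set[str]] = {}
    tax_rows = []
    genera_per_phylum = int(np.ceil(params.n_genera / params.n_phyla))
    for gi, genus in enumerate(genera):
        phylum_i = gi // genera_per_phylum
        family = f"family_{gi // 2 + 1}"
        order = f"order_{phylum_i + 1}"
        clazz = f"class_{phylum_i + 1}"
        phylum = f"phylum_{phylum_i + 1}"
        for si in range(params.msps_per_genus):
            msp_id = f"msp_g{gi + 1}_{si + 1}"
            genes: set[str] = set()
            for rid in core:
                genes.update(genes_of[rid])
            for rid in accessory:
                p = p_in if rid in signatures[genus] else p_out
                if rng.random() < p:
                    genes.update(genes_of[rid])
            msps[msp_id] = genes
            tax_rows.append(
                (msp_id, f"{genus} sp. {si + 1}", genus, family, order, clazz, phylum)
            )
    taxonomy = pd.DataFrame(
        tax_rows, columns=["msp_id", "species"] + list(TAXONOMY_LEVELS)
    ).set_index("msp_id")

    result = (catalog, komap, msps, taxonomy)
    if return_details:
        effect_reactions = sorted(
            r for r in signatures.get(params.effect_genus, set())
            if r.startswith("ALT_")
        )
        details = {
            "core": core,
            "accessory": accessory,
            "signatures": signatures,
            "effect_reactions": effect_reactions,
            "genes_of": genes_of,
        }
        return result + (details,)
    return result


def make_abundance_table(params: FixtureParams = DEMO_PARAMS) -> tuple[pd.DataFrame, pd.Series]:
    """MSP x sample abundances (columns sum to 1) and case/control labels.

    Per-MSP baselines and per-sample noise are lognormal
    (``sigma = lognormal_sigma``); in case samples (the second half), the
    MSPs of ``effect_genus`` are boosted by ``effect_size`` before
    renormalization, planting a detectable reactobiome contrast.
    """
    rng = np.random.default_rng(params.seed + 2)
    msp_ids = [
        f"msp_g{gi + 1}_{si + 1}"
        for gi in range(params.n_genera)
        for si in range(params.msps_per_genus)
    ]
    n = len(msp_ids)
    samples = [f"S{i + 1:03d}" for i in range(params.n_samples)]
    n_ctrl = params.n_samples // 2
    groups = pd.Series(
        ["control"] * n_ctrl + ["case"] * (params.n_samples - n_ctrl),
        index=samples, name="group",
    )
    baseline = rng.normal(0.0, 1.0, size=n)
    noise = rng.normal(0.0, params.lognormal_sigma, size=(n, params.n_samples))
    log_ab = baseline[:, None] + noise
    ab = np.exp(log_ab)
    effect_gi = int(params.effect_genus.rsplit("_", 1)[-1]) if "_" in params.effect_genus else 0
    boost_rows = [i for i, m in enumerate(msp_ids) if m.startswith(f"msp_g{effect_gi}_")]
    case_cols = np.arange(n_ctrl, params.n_samples)
    if boost_rows and params.effect_size != 1.0:
        ab[np.ix_(boost_rows, case_cols)] *= params.effect_size
    ab = ab / ab.sum(axis=0)
    return pd.DataFrame(ab, index=msp_ids, columns=samples), groups


_DIET_NAMES = (
    "high_protein_plant_based",
    "high_protein_omnivorous",
    "high_fiber_plant_based",
    "high_fiber_omnivorous",
    "average_UK",
)


def fixture_diets(params: FixtureParams = DEMO_PARAMS) -> list[Diet]:
    """Five toy diets (synthetic compositions over the fixture nutrients).

    Each diet opens every fixture nutrient with a diet-specific uptake
    magnitude (mmol/gDW/h), emulating macronutrient shifts at a 2000 kCal
    basis. Compositions are synthetic stand-ins: the named real diets'
    ingredient lists are not part of this package.
    """
    nutrient_ids = [_nutrient_kegg(i) for i in range(params.n_nutrients)]
    diets = []
    for d, name in enumerate(_DIET_NAMES):
        bounds = {
            kegg: float(5 + ((d + i) % 3) * 5)  # 5, 10 or 15
            for i, kegg in enumerate(nutrient_ids)
        }
        diets.append(Diet(name=name, uptake_bounds=bounds, kcal_basis=2000.0))
    return diets


def fixture_pathways(model: GEM) -> dict[str, set[str]]:
    """GMT-style reaction sets from the model's subsystem annotations."""
    sets: dict[str, set[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem and not rxn.is_exchange:
            sets.setdefault(rxn.subsystem, set()).add(rxn.rxn_id)
    return sets


@dataclass
class DemoInputs:
    """Everything the demo pipeline consumes, generated from one seed."""

    params: FixtureParams
    model: GEM
    catalog: GeneCatalog
    ko_map: KoReactionMap
    msps: dict[str, set[str]]
    taxonomy: pd.DataFrame
    abundance: pd.DataFrame
    groups: pd.Series
    diets: list[Diet]
    pathways: dict[str, set[str]]
    effect_reactions: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)


def make_demo_inputs(params: FixtureParams = DEMO_PARAMS) -> DemoInputs:
    """Generate the full demo input set (the canonical test bed)."""
    model = make_generic_model(params)
    catalog, komap, msps, taxonomy, details = make_catalog_and_msps(
        params, model, return_details=True
    )
    abundance, groups = make_abundance_table(params)
    return DemoInputs(
        params=params,
        model=model,
        catalog=catalog,
        ko_map=komap,
        msps=msps,
        taxonomy=taxonomy,
        abundance=abundance,
        groups=groups,
        diets=fixture_diets(params),
        pathways=fixture_pathways(model),
        effect_reactions=details["effect_reactions"],
        details=details,
    )
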