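"""Shared fixtures: toy models and the session-scoped demo pipeline."""

from __future__ import annotations

import warnings

import pytest

import microgem as mg
from microgem.model import GEM, Metabolite, Reaction


def make_chain_gem(uptake: float = 10.0) -> GEM:
    """EX_A -> A->B -> biomass: the analytically forced linear chain."""
    return GEM(
        model_id="chain",
        metabolites=[Metabolite("A", compartment="c"), Metabolite("B", compartment="c")],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, lower_bound=-uptake, upper_bound=1000.0),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=1000.0),
            Reaction("BIOMASS", {"B": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        biomass_reaction_id="BIOMASS",
        compartments={"c": "cytosol"},
    )


def make_parallel_gem() -> GEM:
    """Uptake 10 feeding B through two capacity-10 routes (A->B, A->C->B)."""
    return GEM(
        model_id="parallel",
        metabolites=[
            Metabolite("A", compartment="c"),
            Metabolite("B", compartment="c"),
            Metabolite("C", compartment="c"),
        ],
        reactions=[
            Reaction("EX_A", {"A": -1.0}, lower_bound=-10.0, upper_bound=1000.0),
            Reaction("R_AB", {"A": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("R_AC", {"A": -1.0, "C": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("R_CB", {"C": -1.0, "B": 1.0}, lower_bound=0.0, upper_bound=10.0),
            Reaction("BIOMASS", {"B": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        biomass_reaction_id="BIOMASS",
        compartments={"c": "cytosol"},
    )


def make_toy_reference() -> tuple[GEM, dict[str, set[str]], "pd.DataFrame"]:
    """A GPR-annotated toy reference with parallel pathways and 4 MSPs.

    Route P_A (gene gA) and route P_B (genes gB1, gB2) both make B from A.
    MSP msp1 carries only P_A, msp2 both, msp3 only P_B, msp4 lacks the
    transport gene gT (its sole essential transport must be gap-filled).
    """
    import pandas as pd

    gem = GEM(
        model_id="toy_ref",
        metabolites=[
            Metabolite("A_e", compartment="e", kegg_met_id="C00001"),
            Metabolite("A_c", compartment="c", kegg_met_id="C00001"),
            Metabolite("B_c", compartment="c"),
            Metabolite("C_c", compartment="c"),
            Metabolite("bm_c", compartment="c"),
        ],
        reactions=[
            Reaction("EX_A", {"A_e": -1.0}, lower_bound=-10.0, upper_bound=1000.0),
            Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lower_bound=-1000.0,
                     upper_bound=1000.0, gpr_rule="gT", kegg_rxn_id="R00001"),
            Reaction("R_PA", {"A_c": -1.0, "B_c": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0, gpr_rule="gA", kegg_rxn_id="R00002"),
            Reaction("R_PB1", {"A_c": -1.0, "C_c": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0, gpr_rule="gB1", kegg_rxn_id="R00003"),
            Reaction("R_PB2", {"C_c": -1.0, "B_c": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0, gpr_rule="gB2", kegg_rxn_id="R00004"),
            Reaction("BIOMASS", {"B_c": -1.0, "bm_c": 1.0}, lower_bound=0.0,
                     upper_bound=1000.0),
            Reaction("EX_bm", {"bm_c": -1.0}, lower_bound=0.0, upper_bound=1000.0),
        ],
        genes=["gT", "gA", "gB1", "gB2"],
        biomass_reaction_id="BIOMASS",
        compartments={"c": "cytosol", "e": "extracellular"},
    )
    msps = {
        "msp1": {"gT", "gA"},
        "msp2": {"gT", "gA", "gB1", "gB2"},
        "msp3": {"gT", "gB1", "gB2"},
        "msp4": {"gA"},
    }
    tax = pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(1, 5)],
            "genus": ["gen1"] * 4,
            "family": ["fam1"] * 4,
            "order": ["ord1"] * 4,
            "class": ["cls1"] * 4,
            "phylum": ["phy1"] * 4,
        },
        index=pd.Index(list(msps), name="msp_id"),
    )
    return gem, msps, tax


@pytest.fixture(scope="session")
def demo():
    return mg.make_demo_inputs()


@pytest.fixture(scope="session")
def reference(demo):
    cat, _ = mg.check_catalog([(g, set(k)) for g, k in demo.catalog.entries.items()])
    annotated, _ = mg.convert_ko_to_reactions(cat, demo.ko_map)
    ref, report = mg.build_reference_gem(demo.model, annotated)
    return ref, report


@pytest.fixture(scope="session")
def scored(demo, reference):
    ref, _ = reference
    states = mg.msp_reaction_states(ref, demo.msps)
    freqs = mg.taxon_reaction_frequencies(states, demo.taxonomy)
    scores = mg.reaction_scores(states, freqs)
    thresholds = mg.taxonomy_thresholds(freqs)
    return states, freqs, scores, thresholds


@pytest.fixture(scope="session")
def species_gems(demo, reference, scored):
    ref, _ = reference
    states, freqs, scores, thresholds = scored
    diet = demo.diets[0]
    constrained = mg.apply_diet(ref, diet)
    raw, tuned = [], []
    for msp_id in states.columns:
        sg = mg.generate_species_gem(
            constrained, scores, states, freqs, thresholds, demo.taxonomy,
            msp_id, diet_name=diet.name,
        )
        raw.append(sg)
        tuned.append(mg.tune_species_gem(sg))
    return raw, tuned


@pytest.fixture(scope="session")
def pool_and_cpf(demo, species_gems):
    _, tuned = species_gems
    pool = mg.build_reaction_pool(tuned)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cpf = mg.reactobiome(pool, demo.abundance)
    return pool, cpf
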