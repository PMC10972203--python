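"""Core containers for constraint-based metabolic models.

A :class:`GEM` is a genome-scale metabolic model: an ordered list of
reactions over an ordered list of metabolites, flux bounds, boolean
gene-protein-reaction (GPR) rules, and a biomass objective reaction.
Reversibility is encoded purely by the bounds (``lower_bound < 0``);
there is no separate flag. Exchange reactions are boundary reactions
with exactly one metabolite; uptake is negative flux and secretion is
positive flux, everywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np
from cobra.core.gene import GPR
from scipy import sparse


class ModelValidationError(ValueError):
    """A GEM violates one of its structural invariants."""


@lru_cache(maxsize=None)
def _parsed_gpr(rule: str) -> GPR:
    return GPR.from_string(rule)


def gpr_genes(rule: str) -> frozenset[str]:
    """Gene identifiers appearing in a boolean GPR rule string."""
    if not rule or not rule.strip():
        return frozenset()
    return frozenset(_parsed_gpr(rule).genes)


def eval_gpr(rule: str, present_genes: Iterable[str]) -> bool:
    """Evaluate a GPR rule with the given genes present (all others absent).

    An empty rule evaluates to False: a reaction with no gene association
    cannot be attributed to any gene set.
    """
    if not rule or not rule.strip():
        return False
    gpr = _parsed_gpr(rule)
    present = frozenset(present_genes)
    return gpr.eval(knockouts=gpr.genes - present)


@dataclass(frozen=True)
class Metabolite:
    met_id: str
    formula: str = ""
    kegg_met_id: str = ""
    compartment: str = "c"


@dataclass
class Reaction:
    """A stoichiometric reaction with bounds in mmol / gDW / h."""

    rxn_id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr_rule: str = ""
    kegg_rxn_id: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.rxn_id}: coefficient for {met} must be "
                    f"finite and nonzero, got {coef!r}"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.rxn_id}: lower_bound {self.lower_bound} "
                f"exceeds upper_bound {self.upper_bound}"
            )

    @property
    def is_exchange(self) -> bool:
        """True iff the reaction has exactly one metabolite (boundary reaction)."""
        return len(self.stoichiometry) == 1

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr_rule)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class FluxSolution:
    """Outcome of an LP solve: status, objective, and a flux vector."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class GEM:
    model_id: str
    reactions: list[Reaction]
    metabolites: list[Metabolite]
    genes: list[str] = field(default_factory=list)
    biomass_reaction_id: str = ""
    compartments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rxn_index: dict[str, int] = {
            r.rxn_id: i for i, r in enumerate(self.reactions)
        }
        self._met_index: dict[str, int] = {
            m.met_id: i for i, m in enumerate(self.metabolites)
        }

    # -- lookups ---------------------------------------------------------
    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.rxn_id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.met_id for m in self.metabolites]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def is_transport(self, rxn: Reaction) -> bool:
        """True iff the reaction's metabolites span more than one compartment."""
        comps = {self.metabolite(m).compartment for m in rxn.stoichiometry}
        return len(comps) > 1

    @property
    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- derived structure -----------------------------------------------
    def stoichiometric_matrix(self) -> tuple[sparse.csr_matrix, dict[str, int], dict[str, int]]:
        """Sparse S (metabolites x reactions) with index maps."""
        rows, cols, vals = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met])
                cols.append(j)
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(self.metabolites), len(self.reactions)),
        )
        return S, dict(self._met_index), dict(self._rxn_index)

    def rxn_gene_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Binary reaction x gene incidence derived from the GPR rules."""
        genes = list(self.genes)
        gidx = {g: j for j, g in enumerate(genes)}
        mat = np.zeros((len(self.reactions), len(genes)), dtype=np.int8)
        for i, rxn in enumerate(self.reactions):
            for g in rxn.genes:
                mat[i, gidx[g]] = 1
        return mat, self.reaction_ids, genes

    # -- editing ---------------------------------------------------------
    def copy(self, model_id: str | None = None) -> "GEM":
        return GEM(
            model_id=model_id or self.model_id,
            reactions=[r.copy() for r in self.reactions],
            metabolites=list(self.metabolites),
            genes=list(self.genes),
            biomass_reaction_id=self.biomass_reaction_id,
            compartments=dict(self.compartments),
        )

    def remove_reactions(self, rxn_ids: Iterable[str], prune_metabolites: bool = False) -> None:
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise KeyError(f"reactions not in model: {sorted(missing)}")
        self.reactions = [r for r in self.reactions if r.rxn_id not in drop]
        if prune_metabolites:
            used = {m for r in self.reactions for m in r.stoichiometry}
            self.metabolites = [m for m in self.metabolites if m.met_id in used]
        used_genes = {g for r in self.reactions for g in r.genes}
        self.genes = [g for g in self.genes if g in used_genes]
        self.__post_init__()

    def refresh(self) -> None:
        """Rebuild internal indices after in-place edits to the lists."""
        self.__post_init__()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ModelValidationError` on any broken invariant."""
        if len(self._rxn_index) != len(self.reactions):
            raise ModelValidationError(f"{self.model_id}: duplicate reaction ids")
        if len(self._met_index) != len(self.metabolites):
            raise ModelValidationError(f"{self.model_id}: duplicate metabolite ids")
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in self._met_index:
                    raise ModelValidationError(
                        f"reaction {rxn.rxn_id} references unknown metabolite {met}"
                    )
            stray = rxn.genes - gene_set
            if stray:
                raise ModelValidationError(
                    f"reaction {rxn.rxn_id} GPR uses genes missing from the "
                    f"gene list: {sorted(stray)}"
                )
        for met in self.metabolites:
            if self.compartments and met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.met_id} in undeclared compartment "
                    f"{met.compartment!r}"
                )
        if self.biomass_reaction_id and self.biomass_reaction_id not in self._rxn_index:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )


def _production_consumption(gem: GEM) -> tuple[Mapping[str, bool], Mapping[str, bool]]:
    can_produce = {m.met_id: False for m in gem.metabolites}
    can_consume = {m.met_id: False for m in gem.metabolites}
    for rxn in gem.reactions:
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and fwd) or (coef < 0 and rev):
                can_produce[met] = True
            if (coef < 0 and fwd) or (coef > 0 and rev):
                can_consume[met] = True
    return can_produce, can_consume


def find_dead_end_metabolites(gem: GEM) -> list[str]:
    """Metabolites that cannot carry steady-state flux.

    A metabolite is a dead end when, accounting for reversibility via the
    bounds, it can only be produced, only be consumed, or appears in no
    reaction at all. Any reaction touching such a metabolite is forced to
    zero flux at steady state.
    """
    can_produce, can_consume = _production_consumption(gem)
    return [
        m.met_id
        for m in gem.metabolites
        if not (can_produce[m.met_id] and can_consume[m.met_id])
    ]
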