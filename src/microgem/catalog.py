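"""Gene-catalogue validation and integration into the reference GEM.

A non-redundant microbial gene catalogue (gene id -> KEGG Orthology
terms) is validated, its KO annotations are translated to KEGG reaction
identifiers through an offline mapping table, and the annotated genes
are woven into a generic metabolic model as gene-protein-reaction (GPR)
rules keyed on the reactions' KEGG ids. The result is the microbiome
reference GEM from which all species models are carved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import GEM

KO_PATTERN = re.compile(r"^K\d{5}$")
RXN_PATTERN = re.compile(r"^R\d{5}$")


@dataclass
class GeneCatalog:
    """Ordered mapping gene_id -> set of KO identifiers (possibly empty)."""

    entries: dict[str, frozenset[str]]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CatalogReport:
    n_genes: int = 0
    duplicates: dict[str, int] = field(default_factory=dict)
    malformed_kos: dict[str, list[str]] = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return not self.duplicates and not self.malformed_kos


def check_catalog(raw_entries: list[tuple[str, set[str]]]) -> tuple[GeneCatalog, CatalogReport]:
    """Validate and restructure a raw gene catalogue.

    Duplicate gene ids are collapsed by taking the union of their KO sets;
    malformed KO tokens (anything but K + 5 digits) are dropped. Both are
    reported, never fatal. An empty catalogue is an error.
    """
    if not raw_entries:
        raise ValueError("empty gene catalogue")
    report = CatalogReport()
    merged: dict[str, set[str]] = {}
    for gene_id, kos in raw_entries:
        if gene_id in merged:
            report.duplicates[gene_id] = report.duplicates.get(gene_id, 1) + 1
        merged.setdefault(gene_id, set()).update(kos)
    entries: dict[str, frozenset[str]] = {}
    for gene_id, kos in merged.items():
        bad = sorted(k for k in kos if not KO_PATTERN.match(k))
        if bad:
            report.malformed_kos[gene_id] = bad
        entries[gene_id] = frozenset(k for k in kos if KO_PATTERN.match(k))
    report.n_genes = len(entries)
    return GeneCatalog(entries), report


@dataclass
class KoReactionMap:
    """KO identifier -> set of KEGG reaction identifiers."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean = {}
        for ko, rxns in self.mapping.items():
            if not KO_PATTERN.match(ko):
                raise ValueError(f"malformed KO identifier {ko!r} in mapping")
            bad = [r for r in rxns if not RXN_PATTERN.match(r)]
            if bad:
                raise ValueError(f"malformed reaction identifiers for {ko}: {bad}")
            if rxns:
                clean[ko] = frozenset(rxns)
        self.mapping = clean

    def __len__(self) -> int:
        return len(self.mapping)


def convert_ko_to_reactions(
    catalog: GeneCatalog, ko_map: KoReactionMap
) -> tuple[dict[str, frozenset[str]], set[str]]:
    """Translate each gene's KO terms into KEGG reaction identifiers.

    Returns the annotated catalogue (gene -> union of mapped reactions,
    empty set when nothing maps) and the set of KO terms that had no
    mapping entry (reported, not fatal).
    """
    if not len(ko_map):
        raise ValueError("empty KO-to-reaction mapping")
    annotated: dict[str, frozenset[str]] = {}
    unmapped: set[str] = set()
    for gene_id, kos in catalog.entries.items():
        rxns: set[str] = set()
        for ko in kos:
            hit = ko_map.mapping.get(ko)
            if hit is None:
                unmapped.add(ko)
            else:
                rxns.update(hit)
        annotated[gene_id] = frozenset(rxns)
    return annotated, unmapped


@dataclass
class IntegrationReport:
    n_reactions: int
    n_with_gpr: int
    n_flagged_no_gpr: int
    replaced_rules: dict[str, str] = field(default_factory=dict)
    no_gpr_reactions: list[str] = field(default_factory=list)

    @property
    def percent_with_gpr(self) -> float:
        return 100.0 * self.n_with_gpr / self.n_reactions if self.n_reactions else 0.0


def build_reference_gem(
    generic: GEM, annotated: dict[str, frozenset[str]]
) -> tuple[GEM, IntegrationReport]:
    """Attach catalogue genes to a generic model as OR-joined GPR rules.

    Every model reaction whose KEGG reaction id is hit by at least one
    catalogue gene gets ``gpr_rule = "gA or gB or ..."`` (isozyme
    semantics; catalogue genes are non-redundant representatives, not
    complex subunits). Reactions with no hit keep an empty GPR and are
    flagged. Pre-existing GPRs are replaced when hits exist, with the
    original rule preserved in the report. Stoichiometry, bounds and
    metabolites are never altered, and integration is idempotent.
    """
    if not any(r.kegg_rxn_id for r in generic.reactions):
        raise ValueError(
            f"model {generic.model_id} has no resolvable KEGG reaction identifiers"
        )
    rxn_to_genes: dict[str, set[str]] = {}
    for gene_id, rxns in annotated.items():
        for rxn in rxns:
            rxn_to_genes.setdefault(rxn, set()).add(gene_id)

    gem = generic.copy()
    report = IntegrationReport(
        n_reactions=len(gem.reactions), n_with_gpr=0, n_flagged_no_gpr=0
    )
    used_genes: set[str] = set()
    for rxn in gem.reactions:
        hits = rxn_to_genes.get(rxn.kegg_rxn_id) if rxn.kegg_rxn_id else None
        if hits:
            rule = " or ".join(sorted(hits))
            if rxn.gpr_rule and rxn.gpr_rule != rule:
                report.replaced_rules[rxn.rxn_id] = rxn.gpr_rule
            rxn.gpr_rule = rule
            used_genes.update(hits)
            report.n_with_gpr += 1
        else:
            if rxn.gpr_rule:
                report.replaced_rules[rxn.rxn_id] = rxn.gpr_rule
                rxn.gpr_rule = ""
            report.n_flagged_no_gpr += 1
            report.no_gpr_reactions.append(rxn.rxn_id)
    gem.genes = sorted(used_genes)
    gem.validate()
    return gem, report
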