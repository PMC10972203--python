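"""Model serialization: SBML Level 3 + FBC v2 and a JSON dialect.

SBML-FBC is the interchange format (read and written through cobrapy /
libsbml). The JSON dialect mirrors the :class:`~microgem.model.GEM`
type one-to-one and is the fast, diffable format used for fixtures::

    {
      "model_id": str,
      "compartments": {code: description, ...},
      "metabolites": [{"id", "formula", "kegg_id", "compartment"}, ...],
      "reactions": [{"id", "name", "stoichiometry": {met: coef},
                     "lower_bound", "upper_bound", "gpr", "kegg_id",
                     "subsystem"}, ...],
      "biomass_reaction_id": str
    }

Derived structure (exchange/transport status, the reaction-gene matrix)
is never stored; it is recomputed from the fields above.
"""

from __future__ import annotations

import json
from pathlib import Path

import cobra

from .model import GEM, Metabolite, ModelValidationError, Reaction, gpr_genes


class ModelFormatError(ValueError):
    """A model file does not parse under the named standard."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ModelFormatError(f"cannot infer model format from {path.name!r}")


# ---------------------------------------------------------------------------
# cobra conversion
# ---------------------------------------------------------------------------

def to_cobra(gem: GEM) -> cobra.Model:
    """Convert to a cobrapy model (used for SBML I/O and as an FBA oracle)."""
    model = cobra.Model(gem.model_id)
    model.compartments = dict(gem.compartments)
    mets = {}
    for m in gem.metabolites:
        cm = cobra.Metabolite(
            m.met_id, formula=m.formula or None, compartment=m.compartment
        )
        if m.kegg_met_id:
            cm.annotation["kegg.compound"] = m.kegg_met_id
        mets[m.met_id] = cm
    model.add_metabolites(list(mets.values()))
    rxns = []
    for r in gem.reactions:
        cr = cobra.Reaction(
            r.rxn_id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        if r.kegg_rxn_id:
            cr.annotation["kegg.reaction"] = r.kegg_rxn_id
        if r.subsystem:
            cr.subsystem = r.subsystem
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in gem.reactions:
        cr = model.reactions.get_by_id(r.rxn_id)
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr_rule:
            cr.gene_reaction_rule = r.gpr_rule
    if gem.biomass_reaction_id:
        model.objective = gem.biomass_reaction_id
    return model


def from_cobra(model: cobra.Model) -> GEM:
    """Convert a cobrapy model to a :class:`GEM`."""
    metabolites = [
        Metabolite(
            met_id=m.id,
            formula=m.formula or "",
            kegg_met_id=_first(m.annotation.get("kegg.compound", "")),
            compartment=m.compartment or "c",
        )
        for m in model.metabolites
    ]
    reactions = []
    for r in model.reactions:
        if r.lower_bound is None or r.upper_bound is None:
            raise ModelFormatError(f"reaction {r.id} has no flux bounds")
        reactions.append(
            Reaction(
                rxn_id=r.id,
                name=r.name or "",
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr_rule=r.gene_reaction_rule or "",
                kegg_rxn_id=_first(r.annotation.get("kegg.reaction", "")),
                subsystem=r.subsystem or "",
            )
        )
    objective_rxns = [
        r.id for r in model.reactions if r.objective_coefficient
    ]
    biomass = objective_rxns[0] if objective_rxns else ""
    compartments = dict(model.compartments)
    for m in metabolites:
        compartments.setdefault(m.compartment, m.compartment)
    genes = sorted({g for r in reactions for g in gpr_genes(r.gpr_rule)})
    gem = GEM(
        model_id=model.id or "model",
        reactions=reactions,
        metabolites=metabolites,
        genes=genes,
        biomass_reaction_id=biomass,
        compartments=compartments,
    )
    return gem


def _first(value) -> str:
    if isinstance(value, (list, tuple)):
        return str(value[0]) if value else ""
    return str(value)


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def _check_sbml_bounds(path: Path) -> None:
    """Reject SBML whose reactions lack explicit FBC flux bounds.

    cobrapy silently substitutes defaults; the contract here is an
    explicit format error naming the offending reaction.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(f"{path.name}: {err.getMessage().strip()}")
    model = doc.getModel()
    if model is None:
        raise ModelFormatError(f"{path.name}: no SBML model element")
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise ModelFormatError(
                f"{path.name}: reaction {rxn.getId()!r} has no FBC flux bounds"
            )

def read_model(path: str | Path, format: str | None = None, require_objective: bool = True) -> GEM:
    """Read a GEM from SBML-FBC or the JSON dialect.

    Raises :class:`ModelFormatError` on parse failure (naming the offending
    element where known) and on a missing objective unless
    ``require_objective=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        _check_sbml_bounds(path)
        try:
            model = cobra.io.read_sbml_model(str(path))
        except ModelFormatError:
            raise
        except Exception as exc:  # libsbml errors are not a single type
            raise ModelFormatError(f"{path.name}: {exc}") from exc
        gem = from_cobra(model)
    elif fmt == "json":
        gem = _read_json(path)
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")
    if require_objective and not gem.biomass_reaction_id:
        raise ModelFormatError(f"{path.name}: no objective reaction defined")
    gem.validate()
    return gem


def write_model(gem: GEM, path: str | Path, format: str | None = None) -> Path:
    """Write a GEM; ``read_model(write_model(gem))`` reproduces all fields."""
    gem.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cobra.io.write_sbml_model(to_cobra(gem), str(path))
    elif fmt == "json":
        path.write_text(json.dumps(_to_dict(gem), indent=1, sort_keys=False) + "\n")
    else:
        raise ModelFormatError(f"unknown model format {fmt!r}")
    return path


def _to_dict(gem: GEM) -> dict:
    return {
        "model_id": gem.model_id,
        "compartments": dict(gem.compartments),
        "metabolites": [
            {
                "id": m.met_id,
                "formula": m.formula,
                "kegg_id": m.kegg_met_id,
                "compartment": m.compartment,
            }
            for m in gem.metabolites
        ],
        "reactions": [
            {
                "id": r.rxn_id,
                "name": r.name,
                "stoichiometry": {m: c for m, c in r.stoichiometry.items()},
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr_rule,
                "kegg_id": r.kegg_rxn_id,
                "subsystem": r.subsystem,
            }
            for r in gem.reactions
        ],
        "biomass_reaction_id": gem.biomass_reaction_id,
    }


def _read_json(path: Path) -> GEM:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path.name}: invalid JSON ({exc})") from exc
    try:
        metabolites = [
            Metabolite(
                met_id=m["id"],
                formula=m.get("formula", ""),
                kegg_met_id=m.get("kegg_id", ""),
                compartment=m.get("compartment", "c"),
            )
            for m in data["metabolites"]
        ]
        reactions = []
        for r in data["reactions"]:
            if "lower_bound" not in r or "upper_bound" not in r:
                raise ModelFormatError(
                    f"{path.name}: reaction {r.get('id', '?')} has no flux bounds"
                )
            reactions.append(
                Reaction(
                    rxn_id=r["id"],
                    name=r.get("name", ""),
                    stoichiometry={m: float(c) for m, c in r["stoichiometry"].items()},
                    lower_bound=float(r["lower_bound"]),
                    upper_bound=float(r["upper_bound"]),
                    gpr_rule=r.get("gpr", ""),
                    kegg_rxn_id=r.get("kegg_id", ""),
                    subsystem=r.get("subsystem", ""),
                )
            )
        genes = sorted({g for r in reactions for g in gpr_genes(r.gpr_rule)})
        return GEM(
            model_id=data["model_id"],
            reactions=reactions,
            metabolites=metabolites,
            genes=genes,
            biomass_reaction_id=data.get("biomass_reaction_id", ""),
            compartments=data.get("compartments", {}),
        )
    except ModelFormatError:
        raise
    except (KeyError, TypeError, ValueError, ModelValidationError) as exc:
        raise ModelFormatError(f"{path.name}: {exc}") from exc
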