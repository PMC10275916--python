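"""SBML Level 3 + FBC read/write, model validation and annotation.

Models are written with the Flux Balance Constraints (fbc v2) extension so
bounds, GPR associations and the objective all round-trip; provenance tags
(``source``, ``gapfilled``) ride in reaction notes.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import cobra
import cobra.io

logger = logging.getLogger(__name__)

_NAMESPACE = re.compile(r"(rxn\d+_[a-z]|cpd\d+_[a-z]|EX_cpd\d+_e|TP_cpd\d+|biomass)")


class ModelValidationError(ValueError):
    """Raised when a model violates structural invariants."""


def validate_model(model: cobra.Model) -> None:
    """Enforce structural invariants before serialization.

    A valid model has at least one reaction, exactly one objective
    reaction present in the model, consistent bounds, and a gene set equal
    to the union of gene ids over all GPRs (cobra maintains the latter;
    we assert it anyway as a guard against manual mutation).
    """
    if len(model.reactions) == 0:
        raise ModelValidationError("model has no reactions")
    objective = [r for r in model.reactions if r.objective_coefficient != 0]
    if len(objective) != 1:
        raise ModelValidationError(
            f"model must have exactly one objective reaction, found "
            f"{[r.id for r in objective]}"
        )
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"reaction {rxn.id}: lower bound exceeds upper bound"
            )
    gpr_genes = set()
    for rxn in model.reactions:
        gpr_genes.update(g.id for g in rxn.genes)
    model_genes = {g.id for g in model.genes}
    if gpr_genes != model_genes:
        raise ModelValidationError(
            f"gene set out of sync with GPRs: {model_genes ^ gpr_genes}"
        )


def write_sbml(model: cobra.Model, path: str | Path) -> None:
    """Write a validated model as SBML L3V1 with FBC v2."""
    validate_model(model)
    cobra.io.write_sbml_model(model, str(path))


def read_sbml(path: str | Path) -> cobra.Model:
    """Read an SBML+FBC model, enforcing invariants.

    Invalid XML or a document without an objective is a hard error; ids
    outside the ``cpd/rxn`` namespace only provoke a warning, since
    foreign-namespace models are loadable but will not gap-fill against a
    ModelSEED-style database.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as err:  # libsbml raises a zoo of types
        raise ModelValidationError(f"could not parse SBML from {path}: {err}") from err
    objective = [r for r in model.reactions if r.objective_coefficient != 0]
    if not objective:
        raise ModelValidationError(f"{path}: SBML document defines no objective")
    ids = [r.id for r in model.reactions] + [m.id for m in model.metabolites]
    matched = sum(1 for i in ids if _NAMESPACE.fullmatch(i))
    if ids and matched < len(ids) / 2:
        logger.warning(
            "%s: %d/%d ids fall outside the cpd/rxn namespace; gap-filling "
            "against a ModelSEED-style database may find nothing",
            path, len(ids) - matched, len(ids),
        )
    return model


def annotate(
    model: cobra.Model,
    metabolite_names: dict[str, str] | None = None,
    reaction_names: dict[str, str] | None = None,
    gene_xrefs: dict[str, str] | None = None,
) -> dict[str, int]:
    """Fill names/cross-references from id dictionaries, in place.

    Ids absent from a dictionary are left bare; the returned counts
    record how many of each component stayed unannotated.
    """
    missing = {"metabolites": 0, "reactions": 0, "genes": 0}
    for met in model.metabolites:
        name = (metabolite_names or {}).get(met.id)
        if name:
            met.name = name
        else:
            missing["metabolites"] += 1
    for rxn in model.reactions:
        name = (reaction_names or {}).get(rxn.id)
        if name:
            rxn.name = name
        else:
            missing["reactions"] += 1
    for gene in model.genes:
        xref = (gene_xrefs or {}).get(gene.id)
        if xref:
            gene.annotation["kegg.genes"] = xref
        else:
            missing["genes"] += 1
    return missing


def structurally_equal(a: cobra.Model, b: cobra.Model) -> bool:
    """Structural equality: same reactions, stoichiometries, bounds, GPRs,
    provenance notes, metabolite attributes and objective."""
    if sorted(r.id for r in a.reactions) != sorted(r.id for r in b.reactions):
        return False
    if sorted(m.id for m in a.metabolites) != sorted(m.id for m in b.metabolites):
        return False
    for ma in a.metabolites:
        mb = b.metabolites.get_by_id(ma.id)
        if (ma.formula or None, ma.charge, ma.compartment) != (
            mb.formula or None, mb.charge, mb.compartment,
        ):
            return False
    for ra in a.reactions:
        rb = b.reactions.get_by_id(ra.id)
        if {m.id: c for m, c in ra.metabolites.items()} != {
            m.id: c for m, c in rb.metabolites.items()
        }:
            return False
        if ra.bounds != rb.bounds:
            return False
        if ra.gene_reaction_rule != rb.gene_reaction_rule:
            return False
        if ra.notes.get("source") != rb.notes.get("source"):
            return False
        if ra.notes.get("gapfilled") != rb.notes.get("gapfilled"):
            return False
        if ra.objective_coefficient != rb.objective_coefficient:
            return False
    return True
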