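"""Helpers that copy universal-database records into COBRApy models."""

from __future__ import annotations

import cobra

from .database import Reaction, UniversalDatabase


def cobra_metabolite(db: UniversalDatabase, met_id: str) -> cobra.Metabolite:
    rec = db.metabolites[met_id]
    met = cobra.Metabolite(
        rec.id,
        name=rec.name or rec.id,
        formula=rec.formula,
        charge=rec.charge,
        compartment=rec.compartment,
    )
    return met


def add_db_reaction(
    model: cobra.Model,
    db: UniversalDatabase,
    rxn_id: str,
    source: str,
    gpr: str = "",
    extra_notes: dict | None = None,
) -> cobra.Reaction:
    """Copy one database reaction (and any missing metabolites) into a model.

    The copy carries the provenance tag in ``notes["source"]`` and the given
    GPR; database bounds are inherited.  Adding an id already present is an
    error — callers decide what is a candidate.
    """
    rec: Reaction = db.reactions[rxn_id]
    if rxn_id in model.reactions:
        raise ValueError(f"reaction {rxn_id} already present in model {model.id}")
    rxn = cobra.Reaction(
        rec.id, name=rec.name or rec.id,
        lower_bound=rec.lower_bound, upper_bound=rec.upper_bound,
    )
    model.add_reactions([rxn])
    stoich = {}
    for mid, coeff in rec.stoichiometry.items():
        if mid in model.metabolites:
            met = model.metabolites.get_by_id(mid)
        else:
            met = cobra_metabolite(db, mid)
        stoich[met] = coeff
    rxn.add_metabolites(stoich)
    if gpr:
        rxn.gene_reaction_rule = gpr
    rxn.notes["source"] = source
    if extra_notes:
        rxn.notes.update(extra_notes)
    return rxn


def reaction_source(rxn: cobra.Reaction) -> str:
    """Provenance tag of a model reaction (empty string when untagged)."""
    return str(rxn.notes.get("source", ""))
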