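"""From protein-annotation evidence to a draft gene-associated model.

The draft is built solely from reactions with genetic evidence: tabular
protein-alignment hits (BLAST outfmt-6 dialect) are filtered, translated
through a gene→reaction map into the universal namespace, and the mapped
reactions are copied from the universal database with an OR-combined GPR
over their supporting genes.  Media exchanges/transports are then added so
defined uptake is possible at all.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import cobra

from .build import add_db_reaction
from .constants import BIOMASS_ID, DEFAULT_BOUND
from .database import DatabaseError, Metabolite, Reaction, UniversalDatabase
from .media import MediaCondition, set_media

logger = logging.getLogger(__name__)

#: Default alignment-hit thresholds; the hit table prints no provenance, so
#: these are explicit, logged and overridable.
DEFAULT_MAX_EVALUE = 1e-10
DEFAULT_MIN_BITSCORE = 50.0


class HitTableError(ValueError):
    """Raised when a hit table yields no parseable rows."""


@dataclass(frozen=True)
class GeneHit:
    """One protein-alignment hit of a query gene against the gene namespace."""

    query_gene: str
    subject_gene: str
    percent_identity: float
    evalue: float
    bitscore: float


def parse_hits(path: str | Path) -> list[GeneHit]:
    """Parse a 12-column tab-separated alignment hit table.

    Columns follow the tabular BLAST dialect: qseqid, sseqid, pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore.  Malformed rows are skipped with a logged count; a table
    with zero parseable rows is a hard error.
    """
    hits: list[GeneHit] = []
    malformed = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                malformed += 1
                continue
            try:
                hits.append(
                    GeneHit(
                        query_gene=cols[0],
                        subject_gene=cols[1],
                        percent_identity=float(cols[2]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError:
                malformed += 1
    if malformed:
        logger.warning("%s: skipped %d malformed hit rows", path, malformed)
    if not hits:
        raise HitTableError(f"no parseable alignment hits in {path}")
    return hits


def filter_hits(
    hits: Iterable[GeneHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    best_per_subject: bool = True,
) -> list[GeneHit]:
    """Threshold and deduplicate hits.

    Keeps hits with evalue ≤ max_evalue and bitscore ≥ min_bitscore; with
    ``best_per_subject`` (default) only the highest-bitscore hit per
    (query, subject) pair survives.  Output is ranked by bitscore
    descending (ties broken by ids, for determinism).
    """
    kept = [h for h in hits if h.evalue <= max_evalue and h.bitscore >= min_bitscore]
    if best_per_subject:
        best: dict[tuple[str, str], GeneHit] = {}
        for h in kept:
            key = (h.query_gene, h.subject_gene)
            if key not in best or h.bitscore > best[key].bitscore:
                best[key] = h
        kept = list(best.values())
    return sorted(kept, key=lambda h: (-h.bitscore, h.query_gene, h.subject_gene))


class GeneReactionMap:
    """Subject gene/ortholog id → reaction ids in the universal namespace."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]) -> None:
        self.mapping: dict[str, list[str]] = {
            k: sorted(set(v)) for k, v in mapping.items()
        }

    def __contains__(self, subject: str) -> bool:
        return subject in self.mapping

    def __getitem__(self, subject: str) -> list[str]:
        return self.mapping[subject]

    def validate(self, db: UniversalDatabase) -> None:
        """Every right-hand-side reaction id must resolve in the database."""
        missing = {
            r for rxns in self.mapping.values() for r in rxns if r not in db.reactions
        }
        if missing:
            raise DatabaseError(
                "gene-reaction map references reactions absent from the "
                f"universal database: {sorted(missing)[:10]}"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneReactionMap":
        """Load from JSON ({subject: [rxn, ...]}) or two-column TSV."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls(json.loads(path.read_text()))
        mapping: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) >= 2 and cols[0] and not cols[0].startswith("#"):
                    mapping.setdefault(cols[0], []).extend(cols[1].split(";"))
        return cls(mapping)


def hits_to_evidence(
    hits: Iterable[GeneHit], grm: GeneReactionMap
) -> dict[str, set[str]]:
    """Translate hits into per-reaction supporting-gene evidence.

    Every reaction mapped from a hit's subject gains the hit's query gene
    as support.  Subjects absent from the map are counted and logged,
    never fatal.
    """
    evidence: dict[str, set[str]] = {}
    unmapped = 0
    for hit in hits:
        if hit.subject_gene not in grm:
            unmapped += 1
            continue
        for rxn_id in grm[hit.subject_gene]:
            evidence.setdefault(rxn_id, set()).add(hit.query_gene)
    if unmapped:
        logger.warning("%d hits had subjects absent from the gene-reaction map", unmapped)
    return evidence


def _has_transport(model: cobra.Model, base_id: str) -> bool:
    """Does any model reaction move ``base_id`` between e and c?"""
    e_id, c_id = f"{base_id}_e", f"{base_id}_c"
    for rxn in model.reactions:
        mids = {m.id for m in rxn.metabolites}
        if e_id in mids and c_id in mids:
            return True
    return False


def build_draft(
    evidence: Mapping[str, Iterable[str]],
    db: UniversalDatabase,
    media: MediaCondition,
    model_id: str = "draft",
) -> cobra.Model:
    """Assemble the draft model from gene evidence plus media plumbing.

    The draft contains every evidenced reaction copied from the database
    (source ``gene_annotated``, GPR = OR over supporting genes), the
    biomass reaction as objective, and media-driven additions
    (source ``media_added``): under the complete medium every database
    exchange; under a defined medium each media metabolite's exchange plus,
    when no transport exists, a reversible e↔c transport.  The medium's
    uptake bounds are applied last.  Construction is deterministic
    (sorted insertion order).
    """
    unknown = sorted(r for r in evidence if r not in db.reactions)
    if unknown:
        raise DatabaseError(f"evidence references unknown reactions: {unknown[:10]}")
    if not evidence:
        logger.warning("no reaction evidence: draft will contain only "
                       "biomass and media reactions")

    model = cobra.Model(model_id)
    for rxn_id in sorted(evidence):
        genes = sorted(set(evidence[rxn_id]))
        gpr = " or ".join(genes)
        add_db_reaction(model, db, rxn_id, source="gene_annotated", gpr=gpr)

    if BIOMASS_ID not in db.reactions:
        raise DatabaseError("universal database has no biomass reaction; curate first")
    if BIOMASS_ID not in model.reactions:
        add_db_reaction(model, db, BIOMASS_ID, source="biomass")
    model.objective = BIOMASS_ID

    if media.is_complete:
        for rxn_id in sorted(db.reactions):
            if db.reactions[rxn_id].is_exchange and rxn_id not in model.reactions:
                add_db_reaction(model, db, rxn_id, source="media_added")
    else:
        for met_id in sorted(media.uptake):
            ex_id = f"EX_{met_id}"
            if ex_id not in model.reactions:
                if ex_id in db.reactions:
                    add_db_reaction(model, db, ex_id, source="media_added")
                elif met_id in db.metabolites:
                    _new_exchange(model, db, met_id)
                else:
                    logger.warning(
                        "media %s: metabolite %s unknown to the database; skipped",
                        media.name, met_id,
                    )
                    continue
            base = met_id[:-2]
            if not _has_transport(model, base):
                _new_transport(model, db, base)
    set_media(model, media)
    return model


def _new_exchange(model: cobra.Model, db: UniversalDatabase, met_id: str) -> None:
    tmp = db.copy()
    tmp.reactions = {}
    tmp.add_reaction(
        Reaction(f"EX_{met_id}", {met_id: -1.0}, lower_bound=-DEFAULT_BOUND,
                 upper_bound=DEFAULT_BOUND, source="exchange")
    )
    add_db_reaction(model, tmp, f"EX_{met_id}", source="media_added")


def _new_transport(model: cobra.Model, db: UniversalDatabase, base: str) -> None:
    """Add a reversible e↔c transport for a media compound lacking one."""
    e_id, c_id = f"{base}_e", f"{base}_c"
    tmp = db.copy()
    if c_id not in tmp.metabolites:
        src = tmp.metabolites[e_id]
        tmp.add_metabolite(Metabolite(c_id, src.name, src.formula, src.charge))
    tmp.reactions = {}
    tmp.add_reaction(
        Reaction(f"TP_{base}", {e_id: -1.0, c_id: 1.0},
                 name=f"{base} transport", lower_bound=-DEFAULT_BOUND,
                 upper_bound=DEFAULT_BOUND, source="media_added")
    )
    add_db_reaction(model, tmp, f"TP_{base}", source="media_added")
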