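"""Deterministic toy fixtures with known ground truth.

Every generated artifact comes with the answers seeded into it: which
reactions were made unbalanced, which extracellular metabolite lacks an
exchange, the unique minimal gap-fill completion for any dropped subset of
the pathway, the essential genes, and the closed-form FBA optimum
(uptake bound × pathway yield).  This makes balance curation, draft
building, gap-filling, essentiality and sampling all testable without any
external database.

The topology is a linear catabolic pathway — an extracellular nutrient,
a gene-annotated transporter, a chain of 1:1 cytosolic conversions, and a
biomass sink — surrounded by balanced decoy reactions (disconnected from
the pathway, so they can never be part of a minimal completion),
seeded-unbalanced reactions (one stoichiometric coefficient bumped by +1),
and optionally a short/long bypass pair or a biomass cofactor whose
import is flux-cheaper than its synthesis (the two-step media fixture).
Metabolite formulas are synthetic flat strings chosen so the pathway
balances exactly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .constants import BIOMASS_ID, DEFAULT_BOUND
from .database import Metabolite, Reaction, UniversalDatabase
from .media import MediaCondition

_FORMULAS = ["C2H4O2", "C3H6O3", "C4H8O4", "C6H12O6"]
_PATHWAY_FORMULA = "C6H12O6"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one generated fixture (defaults are the study toy)."""

    seed: int = 1
    pathway_length: int = 4  # number of cytosolic conversion reactions
    n_decoy_reactions: int = 5
    n_unbalanced: int = 2
    bypass_spec: tuple[int, int] | None = None  # (short_len, long_len)
    with_cofactor: bool = False
    uptake_rate: float = 10.0

    def __post_init__(self) -> None:
        if not 3 <= self.pathway_length < 40:
            raise ValueError("pathway_length must be in [3, 40)")
        if self.bypass_spec is not None:
            short, long = self.bypass_spec
            if short < 1 or long <= short:
                raise ValueError(
                    "bypass_spec must satisfy 1 <= short_len < long_len"
                )


@dataclass
class GroundTruth:
    """The seeded answers for one fixture database."""

    spec: FixtureSpec
    unbalanced_ids: set[str] = field(default_factory=set)
    missing_exchange_metabolite: str = ""
    exchange_id: str = ""
    transport_id: str = ""
    pathway_reactions: list[str] = field(default_factory=list)  # in pathway order
    genes_of: dict[str, list[str]] = field(default_factory=dict)
    subject_of: dict[str, str] = field(default_factory=dict)  # gene → ortholog id
    essential_genes: set[str] = field(default_factory=set)
    redundant_genes: set[str] = field(default_factory=set)
    media: MediaCondition | None = None
    yield_: float = 1.0
    bridged_reaction: str | None = None
    bypass_short: list[str] = field(default_factory=list)
    bypass_long: list[str] = field(default_factory=list)
    cofactor_import: list[str] = field(default_factory=list)
    cofactor_synthesis: list[str] = field(default_factory=list)

    @property
    def fba_optimum(self) -> float:
        """Closed-form chain-LP optimum: uptake bound × pathway yield."""
        return self.spec.uptake_rate * self.yield_

    def minimal_completion(self, drop: set[str]) -> set[str]:
        """The unique flux-minimal gap-fill set when ``drop`` is unevidenced."""
        completion = set(drop)
        if self.bridged_reaction is not None:
            completion |= set(self.bypass_short)
        return completion


def make_universal_fixture(spec: FixtureSpec) -> tuple[UniversalDatabase, GroundTruth]:
    """Generate a raw (pre-curation) universal database plus its answers.

    Identical specs produce identical databases; all randomness (decoy
    formulas, which coefficient gets perturbed) flows from ``spec.seed``.
    """
    rng = random.Random(spec.seed)
    db = UniversalDatabase(provenance=f"fixture seed={spec.seed}")
    gt = GroundTruth(spec=spec)
    L = spec.pathway_length

    def met(idx: int, comp: str, formula: str = _PATHWAY_FORMULA) -> str:
        mid = f"cpd{idx:05d}_{comp}"
        if mid not in db.metabolites:
            db.add_metabolite(Metabolite(mid, f"compound {idx}", formula, 0))
        return mid

    # Nutrient, exchange, gene-annotated transporter.
    nutrient_e, nutrient_c = met(1, "e"), met(1, "c")
    gt.exchange_id = "EX_cpd00001_e"
    db.add_reaction(Reaction(gt.exchange_id, {nutrient_e: -1.0},
                             name="nutrient exchange", source="exchange"))
    gt.transport_id = "rxn00001_c"
    db.add_reaction(Reaction(gt.transport_id, {nutrient_e: -1.0, nutrient_c: 1.0},
                             name="nutrient transport", lower_bound=0.0))
    gt.pathway_reactions.append(gt.transport_id)
    gt.genes_of[gt.transport_id] = ["g00001"]

    # Cytosolic conversion chain M1 → M2 → ... → M(L+1); biomass eats M(L+1).
    redundant_idx = 3  # rxn00003_c carries an OR pair of isozymes
    bridged_idx = L + 1 if spec.bypass_spec else None  # last chain reaction
    chain_mets = [nutrient_c] + [met(k, "c") for k in range(2, L + 2)]
    for k in range(2, L + 2):
        rid = f"rxn{k:05d}_c"
        stoich = {chain_mets[k - 2]: -1.0, chain_mets[k - 1]: 1.0}
        if k == bridged_idx:
            # The bridged step is deliberately absent from the database;
            # only the bypass routes below can close this gap.
            gt.bridged_reaction = rid
            continue
        db.add_reaction(Reaction(rid, stoich, name=f"chain step {k - 1}",
                                 lower_bound=0.0))
        gt.pathway_reactions.append(rid)
        genes = [f"g{k:05d}"]
        if k == redundant_idx:
            genes.append(f"g{k:05d}b")
            gt.redundant_genes = set(genes)
        gt.genes_of[rid] = genes

    precursor = chain_mets[-1]
    biomass_stoich = {precursor: -1.0}
    gt.yield_ = 1.0

    # Optional short/long bypass pair around the bridged step.
    if spec.bypass_spec:
        short_len, long_len = spec.bypass_spec
        src, dst = chain_mets[-2], chain_mets[-1]
        for prefix, base_idx, length, out_list in (
            ("short", 300, short_len, gt.bypass_short),
            ("long", 400, long_len, gt.bypass_long),
        ):
            nodes = [src] + [met(base_idx + j, "c") for j in range(1, length)] + [dst]
            for j in range(length):
                rid = f"rxn{base_idx + j:05d}_c"
                db.add_reaction(Reaction(
                    rid, {nodes[j]: -1.0, nodes[j + 1]: 1.0},
                    name=f"{prefix} bypass step {j + 1}", lower_bound=0.0))
                out_list.append(rid)

    # Optional biomass cofactor: import (2 candidate reactions) is
    # flux-cheaper than the 3-step synthesis from the first chain
    # intermediate, so complete-media gap-filling imports it and
    # minimal-media gap-filling must then add the synthesis chain.
    if spec.with_cofactor:
        cof_e, cof_c = met(50, "e"), met(50, "c")
        db.add_reaction(Reaction("EX_cpd00050_e", {cof_e: -1.0},
                                 name="cofactor exchange", source="exchange"))
        db.add_reaction(Reaction("rxn00050_c", {cof_e: -1.0, cof_c: 1.0},
                                 name="cofactor transport"))
        gt.cofactor_import = ["EX_cpd00050_e", "rxn00050_c"]
        nodes = [chain_mets[1], met(51, "c"), met(52, "c"), cof_c]
        for j in range(3):
            rid = f"rxn{51 + j:05d}_c"
            db.add_reaction(Reaction(rid, {nodes[j]: -1.0, nodes[j + 1]: 1.0},
                                     name=f"cofactor synthesis {j + 1}",
                                     lower_bound=0.0))
            gt.cofactor_synthesis.append(rid)
        biomass_stoich[cof_c] = -1.0
        gt.yield_ = 0.5  # two nutrient units per biomass unit

    db.biomass_template = Reaction(BIOMASS_ID, biomass_stoich, name="biomass",
                                   lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                                   source="biomass")

    # Balanced decoys: disconnected A→B pairs that can never help growth.
    for i in range(spec.n_decoy_reactions):
        formula = rng.choice(_FORMULAS)
        a = met(101 + 2 * i, "c", formula)
        b = met(102 + 2 * i, "c", formula)
        db.add_reaction(Reaction(f"rxn{101 + i:05d}_c", {a: -1.0, b: 1.0},
                                 name=f"decoy {i + 1}", lower_bound=0.0))

    # Seeded-unbalanced reactions: one coefficient bumped by +1.
    for i in range(spec.n_unbalanced):
        formula = rng.choice(_FORMULAS)
        a = met(201 + 2 * i, "c", formula)
        b = met(202 + 2 * i, "c", formula)
        stoich = {a: -1.0, b: 1.0}
        bumped = rng.choice([a, b])
        stoich[bumped] += 1.0
        if stoich[bumped] == 0:  # -1 + 1: keep it nonzero, bump further
            stoich[bumped] = 1.0
        rid = f"rxn{201 + i:05d}_c"
        db.add_reaction(Reaction(rid, stoich, name=f"unbalanced {i + 1}",
                                 lower_bound=0.0))
        gt.unbalanced_ids.add(rid)

    # An extracellular orphan whose exchange curation must create.
    orphan_e, orphan_c = met(99, "e"), met(99, "c")
    db.add_reaction(Reaction("rxn00099_c", {orphan_e: -1.0, orphan_c: 1.0},
                             name="orphan transport"))
    gt.missing_exchange_metabolite = orphan_e

    gt.media = MediaCondition("minimal", {nutrient_e: spec.uptake_rate})
    counter = 0
    for rid in gt.pathway_reactions:
        for g in gt.genes_of[rid]:
            counter += 1
            gt.subject_of[g] = f"K{counter:05d}"
    gt.essential_genes = {
        g for genes in gt.genes_of.values() for g in genes
    } - gt.redundant_genes
    return db, gt


def make_hit_fixture(
    gt: GroundTruth,
    drop: set[str] = frozenset(),
    hits_path=None,
    map_path=None,
):
    """Synthetic alignment hits covering the pathway minus ``drop``.

    Emits one high-confidence outfmt-6 row per (gene, pathway reaction)
    pair whose reaction is not dropped, plus the gene→reaction map that
    routes each synthetic ortholog id back to its reaction.  The dropped
    set is the known gap-fill answer (see
    :meth:`GroundTruth.minimal_completion`).
    """
    unknown = drop - set(gt.pathway_reactions)
    if unknown:
        raise ValueError(f"drop contains non-pathway reactions: {sorted(unknown)}")
    rows: list[str] = []
    mapping: dict[str, list[str]] = {}
    for rid in gt.pathway_reactions:
        for gene in gt.genes_of[rid]:
            subject = gt.subject_of[gene]
            mapping.setdefault(subject, []).append(rid)
            if rid in drop:
                continue
            rows.append("\t".join([
                gene, subject, "99.0", "300", "1", "0", "1", "300",
                "1", "300", "1e-80", "500.0",
            ]))
    from .annotation import GeneReactionMap

    grm = GeneReactionMap(mapping)
    if hits_path is not None:
        with open(hits_path, "w") as fh:
            fh.write("\n".join(rows) + ("\n" if rows else ""))
    if map_path is not None:
        import json

        with open(map_path, "w") as fh:
            json.dump(grm.mapping, fh, indent=1)
    return rows, grm
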