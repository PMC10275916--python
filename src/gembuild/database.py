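"""Universal reaction database: records, balance checking and curation.

The universal database is the pool of namespaced reactions (ModelSEED-style
``rxn#####_c`` / ``cpd#####_c`` ids) from which draft models draw their
gene-annotated reactions and from which the gap-filler draws candidates.
Before use the raw database is curated: elementally or charge unbalanced
reactions are removed, missing exchange reactions for extracellular
metabolites are added, and a biomass template is installed as the growth
objective.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from .constants import BIOMASS_ID, DEFAULT_BOUND

logger = logging.getLogger(__name__)

# Token grammar for flat elemental formulas: element symbol then optional count.
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_FORMULA = re.compile(r"(?:[A-Z][a-z]?\d*)+\Z")

#: Allowed reaction provenance tags.
SOURCES = ("gene_annotated", "gapfilled", "exchange", "biomass", "media_added")


class DatabaseError(ValueError):
    """Raised for unresolvable ids or structurally invalid databases."""


def parse_formula(formula: str | None) -> dict[str, int] | None:
    """Parse a flat elemental formula into an element→count map.

    The grammar accepts sequences of ``Symbol[count]`` tokens where a symbol
    is an upper-case letter optionally followed by one lower-case letter
    (``H``, ``He``, and pseudo-elements such as ``R`` are all treated as
    literal symbols that must cancel across a reaction).  Any formula
    containing characters outside ``[A-Za-z0-9]`` — ``*``, parentheses,
    charges — or otherwise failing the token grammar yields ``None``
    ("undetermined"); parsing never raises.

    >>> parse_formula("C6H12O6")
    {'C': 6, 'H': 12, 'O': 6}
    """
    if not formula or not _FORMULA.match(formula):
        return None
    counts: dict[str, int] = {}
    for symbol, digits in _TOKEN.findall(formula):
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    return counts


@dataclass(frozen=True)
class Metabolite:
    """A namespaced metabolite record (``cpd#####_c`` / ``cpd#####_e``)."""

    id: str
    name: str = ""
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not (self.id.endswith("_c") or self.id.endswith("_e")):
            raise DatabaseError(
                f"metabolite id {self.id!r} must end with a '_c' or '_e' "
                "compartment suffix"
            )

    @property
    def compartment(self) -> str:
        return self.id[-1]

    @property
    def base_id(self) -> str:
        """Compound id with the compartment suffix stripped."""
        return self.id[:-2]


@dataclass(frozen=True)
class Reaction:
    """A namespaced reaction record with stoichiometry, bounds and GPR.

    ``stoichiometry`` maps metabolite id → signed coefficient (negative =
    consumed).  ``source`` records provenance; exchange reactions carry a
    single extracellular metabolite with coefficient −1.
    """

    id: str
    stoichiometry: Mapping[str, float]
    name: str = ""
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    source: str = "gene_annotated"

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise DatabaseError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.source not in SOURCES:
            raise DatabaseError(f"reaction {self.id}: unknown source {self.source!r}")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise DatabaseError(f"reaction {self.id}: zero stoichiometric coefficient")
        if self.source == "exchange":
            items = list(self.stoichiometry.items())
            if len(items) != 1 or items[0][1] != -1 or not items[0][0].endswith("_e"):
                raise DatabaseError(
                    f"exchange reaction {self.id} must consume exactly one "
                    "extracellular metabolite with coefficient -1"
                )
        if self.source == "gapfilled" and self.gpr:
            raise DatabaseError(f"gap-filled reaction {self.id} must have an empty GPR")

    @property
    def is_exchange(self) -> bool:
        return self.source == "exchange" or self.id.startswith("EX_")


@dataclass
class BalanceEntry:
    """Balance verdict for one reaction.

    Deltas are product side minus substrate side; a reaction is balanced
    iff every element delta and the charge delta is exactly zero.
    Exchange, biomass and transport-of-identical-species reactions are
    exempt from removal (they are unbalanced by construction) and are
    recorded as balanced with ``exempt=True``.
    """

    reaction_id: str
    verdict: str  # "balanced" | "unbalanced" | "undetermined"
    element_deltas: dict[str, float] = field(default_factory=dict)
    charge_delta: float | None = None
    exempt: bool = False


class BalanceReport(dict):
    """Mapping reaction id → :class:`BalanceEntry` with a TSV dump."""

    @property
    def unbalanced_ids(self) -> set[str]:
        return {r for r, e in self.items() if e.verdict == "unbalanced"}

    @property
    def undetermined_ids(self) -> set[str]:
        return {r for r, e in self.items() if e.verdict == "undetermined"}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("reaction_id\tverdict\texempt\telement_deltas\tcharge_delta\n")
            for rid in sorted(self):
                e = self[rid]
                deltas = ";".join(
                    f"{el}:{d:g}" for el, d in sorted(e.element_deltas.items()) if d
                )
                cd = "" if e.charge_delta is None else f"{e.charge_delta:g}"
                fh.write(f"{rid}\t{e.verdict}\t{int(e.exempt)}\t{deltas}\t{cd}\n")


class UniversalDatabase:
    """Curated pool of metabolites and reactions plus a biomass template."""

    def __init__(
        self,
        metabolites: Iterable[Metabolite] = (),
        reactions: Iterable[Reaction] = (),
        biomass_template: Reaction | None = None,
        provenance: str = "",
    ) -> None:
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.biomass_template = biomass_template
        self.provenance = provenance
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)

    # -- construction -----------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise DatabaseError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise DatabaseError(f"duplicate reaction id {rxn.id}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise DatabaseError(
                    f"reaction {rxn.id} references unknown metabolite {mid}"
                )
        self.reactions[rxn.id] = rxn

    def copy(self) -> "UniversalDatabase":
        db = UniversalDatabase(provenance=self.provenance)
        db.metabolites = dict(self.metabolites)
        db.reactions = dict(self.reactions)
        db.biomass_template = self.biomass_template
        return db

    # -- queries ----------------------------------------------------------

    def extracellular_metabolites(self) -> set[str]:
        """Ids of ``_e`` metabolites referenced by at least one reaction."""
        out: set[str] = set()
        for rxn in self.reactions.values():
            out.update(m for m in rxn.stoichiometry if m.endswith("_e"))
        return out

    def exchange_for(self, met_id: str) -> Reaction | None:
        return self.reactions.get(f"EX_{met_id}")

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "provenance": self.provenance,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "formula": m.formula,
                    "charge": m.charge,
                }
                for m in sorted(self.metabolites.values(), key=lambda m: m.id)
            ],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "stoichiometry": dict(sorted(r.stoichiometry.items())),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gpr": r.gpr,
                    "source": r.source,
                }
                for r in sorted(self.reactions.values(), key=lambda r: r.id)
            ],
            "biomass": None
            if self.biomass_template is None
            else {
                "id": self.biomass_template.id,
                "name": self.biomass_template.name,
                "stoichiometry": dict(sorted(self.biomass_template.stoichiometry.items())),
                "lower_bound": self.biomass_template.lower_bound,
                "upper_bound": self.biomass_template.upper_bound,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "UniversalDatabase":
        doc = json.loads(Path(path).read_text())
        db = cls(provenance=doc.get("provenance", ""))
        for m in doc["metabolites"]:
            db.add_metabolite(
                Metabolite(m["id"], m.get("name", ""), m.get("formula"), m.get("charge"))
            )
        for r in doc["reactions"]:
            db.add_reaction(
                Reaction(
                    r["id"],
                    r["stoichiometry"],
                    r.get("name", ""),
                    r.get("lower_bound", -DEFAULT_BOUND),
                    r.get("upper_bound", DEFAULT_BOUND),
                    r.get("gpr", ""),
                    r.get("source", "gene_annotated"),
                )
            )
        bm = doc.get("biomass")
        if bm is not None:
            db.biomass_template = Reaction(
                bm["id"],
                bm["stoichiometry"],
                bm.get("name", "biomass"),
                bm.get("lower_bound", 0.0),
                bm.get("upper_bound", DEFAULT_BOUND),
                source="biomass",
            )
        return db

    @classmethod
    def from_tsv(
        cls, reactions_path: str | Path, metabolites_path: str | Path
    ) -> "UniversalDatabase":
        """Read ModelSEED-dialect TSV dictionaries.

        Metabolite columns: id, name, formula, charge.  Reaction columns:
        id, name, stoichiometry (``coeff:cpd_id;...``), lower_bound,
        upper_bound, gpr, source — missing trailing columns take defaults.
        """
        db = cls(provenance=f"tsv:{reactions_path}")
        for row in _tsv_rows(metabolites_path):
            charge = row[3] if len(row) > 3 else ""
            db.add_metabolite(
                Metabolite(
                    row[0],
                    row[1] if len(row) > 1 else "",
                    (row[2] or None) if len(row) > 2 else None,
                    int(charge) if charge not in ("", "null", "None") else None,
                )
            )
        for row in _tsv_rows(reactions_path):
            stoich: dict[str, float] = {}
            for term in row[2].split(";"):
                if not term:
                    continue
                coeff, mid = term.split(":", 1)
                stoich[mid] = float(coeff)
            db.add_reaction(
                Reaction(
                    row[0],
                    stoich,
                    row[1] if len(row) > 1 else "",
                    float(row[3]) if len(row) > 3 and row[3] else -DEFAULT_BOUND,
                    float(row[4]) if len(row) > 4 and row[4] else DEFAULT_BOUND,
                    row[5] if len(row) > 5 else "",
                    row[6] if len(row) > 6 and row[6] else "gene_annotated",
                )
            )
        return db


def _tsv_rows(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        header = True
        for line in fh:
            line = line.rstrip("\n")
            if header:
                header = False
                continue
            if line:
                yield line.split("\t")


# -- balance checking ------------------------------------------------------


def _is_identity_transport(rxn: Reaction) -> bool:
    """True when the reaction only moves compounds between compartments.

    Grouping metabolites by their compartment-stripped compound id, every
    group's coefficients must cancel and at least two compartments must be
    involved (e.g. ``cpd00001_e → cpd00001_c``).
    """
    sums: dict[str, float] = {}
    comps = set()
    for mid, coeff in rxn.stoichiometry.items():
        sums[mid[:-2]] = sums.get(mid[:-2], 0.0) + coeff
        comps.add(mid[-1])
    return len(comps) > 1 and all(abs(s) < 1e-9 for s in sums.values())


def check_balance(
    rxn: Reaction, db: UniversalDatabase, check_charge: bool = True
) -> BalanceEntry:
    """Elemental (and optionally charge) balance verdict for one reaction.

    Exchange and biomass reactions, and pure inter-compartment transports of
    identical species, are unbalanced by construction and are exempt.  A
    reaction whose participants lack a parseable formula is ``undetermined``
    (never removed by curation); likewise a mass-balanced reaction whose
    charges are not all known when charge checking is on.
    """
    for mid in rxn.stoichiometry:
        if mid not in db.metabolites:
            raise DatabaseError(
                f"reaction {rxn.id} references metabolite {mid} absent from database"
            )
    if rxn.is_exchange or rxn.source == "biomass" or rxn.id == BIOMASS_ID:
        return BalanceEntry(rxn.id, "balanced", exempt=True)
    if _is_identity_transport(rxn):
        return BalanceEntry(rxn.id, "balanced", exempt=True)

    deltas: dict[str, float] = {}
    for mid, coeff in rxn.stoichiometry.items():
        counts = parse_formula(db.metabolites[mid].formula)
        if counts is None:
            return BalanceEntry(rxn.id, "undetermined")
        for el, n in counts.items():
            deltas[el] = deltas.get(el, 0.0) + coeff * n
    deltas = {el: d for el, d in deltas.items() if abs(d) > 1e-9}
    if deltas:
        return BalanceEntry(rxn.id, "unbalanced", element_deltas=deltas)

    if check_charge:
        charges = [db.metabolites[mid].charge for mid in rxn.stoichiometry]
        if any(c is None for c in charges):
            return BalanceEntry(rxn.id, "undetermined")
        charge_delta = sum(
            coeff * db.metabolites[mid].charge
            for mid, coeff in rxn.stoichiometry.items()
        )
        if abs(charge_delta) > 1e-9:
            return BalanceEntry(
                rxn.id, "unbalanced", charge_delta=float(charge_delta)
            )
        return BalanceEntry(rxn.id, "balanced", charge_delta=0.0)
    return BalanceEntry(rxn.id, "balanced")


def curate_database(
    raw: UniversalDatabase,
    biomass_template: Reaction | None = None,
    check_charge: bool = True,
) -> tuple[UniversalDatabase, BalanceReport]:
    """Curate a raw universal database.

    Removes every reaction with verdict ``unbalanced`` (undetermined ones
    are retained but flagged in the report), adds an ``EX_<cpd>_e`` exchange
    with bounds ±1000 for every extracellular metabolite lacking one, and
    installs the biomass template as reaction ``biomass``.  Idempotent:
    curating a curated database changes nothing but the audit report.
    """
    report = BalanceReport()
    curated = UniversalDatabase(provenance=raw.provenance or "curated")
    curated.metabolites = dict(raw.metabolites)
    for rid in sorted(raw.reactions):
        entry = check_balance(raw.reactions[rid], raw, check_charge=check_charge)
        report[rid] = entry
        if entry.verdict != "unbalanced":
            curated.reactions[rid] = raw.reactions[rid]
    if report.unbalanced_ids:
        logger.info(
            "curation removed %d unbalanced reactions", len(report.unbalanced_ids)
        )
    if report.undetermined_ids:
        logger.info(
            "%d reactions have undetermined balance and were retained",
            len(report.undetermined_ids),
        )

    for met_id in sorted(curated.extracellular_metabolites()):
        ex_id = f"EX_{met_id}"
        if ex_id not in curated.reactions:
            curated.reactions[ex_id] = Reaction(
                ex_id,
                {met_id: -1.0},
                name=f"{curated.metabolites[met_id].name or met_id} exchange",
                lower_bound=-DEFAULT_BOUND,
                upper_bound=DEFAULT_BOUND,
                source="exchange",
            )

    template = biomass_template or raw.biomass_template
    if template is None:
        raise DatabaseError("no biomass template configured for curation")
    template = replace(
        template, id=BIOMASS_ID, source="biomass", gpr="",
        lower_bound=max(template.lower_bound, 0.0),
    )
    for mid in template.stoichiometry:
        if mid not in curated.metabolites:
            raise DatabaseError(f"biomass template references unknown metabolite {mid}")
    curated.reactions[BIOMASS_ID] = template
    curated.biomass_template = template

    if not curated.reactions:
        raise DatabaseError("curation produced an empty reaction set")
    return curated, report
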