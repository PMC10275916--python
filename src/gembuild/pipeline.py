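"""End-to-end reconstruction pipeline and the ``reconstruct()`` entry point.

Three input types are supported: an annotated protein FASTA (Type 1,
aligned by an external aligner hook), a tabular protein-alignment hit
table (Type 2), or an existing SBML model to be further gap-filled
(Type 3).  All paths converge on the two-step parsimonious-flux gap-fill
and an SBML + run-report output.  ``reconstruct()`` mirrors the CLI
parameter-for-parameter so models can be built directly inside a Python
session and analysed with COBRApy immediately.
"""

from __future__ import annotations

import json
import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import cobra

from .annotation import (
    DEFAULT_MAX_EVALUE,
    DEFAULT_MIN_BITSCORE,
    GeneReactionMap,
    build_draft,
    filter_hits,
    hits_to_evidence,
    parse_hits,
)
from .database import UniversalDatabase, curate_database
from .gapfill import DEFAULT_MIN_GROWTH, GapfillResult, two_step_gapfill
from .media import MediaCondition, resolve_media
from .sbml import read_sbml, write_sbml

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Unusable pipeline input (missing file, unknown type, no aligner)."""


@dataclass
class RunReport:
    """Model statistics for one pipeline run.

    Counts are reported for the draft and the final model so the user can
    see what gap-filling contributed, together with the final biomass
    objective flux as the success check.
    """

    input_type: int = 0
    input_file: str = ""
    media_name: str = ""
    draft_counts: dict[str, int] = field(default_factory=dict)
    final_counts: dict[str, int] = field(default_factory=dict)
    gapfilled_step1: int = 0
    gapfilled_step2: int = 0
    final_objective_flux: float = 0.0
    parameters: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def gapfilled_count(self) -> int:
        return self.gapfilled_step1 + self.gapfilled_step2

    def validate(self) -> None:
        for key in ("genes", "reactions", "metabolites"):
            if self.final_counts.get(key, 0) < self.draft_counts.get(key, 0):
                raise ValueError(f"final {key} count below draft count")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "input_type": self.input_type,
            "input_file": self.input_file,
            "media": self.media_name,
            "draft": self.draft_counts,
            "final": self.final_counts,
            "gapfilled": {
                "step1": self.gapfilled_step1,
                "step2": self.gapfilled_step2,
                "total": self.gapfilled_count,
            },
            "final_objective_flux": self.final_objective_flux,
            "parameters": self.parameters,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _counts(model: cobra.Model) -> dict[str, int]:
    return {
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "metabolites": len(model.metabolites),
    }


def _load_database(universal_db, curate: bool) -> UniversalDatabase:
    if isinstance(universal_db, UniversalDatabase):
        db = universal_db
    else:
        db = UniversalDatabase.from_json(universal_db)
    if curate:
        db, _ = curate_database(db)
    return db


def align_fasta(fasta: str | Path, reference_db: str | Path | None, out: Path) -> Path:
    """Type 1 hook: align protein FASTA with an external aligner, if present.

    Looks for ``diamond`` then ``blastp`` on PATH and produces a tabular
    (outfmt 6) hit table.  Without an aligner — or without a reference
    database to align against — raises an instructive error pointing the
    user at Type 2 input.
    """
    aligner = shutil.which("diamond") or shutil.which("blastp")
    if aligner is None or reference_db is None:
        raise InputError(
            "Type 1 input needs an external protein aligner (diamond or "
            "blastp) on PATH and an --align-db reference. Neither a bundled "
            "aligner nor a reference database ships with this package: run "
            "the alignment yourself and supply the tabular hit table as "
            "Type 2 input instead."
        )
    if aligner.endswith("diamond"):
        cmd = [aligner, "blastp", "-q", str(fasta), "-d", str(reference_db),
               "-o", str(out), "--outfmt", "6"]
    else:
        cmd = [aligner, "-query", str(fasta), "-db", str(reference_db),
               "-out", str(out), "-outfmt", "6"]
    logger.info("running aligner: %s", " ".join(cmd))
    subprocess.run(cmd, check=True)
    return out


def reconstruct(
    input_file: str | Path,
    file_type: int,
    universal_db: "str | Path | UniversalDatabase",
    gene_reaction_map: "str | Path | GeneReactionMap | None" = None,
    media: "str | MediaCondition | None" = None,
    min_growth: float = DEFAULT_MIN_GROWTH,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_bitscore: float = DEFAULT_MIN_BITSCORE,
    best_per_subject: bool = True,
    gene_weight: float = 0.0,
    out: str | Path | None = None,
    save_draft: str | Path | None = None,
    align_db: str | Path | None = None,
    curate: bool = True,
    seed: int = 0,
) -> tuple[cobra.Model, RunReport]:
    """Build a gap-filled genome-scale model from one of the three inputs.

    Returns the final COBRApy model and the run report; when ``out`` is
    given the model is also written as SBML L3+FBC and the report as JSON
    next to it.  ``seed`` feeds any downstream stochastic analysis
    (e.g. flux sampling); reconstruction itself is deterministic.
    """
    input_file = Path(input_file)
    if not input_file.exists():
        raise InputError(f"input file not found: {input_file}")
    if file_type not in (1, 2, 3):
        raise InputError(f"unknown input type {file_type}; expected 1, 2 or 3")

    media_condition = resolve_media(media)
    db = _load_database(universal_db, curate=curate)
    report = RunReport(
        input_type=file_type,
        input_file=str(input_file),
        media_name=media_condition.name,
        parameters={
            "min_growth": min_growth, "max_evalue": max_evalue,
            "min_bitscore": min_bitscore, "best_per_subject": best_per_subject,
            "gene_weight": gene_weight, "seed": seed,
        },
    )

    if file_type == 1:
        hits_path = input_file.with_suffix(".hits.tsv")
        align_fasta(input_file, align_db, hits_path)
        input_file, file_type = hits_path, 2

    if file_type == 2:
        if gene_reaction_map is None:
            raise InputError("Type 2 input requires a gene-reaction map")
        grm = (
            gene_reaction_map
            if isinstance(gene_reaction_map, GeneReactionMap)
            else GeneReactionMap.from_file(gene_reaction_map)
        )
        grm.validate(db)
        hits = filter_hits(
            parse_hits(input_file),
            max_evalue=max_evalue, min_bitscore=min_bitscore,
            best_per_subject=best_per_subject,
        )
        evidence = hits_to_evidence(hits, grm)
        draft = build_draft(evidence, db, media_condition)
    else:
        draft = read_sbml(input_file)

    report.draft_counts = _counts(draft)
    if save_draft:
        write_sbml(draft, save_draft)

    final, gf = two_step_gapfill(
        draft, db, media_condition,
        gene_weight=gene_weight, min_growth=min_growth,
    )
    final.id = input_file.stem

    report.final_counts = _counts(final)
    report.gapfilled_step1 = len(gf.added_step1)
    report.gapfilled_step2 = len(gf.added_step2)
    report.final_objective_flux = gf.objective_flux_final
    report.validate()

    if out:
        out = Path(out)
        write_sbml(final, out)
        report.to_json(out.with_suffix(".report.json"))
        gf.to_tsv(out.with_suffix(".gapfill.tsv"))
    return final, report
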