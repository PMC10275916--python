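"""Media conditions: named exchange-bound profiles applied to models.

A medium either names explicit extracellular metabolites with maximal
uptake rates, or is the distinguished COMPLETE medium in which every
exchange reaction is fully open (lower bound −1000).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra

from .constants import DEFAULT_BOUND, DEFAULT_UPTAKE

logger = logging.getLogger(__name__)


class _Complete:
    """Sentinel uptake profile meaning 'every exchange fully open'."""

    def __repr__(self) -> str:  # pragma: no cover
        return "COMPLETE"


COMPLETE = _Complete()


@dataclass(frozen=True)
class MediaCondition:
    """A named uptake profile: metabolite id → max uptake rate, or COMPLETE."""

    name: str
    uptake: Mapping[str, float] | _Complete = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.is_complete:
            bad = {m: r for m, r in self.uptake.items() if r <= 0}
            if bad:
                raise ValueError(f"uptake rates must be strictly positive: {bad}")

    @property
    def is_complete(self) -> bool:
        return isinstance(self.uptake, _Complete)

    @classmethod
    def complete(cls) -> "MediaCondition":
        return cls("complete", COMPLETE)

    @classmethod
    def from_file(cls, path: str | Path) -> "MediaCondition":
        """Load a medium from JSON.

        Accepts ``{"name": ..., "uptake": {met_id: rate, ...}}`` or a bare
        list of metabolite ids (each assigned the default uptake rate).
        """
        doc = json.loads(Path(path).read_text())
        if isinstance(doc, list):
            return cls(Path(path).stem, {m: DEFAULT_UPTAKE for m in doc})
        uptake = doc.get("uptake", {})
        if uptake == "complete":
            return cls.complete()
        return cls(doc.get("name", Path(path).stem), dict(uptake))


def resolve_media(spec: "str | MediaCondition | None") -> MediaCondition:
    """Turn a CLI-style media argument into a MediaCondition.

    ``None`` or the string ``"complete"`` → the complete medium; any other
    string is treated as a path to a media file.
    """
    if spec is None:
        return MediaCondition.complete()
    if isinstance(spec, MediaCondition):
        return spec
    if spec.lower() == "complete":
        return MediaCondition.complete()
    return MediaCondition.from_file(spec)


def set_media(model: cobra.Model, media: MediaCondition) -> cobra.Model:
    """Apply a medium to a model's exchange reactions, in place.

    COMPLETE opens every exchange (lower bound −1000); otherwise every
    exchange lower bound is closed to 0 except the media metabolites, whose
    exchanges get lower bound −uptake.  Exchange upper bounds are always
    1000.  Media metabolites without an exchange in the model are skipped
    with a warning.
    """
    exchanges = [r for r in model.reactions if r.id.startswith("EX_")]
    if media.is_complete:
        for rxn in exchanges:
            rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
        return model
    by_id = {r.id: r for r in exchanges}
    for rxn in exchanges:
        rxn.bounds = (0.0, DEFAULT_BOUND)
    for met_id, rate in media.uptake.items():
        rxn = by_id.get(f"EX_{met_id}")
        if rxn is None:
            logger.warning(
                "media %s: metabolite %s has no exchange reaction in the model; "
                "skipped", media.name, met_id,
            )
            continue
        rxn.bounds = (-float(rate), DEFAULT_BOUND)
    return model
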