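"""Composed multi-stage runs used by the analysis drivers and validation.

These helpers only chain the public stage functions; no computation of their
own beyond bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .motif import CbsHit, CbsMotifModel, scan_genome
from .junctions import (
    TELOMERE_UNIT,
    AnchoredEnd,
    FunctionalCbs,
    JunctionMeasurement,
    TelomerizedEnd,
    anchor_ends,
    find_telomerized_ends,
    measure_junction,
    validate_functional_cbs,
)

__all__ = ["JunctionSurvey", "junction_survey"]


@dataclass
class JunctionSurvey:
    """All intermediate products of a MAC-end-to-Cbs mapping run."""

    ends: list[TelomerizedEnd]
    anchored: list[AnchoredEnd]
    functional: list[FunctionalCbs]
    unassigned: list[AnchoredEnd]
    measurements: list[JunctionMeasurement] = field(default_factory=list)

    @property
    def two_sided(self) -> list[JunctionMeasurement]:
        return [m for m in self.measurements if m.two_sided]


def junction_survey(
    mic_genome,
    mac_scaffolds,
    hits: Sequence[CbsHit] | None = None,
    model: CbsMotifModel | None = None,
    telomere_unit: str = TELOMERE_UNIT,
    min_repeats: int = 3,
    k: int = 30,
    window: int = 50,
    extra_ends: Sequence[TelomerizedEnd] = (),
) -> JunctionSurvey:
    """Scan (if needed), detect/anchor telomerized ends, validate and measure."""
    if hits is None:
        hits = scan_genome(mic_genome, model)
    ends = find_telomerized_ends(mac_scaffolds, telomere_unit, min_repeats, k)
    ends = list(ends) + list(extra_ends)
    anchored = anchor_ends(ends, mic_genome)
    functional, unassigned = validate_functional_cbs(hits, anchored, window)
    measurements = [measure_junction(f) for f in functional]
    return JunctionSurvey(ends, anchored, functional, unassigned, measurements)
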