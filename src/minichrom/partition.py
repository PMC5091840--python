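"""Cbs-delimited partitioning of germline contigs into putative minichromosome sections.

Each copy of the breakage element splits a MIC contig; ``n`` copies on a
contig define ``n + 1`` sections, numbered left to right starting at 0 and
named ``echr<contig>.<index>``.  A section bounded by Cbs on both sides is a
complete putative minichromosome ("cbs_bounded"); one bounded by a contig end
on either side is "cbs_terminal" (the assembly truncates it).  Contigs with
no Cbs copy produce no sections and are reported separately.

Sections can be matched to fully telomerized MAC scaffolds (full-length
minichromosomes) by anchoring both telomere-stripped scaffold ends inside a
single section; the length difference (section minus stripped scaffold) then
estimates the internally eliminated sequence (IES) content plus the small
breakage flank losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .motif import CbsHit
from .junctions import KmerIndex, find_telomerized_ends, anchor_end, TELOMERE_UNIT

__all__ = [
    "Section",
    "SectionSummary",
    "ScaffoldMatch",
    "resolve_overlaps",
    "partition_contig",
    "partition_genome",
    "summarize_sections",
    "match_sections_to_scaffolds",
    "ies_content_estimate",
]


@dataclass
class Section:
    """A Cbs-delimited interval of a MIC contig (0-based, half-open)."""

    name: str
    contig_id: str
    start: int
    end: int
    left_boundary: str  # "cbs" | "contig_end"
    right_boundary: str  # "cbs" | "contig_end"
    fate: str = "unknown"  # "retained" | "eliminated" | "ambiguous" | "unknown"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def bounded_class(self) -> str:
        if self.left_boundary == "cbs" and self.right_boundary == "cbs":
            return "cbs_bounded"
        return "cbs_terminal"


def resolve_overlaps(hits: Sequence[CbsHit]) -> list[CbsHit]:
    """Greedy left-to-right resolution of overlapping hits on one contig.

    The leftmost hit is kept and the next accepted hit must start at or after
    its end; zero-length sections between adjacent copies are permitted.
    """
    out: list[CbsHit] = []
    for h in sorted(hits, key=lambda h: h.start):
        if not out or h.start >= out[-1].end:
            out.append(h)
    return out


def partition_contig(
    contig_id: str, contig_length: int, hits: Sequence[CbsHit]
) -> list[Section]:
    """Split one contig into sections around its (overlap-resolved) Cbs copies.

    ``n`` hits produce ``n + 1`` sections named ``echr<contig_id>.0`` ..
    ``echr<contig_id>.n``; a contig with no hit produces no sections.
    """
    kept = resolve_overlaps(hits)
    for h in kept:
        if h.contig_id != contig_id:
            raise ValueError(f"hit on {h.contig_id} passed with contig {contig_id}")
        if h.end > contig_length:
            raise ValueError(f"hit at {h.start} extends past contig end {contig_length}")
    if not kept:
        return []
    sections: list[Section] = []
    bounds = [0] + [b for h in kept for b in (h.start, h.end)] + [contig_length]
    n = len(kept)
    for i in range(n + 1):
        start, end = bounds[2 * i], bounds[2 * i + 1]
        sections.append(
            Section(
                name=f"echr{contig_id}.{i}",
                contig_id=contig_id,
                start=start,
                end=end,
                left_boundary="contig_end" if i == 0 else "cbs",
                right_boundary="contig_end" if i == n else "cbs",
            )
        )
    return sections


def partition_genome(
    contig_lengths: Mapping[str, int], hits: Sequence[CbsHit]
) -> tuple[list[Section], list[str]]:
    """Partition every contig; returns (all sections, ids of Cbs-free contigs)."""
    by_contig: dict[str, list[CbsHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    sections: list[Section] = []
    no_cbs: list[str] = []
    for cid, length in contig_lengths.items():
        secs = partition_contig(cid, length, by_contig.get(cid, []))
        if secs:
            sections.extend(secs)
        else:
            no_cbs.append(cid)
    return sections, no_cbs


@dataclass
class SectionSummary:
    """Counts, lengths and genome fractions of a section set."""

    n_sections: int
    n_by_class: dict[str, int]
    n_by_fate: dict[str, int]
    total_length: int
    length_by_class: dict[str, int]
    length_by_fate: dict[str, int]
    genome_size: int
    size_bin_edges: list[float] = field(default_factory=list)
    size_bin_counts: dict[str, list[int]] = field(default_factory=dict)

    @property
    def fraction_of_genome(self) -> float:
        return self.total_length / self.genome_size

    def class_fraction_of_sections(self, cls: str) -> float:
        return self.length_by_class.get(cls, 0) / self.total_length

    def class_fraction_of_genome(self, cls: str) -> float:
        return self.length_by_class.get(cls, 0) / self.genome_size

    def fate_fraction_of_sections(self, fate: str) -> float:
        return self.length_by_fate.get(fate, 0) / self.total_length

    def fate_fraction_of_genome(self, fate: str) -> float:
        return self.length_by_fate.get(fate, 0) / self.genome_size


def summarize_sections(
    sections: Sequence[Section], genome_size: int, n_size_bins: int = 12
) -> SectionSummary:
    """Aggregate section counts/lengths by boundedness class and fate.

    The size histogram uses log10-spaced bins over the observed length range
    (sections of length 0 are counted in the first bin), with one count row
    per fate so retained and eliminated distributions can be compared.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n_by_class: dict[str, int] = {}
    n_by_fate: dict[str, int] = {}
    length_by_class: dict[str, int] = {}
    length_by_fate: dict[str, int] = {}
    for s in sections:
        n_by_class[s.bounded_class] = n_by_class.get(s.bounded_class, 0) + 1
        n_by_fate[s.fate] = n_by_fate.get(s.fate, 0) + 1
        length_by_class[s.bounded_class] = length_by_class.get(s.bounded_class, 0) + s.length
        length_by_fate[s.fate] = length_by_fate.get(s.fate, 0) + s.length
    total = sum(s.length for s in sections)
    edges: list[float] = []
    counts: dict[str, list[int]] = {}
    lengths = np.array([s.length for s in sections], dtype=float)
    if len(lengths) and lengths.max() > 0:
        lo = max(1.0, lengths[lengths > 0].min())
        hi = lengths.max()
        edge_arr = np.logspace(np.log10(lo), np.log10(hi) + 1e-9, n_size_bins + 1)
        edge_arr[0] = lo  # guard against float drift excluding the minimum
        edges = list(edge_arr)
        for fate in sorted(n_by_fate):
            sel = np.array([s.length for s in sections if s.fate == fate], dtype=float)
            c, _ = np.histogram(np.clip(sel, lo, hi), bins=edges)
            counts[fate] = [int(x) for x in c]
    return SectionSummary(
        n_sections=len(sections),
        n_by_class=n_by_class,
        n_by_fate=n_by_fate,
        total_length=total,
        length_by_class=length_by_class,
        length_by_fate=length_by_fate,
        genome_size=genome_size,
        size_bin_edges=edges,
        size_bin_counts=counts,
    )


@dataclass(frozen=True)
class ScaffoldMatch:
    """A MAC scaffold matched to the section it derives from.

    ``delta`` is section length minus telomere-stripped scaffold length; a
    negative delta (scaffold longer than its section) is flagged as a
    violation of the breakage-without-rearrangement model.
    """

    section_name: str
    scaffold_id: str
    length_section: int
    length_scaffold: int

    @property
    def delta(self) -> int:
        return self.length_section - self.length_scaffold

    @property
    def violation(self) -> bool:
        return self.delta < 0


def match_sections_to_scaffolds(
    sections: Sequence[Section],
    mic_genome,
    scaffolds,
    telomere_unit: str = TELOMERE_UNIT,
    min_repeats: int = 3,
    k: int = 30,
) -> tuple[list[ScaffoldMatch], dict[str, str]]:
    """Match full-length MAC scaffolds (telomeres at both ends) to sections.

    A match requires both telomere-stripped scaffold ends to anchor uniquely
    inside the same section.  Scaffold length excludes the telomere runs.
    Returns (matches, reasons for unmatched scaffolds keyed by scaffold id).
    """
    from .motif import _as_contig_items

    index = KmerIndex(mic_genome, k)
    sec_by_contig: dict[str, list[Section]] = {}
    for s in sections:
        sec_by_contig.setdefault(s.contig_id, []).append(s)

    def containing_section(contig: str, pos: int) -> Section | None:
        for s in sec_by_contig.get(contig, []):
            if s.start <= pos < s.end:
                return s
        return None

    matches: list[ScaffoldMatch] = []
    unmatched: dict[str, str] = {}
    for scaffold_id, seq in _as_contig_items(scaffolds):
        ends = find_telomerized_ends(
            {scaffold_id: seq}, telomere_unit, min_repeats, k
        )
        sides = {e.side: e for e in ends}
        if set(sides) != {"left", "right"}:
            unmatched[scaffold_id] = "not telomerized at both ends"
            continue
        u = len(telomere_unit)
        stripped = len(seq) - (sides["left"].repeat_count + sides["right"].repeat_count) * u
        anchors = [
            anchor_end(sides[side], mic_genome, 0, index=index)
            for side in ("left", "right")
        ]
        if not all(a.unique for a in anchors):
            unmatched[scaffold_id] = "end anchor not unique in MIC"
            continue
        secs = [containing_section(a.contig_id, a.junction_coord) for a in anchors]
        if secs[0] is None or secs[1] is None:
            unmatched[scaffold_id] = "end anchors outside any section"
            continue
        if secs[0].name != secs[1].name:
            unmatched[scaffold_id] = "end anchors in different sections"
            continue
        matches.append(
            ScaffoldMatch(
                section_name=secs[0].name,
                scaffold_id=scaffold_id,
                length_section=secs[0].length,
                length_scaffold=stripped,
            )
        )
    return matches, unmatched


def ies_content_estimate(matches: Iterable[ScaffoldMatch]) -> dict[str, float]:
    """Aggregate section-minus-scaffold deltas as an IES-content estimate."""
    matches = list(matches)
    if not matches:
        raise ValueError("need at least one match")
    total_delta = sum(m.delta for m in matches)
    total_section = sum(m.length_section for m in matches)
    return {
        "n_matches": len(matches),
        "total_delta": float(total_delta),
        "total_section_length": float(total_section),
        "fraction_of_section_length": total_delta / total_section,
    }
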