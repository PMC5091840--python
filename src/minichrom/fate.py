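"""Retained/eliminated classification of sections from somatic read coverage.

Whole-cell DNA reads from mature (vegetatively growing) cells are essentially
MAC reads; mapping them back onto MIC coordinates leaves eliminated
minichromosomes (EMCs) devoid of coverage while retained sections sit near
the MAC-wide average.  The workflow here is:

1. normalize a raw coverage track by its mean over MAC-destined (MDS) bases,
   so retained sequence has normalized coverage ~1;
2. call each section retained/eliminated/ambiguous from the fraction of its
   non-IES bases whose normalized coverage falls below a floor epsilon
   (IES bases are masked first — they are absent from the MAC regardless of
   the section's fate);
3. profile candidate EMCs as 100-bin mean coverage differences between an
   early (conjugation, e.g. 24 hpm) sample and a mature sample, where the
   EMC is still present early and gone later.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .partition import Section

__all__ = [
    "CoverageTrack",
    "FateCall",
    "BinProfile",
    "normalize_coverage",
    "classify_section",
    "classify_sections",
    "combine_fate_calls",
    "emc_difference_profile",
    "fate_confusion",
]

logger = logging.getLogger(__name__)

Intervals = Mapping[str, Sequence[tuple[int, int]]]


@dataclass
class CoverageTrack:
    """Per-base coverage over MIC coordinates for one sample."""

    data: dict[str, np.ndarray]
    sample_label: str = ""
    normalization_constant: float | None = None

    def __post_init__(self) -> None:
        for cid, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {cid}")
            self.data[cid] = arr

    def values(self, contig_id: str, start: int, end: int) -> np.ndarray:
        return self.data[contig_id][start:end]


def _interval_mask(length: int, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s) : min(length, e)] = True
    return mask


def normalize_coverage(track: CoverageTrack, mds_intervals: Intervals) -> CoverageTrack:
    """Divide a track by its mean raw coverage over MDS bases.

    After normalization the MDS-wide mean is 1 by construction, so the
    operation is idempotent.  Raises if the MDS mean is zero.
    """
    total, n = 0.0, 0
    for cid, ivs in mds_intervals.items():
        if cid not in track.data:
            continue
        arr = track.data[cid]
        mask = _interval_mask(len(arr), ivs)
        total += float(arr[mask].sum())
        n += int(mask.sum())
    if n == 0:
        raise ValueError("no MDS bases found on the track's contigs")
    constant = total / n
    if constant == 0:
        raise ValueError("zero mean coverage over MDS bases; cannot normalize")
    return CoverageTrack(
        data={cid: arr / constant for cid, arr in track.data.items()},
        sample_label=track.sample_label,
        normalization_constant=constant,
    )


@dataclass(frozen=True)
class FateCall:
    """Coverage-based fate call for one section."""

    section_name: str
    mean_coverage: float
    fraction_below: float
    call: str  # "retained" | "eliminated" | "ambiguous"
    reason: str | None = None


def classify_section(
    section: Section,
    normalized_track: CoverageTrack,
    ies_intervals: Intervals | None = None,
    epsilon: float = 0.05,
    f_elim: float = 0.95,
    f_ret: float = 0.5,
) -> FateCall:
    """Call one section from the below-epsilon fraction of its non-IES bases.

    eliminated if the fraction >= ``f_elim``; retained if <= ``f_ret``;
    ambiguous otherwise (or when the section is entirely IES).  ``epsilon``
    tolerates a sporadic mismapping floor over truly absent DNA.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if not 0 < f_ret <= f_elim <= 1:
        raise ValueError("need 0 < f_ret <= f_elim <= 1")
    vals = normalized_track.values(section.contig_id, section.start, section.end)
    keep = np.ones(len(vals), dtype=bool)
    if ies_intervals:
        ivs = [
            (s - section.start, e - section.start)
            for s, e in ies_intervals.get(section.contig_id, [])
            if e > section.start and s < section.end
        ]
        keep &= ~_interval_mask(len(vals), ivs)
    if not keep.any():
        return FateCall(section.name, float("nan"), float("nan"), "ambiguous",
                        reason="section entirely IES")
    vals = vals[keep]
    frac = float((vals < epsilon).mean())
    if frac >= f_elim:
        call = "eliminated"
    elif frac <= f_ret:
        call = "retained"
    else:
        call = "ambiguous"
    return FateCall(section.name, float(vals.mean()), frac, call)


def classify_sections(
    sections: Sequence[Section],
    normalized_tracks: Sequence[CoverageTrack],
    ies_intervals: Intervals | None = None,
    **kwargs,
) -> dict[str, FateCall]:
    """Per-section calls combined across mature-MAC samples.

    A section is eliminated overall only if eliminated in every sample;
    retained only if retained in every sample; otherwise ambiguous.
    """
    per_sample = [
        {s.name: classify_section(s, t, ies_intervals, **kwargs) for s in sections}
        for t in normalized_tracks
    ]
    return {s.name: combine_fate_calls([calls[s.name] for calls in per_sample])
            for s in sections}


def combine_fate_calls(calls: Sequence[FateCall]) -> FateCall:
    """Consensus across samples (unanimity required for a definite call)."""
    if not calls:
        raise ValueError("no calls to combine")
    votes = {c.call for c in calls}
    if len(votes) == 1:
        call = next(iter(votes))
        reason = calls[0].reason if call == "ambiguous" else None
    else:
        call, reason = "ambiguous", "samples disagree"
    return FateCall(
        section_name=calls[0].section_name,
        mean_coverage=float(np.mean([c.mean_coverage for c in calls])),
        fraction_below=float(np.mean([c.fraction_below for c in calls])),
        call=call,
        reason=reason,
    )


@dataclass(frozen=True)
class BinProfile:
    """Binned early-minus-mature coverage difference over one section."""

    section_name: str
    bin_means: np.ndarray
    bin_edges: np.ndarray  # length n_bins + 1, section-relative coordinates
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_means)

    def fraction_below(self, x: float) -> float:
        """Fraction of per-base differences below ``x`` (from the histogram)."""
        total = self.hist_counts.sum()
        sel = self.hist_edges[1:] <= x
        return float(self.hist_counts[sel].sum() / total) if total else float("nan")


def emc_difference_profile(
    section: Section,
    track_early: CoverageTrack,
    track_mature: CoverageTrack,
    n_bins: int = 100,
    hist_edges: np.ndarray | None = None,
) -> BinProfile:
    """Per-bin mean (early - mature) normalized-coverage difference.

    The section is split into ``n_bins`` equal integer-width bins with the
    division remainder absorbed by the final bin.  Sections shorter than
    ``n_bins`` get one bin per base (count reduced, with a warning).  A
    histogram of the per-base differences (default 0.1-wide bins spanning the
    data) is attached for difference-frequency summaries.
    """
    diff = (
        track_early.values(section.contig_id, section.start, section.end)
        - track_mature.values(section.contig_id, section.start, section.end)
    )
    length = len(diff)
    if length == 0:
        raise ValueError("empty section")
    if length < n_bins:
        logger.warning(
            "section %s (%d bp) shorter than %d bins; using %d 1-bp bins",
            section.name, length, n_bins, length,
        )
        n_bins = length
    width = length // n_bins
    edges = np.array([i * width for i in range(n_bins)] + [length])
    means = np.array(
        [diff[edges[i] : edges[i + 1]].mean() for i in range(n_bins)]
    )
    if hist_edges is None:
        lo = min(-0.05, np.floor(diff.min() * 10) / 10)
        hi = max(0.05, np.ceil(diff.max() * 10) / 10)
        hist_edges = np.arange(lo, hi + 0.1, 0.1)
    counts, hist_edges = np.histogram(diff, bins=hist_edges)
    return BinProfile(section.name, means, edges, counts, hist_edges)


def fate_confusion(
    calls: Mapping[str, FateCall | str], truth: Mapping[str, str]
) -> dict[str, float]:
    """Sensitivity/specificity/accuracy of calls against simulator truth.

    "eliminated" is treated as the positive class; ambiguous calls are
    excluded from the denominator (their count is reported).
    """
    missing = set(calls) - set(truth)
    if missing:
        raise ValueError(f"calls without truth: {sorted(missing)[:5]}")
    tp = tn = fp = fn = amb = 0
    for name, call in calls.items():
        label = call.call if isinstance(call, FateCall) else call
        if label == "ambiguous":
            amb += 1
            continue
        true = truth[name]
        if true == "eliminated":
            tp += label == "eliminated"
            fn += label == "retained"
        else:
            tn += label == "retained"
            fp += label == "eliminated"
    n = tp + tn + fp + fn
    return {
        "n": n,
        "n_ambiguous": amb,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / n if n else float("nan"),
    }
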