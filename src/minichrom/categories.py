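"""Per-category ChIP enrichment, gene density and stage-expression tabulation.

Genomic categories here are labelled interval sets over MIC coordinates —
typically MDS (MAC-destined sequence), IES (internal eliminated sequence),
EMC (eliminated minichromosome) and the Cbs-related sections as a whole.
Heterochromatin-mark enrichment (e.g. Pdd1p ChIP) is consumed as a
precomputed per-base fold-enrichment track; the per-category statistic is
the base-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fate import CoverageTrack, _interval_mask

__all__ = [
    "EnrichmentReport",
    "fold_enrichment",
    "gene_density",
    "stage_expression_counts",
    "STAGES",
]

#: Fixed stage vocabulary for expression matrices.
STAGES = ("growth", "2hpm", "8hpm", "16hpm", "2D")

Intervals = Mapping[str, Sequence[tuple[int, int]]]


@dataclass
class EnrichmentReport:
    """Base-weighted mean enrichment per category plus requested ratios."""

    category_means: dict[str, float]
    category_bases: dict[str, int]
    ratios: dict[str, float] = field(default_factory=dict)
    per_interval: dict[str, list[float]] = field(default_factory=dict)


def fold_enrichment(
    chip_track: CoverageTrack,
    annotations: Mapping[str, Intervals],
    ratio_pairs: Sequence[tuple[str, str]] = (),
) -> EnrichmentReport:
    """Mean per-base enrichment for each labelled category.

    ``annotations`` maps label -> {contig -> [(start, end), ...]}.  Ratios
    ``mean_a / mean_b`` are reported for every requested ``(a, b)`` pair.
    Scaling the track by a constant scales all means by it and leaves the
    ratios unchanged.
    """
    means: dict[str, float] = {}
    bases: dict[str, int] = {}
    per_interval: dict[str, list[float]] = {}
    for label, ivs_by_contig in annotations.items():
        total, n = 0.0, 0
        vals: list[float] = []
        for cid, ivs in ivs_by_contig.items():
            if cid not in chip_track.data:
                continue
            arr = chip_track.data[cid]
            for s, e in ivs:
                seg = arr[max(0, s) : min(len(arr), e)]
                if len(seg):
                    total += float(seg.sum())
                    n += len(seg)
                    vals.append(float(seg.mean()))
        if n == 0:
            raise ValueError(f"category {label!r} covers no bases on the track")
        means[label] = total / n
        bases[label] = n
        per_interval[label] = vals
    ratios = {f"{a}/{b}": means[a] / means[b] for a, b in ratio_pairs}
    return EnrichmentReport(means, bases, ratios, per_interval)


def gene_density(
    genes: Sequence[tuple],
    annotations: Mapping[str, Intervals],
) -> pd.DataFrame:
    """Gene count, total kb and kb-per-gene for each category.

    ``genes`` are (contig, start, end[, id]) tuples; a gene belongs to every
    category whose intervals contain its midpoint (categories may overlap,
    e.g. IES within Cbs-related sections).  kb_per_gene is NaN for empty
    categories; full precision is reported (no rounding of lengths).
    """
    rows = []
    for label, ivs_by_contig in annotations.items():
        total_bp = sum(
            e - s for ivs in ivs_by_contig.values() for s, e in ivs
        )
        count = 0
        for g in genes:
            contig, start, end = g[0], g[1], g[2]
            mid = (start + end) // 2
            if any(s <= mid < e for s, e in ivs_by_contig.get(contig, [])):
                count += 1
        total_kb = total_bp / 1000.0
        rows.append(
            {
                "category": label,
                "gene_count": count,
                "total_kb": total_kb,
                "kb_per_gene": total_kb / count if count else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("category")


def stage_expression_counts(
    matrix: pd.DataFrame,
    gene_to_section: Mapping[str, str],
    threshold: float = 0.0,
    clusters: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-section x per-stage counts of genes expressed above ``threshold``.

    ``matrix`` is genes x stages (columns from :data:`STAGES`).  Genes absent
    from ``gene_to_section`` are returned separately rather than counted.
    ``clusters`` optionally adds summed rows over named groups of sections
    (e.g. a tandem EMC cluster reported as one row).
    """
    if (matrix.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    unmapped = [g for g in matrix.index if g not in gene_to_section]
    mapped = matrix.loc[[g for g in matrix.index if g in gene_to_section]]
    section = pd.Series({g: gene_to_section[g] for g in mapped.index}, name="section")
    counts = (mapped > threshold).groupby(section).sum().astype(int)
    counts.index.name = "section"
    if clusters:
        extra = {}
        for name, members in clusters.items():
            present = [m for m in members if m in counts.index]
            extra[name] = counts.loc[present].sum() if present else counts.iloc[0:0].sum()
        counts = pd.concat([counts, pd.DataFrame(extra).T.astype(int)])
    return counts, unmapped
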