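"""Telomere-junction detection, MIC anchoring and breakage-gap measurement.

Chromosome breakage at a Cbs removes the 15-bp element plus a short stretch of
flanking sequence on each side before de novo telomeres are added to the two
products.  This module reconstructs those events from assembled somatic (MAC)
scaffolds and the germline (MIC) genome:

1. detect telomere-repeat runs at scaffold ends and extract the first ``k`` bp
   of non-telomeric sequence (the junction sequence);
2. anchor each junction sequence to a unique MIC coordinate;
3. pair anchored ends with scanned Cbs copies (a Cbs with at least one
   assigned end is "functional");
4. measure the 5'- and 3'-flank losses on the G strand of the Cbs and the
   total gap (losses + 15 bp).

Flank loss is the number of MIC bases between the Cbs boundary and the first
MAC-retained base.  The G strand is the strand on which the copy matches the
classic orientation, so for a ``-`` strand Cbs the 5' flank lies to the right
in forward MIC coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .motif import CbsHit, revcomp, _as_contig_items

__all__ = [
    "TELOMERE_UNIT",
    "TelomerizedEnd",
    "AnchoredEnd",
    "FunctionalCbs",
    "JunctionMeasurement",
    "KmerIndex",
    "find_telomerized_ends",
    "anchor_end",
    "anchor_ends",
    "validate_functional_cbs",
    "measure_junction",
    "flank_asymmetry_test",
    "core_distance_recheck",
]

logger = logging.getLogger(__name__)

#: The Tetrahymena telomeric repeat unit (G strand).
TELOMERE_UNIT = "GGGGTT"


@dataclass(frozen=True)
class TelomerizedEnd:
    """A scaffold end carrying a tandem run of telomere units."""

    scaffold_id: str
    side: str  # "left" | "right"
    repeat_count: int
    junction_seq: str  # first k bp of non-telomeric sequence, scaffold orientation


@dataclass(frozen=True)
class AnchoredEnd:
    """A telomerized end located in the MIC genome.

    ``junction_coord`` is the 0-based MIC coordinate of the telomere-proximal
    retained base; ``retained_side`` says in which direction from it the
    MAC-retained sequence extends ("upstream" = toward lower coordinates).
    """

    end: TelomerizedEnd
    contig_id: str | None
    junction_coord: int | None
    retained_side: str | None  # "upstream" | "downstream"
    unique: bool
    n_matches: int


@dataclass
class FunctionalCbs:
    """A Cbs copy validated by at least one anchored telomerized MAC end.

    ``left_end`` retains sequence upstream of the Cbs (the left breakage
    product); ``right_end`` retains sequence downstream (the right product).
    """

    hit: CbsHit
    left_end: AnchoredEnd | None = None
    right_end: AnchoredEnd | None = None

    @property
    def one_sided(self) -> bool:
        return (self.left_end is None) != (self.right_end is None)

    @property
    def two_sided(self) -> bool:
        return self.left_end is not None and self.right_end is not None


@dataclass(frozen=True)
class JunctionMeasurement:
    """Flank losses around one functional Cbs, on the G strand of the motif.

    ``total_gap = five_prime_loss + 15 + three_prime_loss`` for two-sided
    measurements; one-sided measurements carry ``None`` for the missing flank.
    """

    contig_id: str
    cbs_start: int
    strand: str
    five_prime_loss: int | None
    three_prime_loss: int | None

    @property
    def total_gap(self) -> int | None:
        if self.five_prime_loss is None or self.three_prime_loss is None:
            return None
        return self.five_prime_loss + 15 + self.three_prime_loss

    @property
    def two_sided(self) -> bool:
        return self.five_prime_loss is not None and self.three_prime_loss is not None


def _leading_repeats(seq: str, unit: str) -> int:
    n, u = 0, len(unit)
    while seq.startswith(unit, n * u):
        n += 1
    return n


def _trailing_repeats(seq: str, unit: str) -> int:
    n, u = 0, len(unit)
    while n * u + u <= len(seq) and seq.endswith(unit, 0, len(seq) - n * u):
        n += 1
    return n


def find_telomerized_ends(
    scaffolds,
    telomere_unit: str = TELOMERE_UNIT,
    min_repeats: int = 3,
    k: int = 30,
) -> list[TelomerizedEnd]:
    """Detect tandem telomere-unit runs at both ends of each scaffold.

    Both the unit and its reverse complement are tried at each end (a left
    scaffold end normally carries the C-strand repeat).  The junction sequence
    is the ``k`` bp immediately interior to the maximal run.
    """
    if not telomere_unit:
        raise ValueError("telomere_unit must be non-empty")
    if min_repeats < 1:
        raise ValueError("min_repeats must be >= 1")
    units = (telomere_unit.upper(), revcomp(telomere_unit.upper()))
    ends: list[TelomerizedEnd] = []
    for scaffold_id, seq in _as_contig_items(scaffolds):
        seq = seq.upper()
        u = len(telomere_unit)
        # left end
        n_left = max(_leading_repeats(seq, unit) for unit in units)
        if n_left >= min_repeats:
            start = n_left * u
            if start + k <= len(seq):
                ends.append(
                    TelomerizedEnd(scaffold_id, "left", n_left, seq[start : start + k])
                )
            else:
                logger.warning("scaffold %s too short for left junction; skipped", scaffold_id)
        # right end
        n_right = max(_trailing_repeats(seq, unit) for unit in units)
        if n_right >= min_repeats:
            stop = len(seq) - n_right * u
            if stop - k >= 0:
                ends.append(
                    TelomerizedEnd(scaffold_id, "right", n_right, seq[stop - k : stop])
                )
            else:
                logger.warning("scaffold %s too short for right junction; skipped", scaffold_id)
    return ends


_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i


class KmerIndex:
    """Exact-match index of all forward-strand k-mers of a genome.

    Windows containing non-ACGT characters are excluded.  Lookups return
    (contig, 0-based start) pairs; a query is also matched against the reverse
    strand by looking up its reverse complement.  k must be <= 31 (2-bit
    packed into uint64).
    """

    def __init__(self, genome, k: int):
        if not 1 <= k <= 31:
            raise ValueError("k must be in 1..31")
        self.k = k
        self._contig_ids: list[str] = []
        codes_all, cid_all, pos_all = [], [], []
        for cid, seq in _as_contig_items(genome):
            n = len(seq)
            if n < k:
                self._contig_ids.append(cid)
                continue
            b = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            valid = b < 4
            # windows free of non-ACGT bases
            cs = np.concatenate(([0], np.cumsum(~valid)))
            ok = (cs[k:] - cs[:-k]) == 0
            code = np.zeros(n - k + 1, dtype=np.uint64)
            bb = b.astype(np.uint64)
            for j in range(k):
                code = (code << np.uint64(2)) | bb[j : j + n - k + 1]
            idx = len(self._contig_ids)
            self._contig_ids.append(cid)
            codes_all.append(code[ok])
            cid_all.append(np.full(int(ok.sum()), idx, dtype=np.int32))
            pos_all.append(np.nonzero(ok)[0].astype(np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._cids = np.concatenate(cid_all)[order]
            self._pos = np.concatenate(pos_all)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._cids = np.empty(0, dtype=np.int32)
            self._pos = np.empty(0, dtype=np.int64)

    def _encode(self, s: str) -> int | None:
        b = _BASE_CODE[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
        if (b >= 4).any():
            return None
        code = 0
        for v in b:
            code = (code << 2) | int(v)
        return code

    def find(self, s: str) -> list[tuple[str, int]]:
        """All forward-strand occurrences of ``s`` (length k) in the genome."""
        if len(s) != self.k:
            raise ValueError(f"query length {len(s)} != k={self.k}")
        code = self._encode(s)
        if code is None:
            return []
        lo = int(np.searchsorted(self._codes, np.uint64(code), side="left"))
        hi = int(np.searchsorted(self._codes, np.uint64(code), side="right"))
        return [
            (self._contig_ids[int(c)], int(p))
            for c, p in zip(self._cids[lo:hi], self._pos[lo:hi])
        ]


def _approx_find(seq: str, query: str, max_mismatches: int) -> list[int]:
    """Start positions where ``query`` matches ``seq`` with <= max_mismatches."""
    k, n = len(query), len(seq)
    if n < k:
        return []
    b = _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    q = _BASE_CODE[np.frombuffer(query.upper().encode("ascii"), dtype=np.uint8)]
    mism = np.zeros(n - k + 1, dtype=np.int32)
    for j in range(k):
        mism += b[j : j + n - k + 1] != q[j]
    return [int(i) for i in np.nonzero(mism <= max_mismatches)[0]]


def anchor_end(
    end: TelomerizedEnd,
    mic_genome,
    max_mismatches: int = 0,
    index: KmerIndex | None = None,
) -> AnchoredEnd:
    """Locate one junction sequence in the MIC genome (either strand).

    ``unique`` is True iff exactly one location matches; the reported
    coordinate is the telomere-proximal edge of the match.  With the default
    ``max_mismatches=0`` an optional precomputed :class:`KmerIndex` makes the
    search O(log n) per end.
    """
    s = end.junction_seq.upper()
    k = len(s)
    matches: list[tuple[str, int, str]] = []  # (contig, start, orientation)
    if max_mismatches == 0:
        if index is None:
            index = KmerIndex(mic_genome, k)
        elif index.k != k:
            raise ValueError("index k does not match junction length")
        for cid, p in index.find(s):
            matches.append((cid, p, "+"))
        rc = revcomp(s)
        if rc != s:
            for cid, p in index.find(rc):
                matches.append((cid, p, "-"))
    else:
        for cid, seq in _as_contig_items(mic_genome):
            for p in _approx_find(seq, s, max_mismatches):
                matches.append((cid, p, "+"))
            for p in _approx_find(seq, revcomp(s), max_mismatches):
                matches.append((cid, p, "-"))
    if len(matches) != 1:
        return AnchoredEnd(end, None, None, None, unique=False, n_matches=len(matches))
    cid, p, orient = matches[0]
    # telomere-proximal base and direction of the retained sequence in MIC
    # coordinates depend on which scaffold end this is and the match strand.
    if end.side == "left":
        if orient == "+":
            coord, retained = p, "downstream"
        else:
            coord, retained = p + k - 1, "upstream"
    else:  # right end: last base of junction_seq is telomere-proximal
        if orient == "+":
            coord, retained = p + k - 1, "upstream"
        else:
            coord, retained = p, "downstream"
    return AnchoredEnd(end, cid, coord, retained, unique=True, n_matches=1)


def anchor_ends(
    ends: Sequence[TelomerizedEnd], mic_genome, max_mismatches: int = 0
) -> list[AnchoredEnd]:
    """Anchor many ends, sharing one index per junction length."""
    out: list[AnchoredEnd] = []
    if max_mismatches == 0:
        indices: dict[int, KmerIndex] = {}
        for end in ends:
            k = len(end.junction_seq)
            if k not in indices:
                indices[k] = KmerIndex(mic_genome, k)
            out.append(anchor_end(end, mic_genome, 0, index=indices[k]))
    else:
        for end in ends:
            out.append(anchor_end(end, mic_genome, max_mismatches))
    return out


def validate_functional_cbs(
    hits: Sequence[CbsHit],
    anchored_ends: Iterable[AnchoredEnd],
    window: int = 50,
) -> tuple[list[FunctionalCbs], list[AnchoredEnd]]:
    """Pair unique anchored ends with the nearest Cbs within ``window`` bp.

    An end retaining upstream sequence belongs to the left breakage product
    and is assigned to the nearest Cbs starting to its right; an end retaining
    downstream sequence to the nearest Cbs ending to its left.  Ends that are
    non-unique, too far from any Cbs, or ambiguous are returned unassigned.

    Returns (functional Cbs list sorted by coordinate, unassigned ends).
    """
    from bisect import bisect_left, bisect_right

    by_contig: dict[str, list[CbsHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    starts_by_contig: dict[str, list[int]] = {}
    for cid, hs in by_contig.items():
        hs.sort(key=lambda h: h.start)
        starts_by_contig[cid] = [h.start for h in hs]

    assigned: dict[tuple[str, int, str], dict[str, tuple[int, AnchoredEnd]]] = {}
    unassigned: list[AnchoredEnd] = []
    for ae in anchored_ends:
        if not ae.unique:
            unassigned.append(ae)
            continue
        all_hits = by_contig.get(ae.contig_id, [])
        starts = starts_by_contig.get(ae.contig_id, [])
        # only hits whose start lies within window+15 of the junction can match
        lo = bisect_left(starts, ae.junction_coord - window - 15)
        hi = bisect_right(starts, ae.junction_coord + window + 15)
        candidates = all_hits[lo:hi]
        best: tuple[int, CbsHit] | None = None
        tie = False
        for h in candidates:
            if ae.retained_side == "upstream":
                gap = h.start - ae.junction_coord - 1
            else:
                gap = ae.junction_coord - h.end
            if gap < 0 or gap > window:
                continue
            if best is None or gap < best[0]:
                best, tie = (gap, h), False
            elif gap == best[0]:
                tie = True
        if best is None or tie:
            unassigned.append(ae)
            continue
        gap, h = best
        side = "left" if ae.retained_side == "upstream" else "right"
        key = (h.contig_id, h.start, h.strand)
        slot = assigned.setdefault(key, {})
        if side in slot and slot[side][0] <= gap:
            unassigned.append(ae)  # a nearer end already claimed this side
        else:
            if side in slot:
                unassigned.append(slot[side][1])
            slot[side] = (gap, ae)

    hit_by_key = {(h.contig_id, h.start, h.strand): h for h in hits}
    functional = [
        FunctionalCbs(
            hit=hit_by_key[key],
            left_end=slot.get("left", (None, None))[1],
            right_end=slot.get("right", (None, None))[1],
        )
        for key, slot in assigned.items()
    ]
    functional.sort(key=lambda f: (f.hit.contig_id, f.hit.start))
    return functional, unassigned


def measure_junction(fcbs: FunctionalCbs) -> JunctionMeasurement:
    """Flank losses for one functional Cbs, on the G strand of the motif.

    For a ``+`` strand hit the 5' flank is the left side in forward MIC
    coordinates; for a ``-`` strand hit the sides swap.  One-sided inputs
    yield a partial measurement (missing flank is None).
    """
    h = fcbs.hit
    left_gap = (
        h.start - fcbs.left_end.junction_coord - 1 if fcbs.left_end is not None else None
    )
    right_gap = (
        fcbs.right_end.junction_coord - h.end if fcbs.right_end is not None else None
    )
    if h.strand == "+":
        five, three = left_gap, right_gap
    else:
        five, three = right_gap, left_gap
    return JunctionMeasurement(
        contig_id=h.contig_id,
        cbs_start=h.start,
        strand=h.strand,
        five_prime_loss=five,
        three_prime_loss=three,
    )


def flank_asymmetry_test(
    measurements: Sequence[JunctionMeasurement],
    method: str = "welch",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> dict[str, float]:
    """Compare 5' and 3' flank losses across two-sided measurements.

    ``method="welch"`` runs Welch's unequal-variance two-sample t-test;
    ``method="permutation"`` a label-permutation test on the mean difference.
    Returns means, sample standard deviations, the mean difference
    (3' - 5'), the test statistic and the p-value.
    """
    five = np.array([m.five_prime_loss for m in measurements if m.two_sided], dtype=float)
    three = np.array([m.three_prime_loss for m in measurements if m.two_sided], dtype=float)
    if len(five) < 2:
        raise ValueError("need at least 2 two-sided measurements")
    if method == "welch":
        res = stats.ttest_ind(three, five, equal_var=False)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        res = stats.permutation_test(
            (three, five),
            lambda a, b: np.mean(a) - np.mean(b),
            permutation_type="independent",
            n_resamples=n_permutations,
            rng=np.random.default_rng(seed),
        )
        statistic, pvalue = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "n": int(len(five)),
        "mean5": float(five.mean()),
        "sd5": float(five.std(ddof=1)),
        "mean3": float(three.mean()),
        "sd3": float(three.std(ddof=1)),
        "difference": float(three.mean() - five.mean()),
        "statistic": statistic,
        "p_value": pvalue,
    }


def core_distance_recheck(
    measurements: Sequence[JunctionMeasurement],
    core_span: tuple[int, int] = (6, 14),
) -> dict[str, float]:
    """Re-measure per-side losses from the conserved core instead of the 15-mer.

    ``core_span`` gives the 1-based first and last motif positions of the
    contiguous conserved core (default positions 6..14).  The 5'-side distance
    to the core is the flank loss plus the ``core_start - 1`` motif bases that
    lie 5' of the core; the 3'-side distance adds ``15 - core_end`` bases.
    An asymmetry confined to the motif-boundary convention disappears when
    distances are taken to the core.
    """
    lo, hi = core_span
    if not 1 <= lo <= hi <= 15:
        raise ValueError("core_span must satisfy 1 <= start <= end <= 15")
    off5, off3 = lo - 1, 15 - hi
    five = np.array([m.five_prime_loss for m in measurements if m.two_sided], dtype=float)
    three = np.array([m.three_prime_loss for m in measurements if m.two_sided], dtype=float)
    return {
        "offset5": off5,
        "offset3": off3,
        "mean5_to_motif": float(five.mean()),
        "mean3_to_motif": float(three.mean()),
        "difference_to_motif": float(three.mean() - five.mean()),
        "mean5_to_core": float(five.mean() + off5),
        "mean3_to_core": float(three.mean() + off3),
        "difference_to_core": float((three.mean() + off3) - (five.mean() + off5)),
    }
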