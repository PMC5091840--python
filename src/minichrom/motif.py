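"""Constrained chromosome breakage sequence (Cbs) motif model and genome scanning.

The Cbs is a 15-bp cis-acting element that directs developmentally programmed
chromosome fragmentation in *Tetrahymena*.  Its classic form is
``AAAGAGGTTGGTTTA``.  Genomic copies differ from the classic sequence only at
five "variable" positions (the five A's at positions 1, 2, 3, 5 and 15,
1-based), each of which tolerates a single specific alternative base, and a
copy may carry at most two such substitutions.  The remaining ten positions
({4, 6..14}) form an invariant core.

Matching is therefore combinatorial (membership in a small admissible set),
not a position-weight-matrix score cut-off.  A position frequency matrix is
still provided as a descriptive summary of a seed collection and as an
optional log-odds scoring mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CLASSIC_CBS",
    "CbsMotifModel",
    "CbsHit",
    "MotifClassification",
    "PositionFrequencyMatrix",
    "revcomp",
    "enumerate_admissible",
    "classify_15mer",
    "build_pfm",
    "scan_genome",
    "class_counts",
]

#: The classic 15-bp chromosome breakage sequence (G strand).
CLASSIC_CBS = "AAAGAGGTTGGTTTA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (preserves N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CbsMotifModel:
    """The constrained Cbs model: an invariant core plus restricted variable positions.

    Parameters
    ----------
    classic
        The reference 15-mer (G-strand orientation).
    variable_alternatives
        Map of 1-based position -> the single allowed alternative base at that
        position.  The classic base at every variable position must be ``A``.
        Defaults to T at positions 1, 2, 3 and 15 and G at position 5; the
        alternatives at positions 2 and 3 are configurable.
    max_substitutions
        Maximum number of variable positions that may deviate from classic.
    """

    classic: str = CLASSIC_CBS
    variable_alternatives: Mapping[int, str] = field(
        default_factory=lambda: {1: "T", 2: "T", 3: "T", 5: "G", 15: "T"}
    )
    max_substitutions: int = 2

    def __post_init__(self) -> None:
        if len(self.classic) != 15 or set(self.classic) - set("ACGT"):
            raise ValueError("classic Cbs must be a 15-mer over ACGT")
        for pos, alt in self.variable_alternatives.items():
            if not 1 <= pos <= 15:
                raise ValueError(f"variable position {pos} outside 1..15")
            if self.classic[pos - 1] != "A":
                raise ValueError(
                    f"variable position {pos} must carry 'A' in the classic sequence"
                )
            if alt not in "ACGT" or alt == self.classic[pos - 1]:
                raise ValueError(f"invalid alternative {alt!r} at position {pos}")
        if self.max_substitutions > len(self.variable_alternatives):
            raise ValueError("max_substitutions exceeds the number of variable positions")
        if self.max_substitutions < 0:
            raise ValueError("max_substitutions must be >= 0")

    @property
    def length(self) -> int:
        return len(self.classic)

    @property
    def variable_positions(self) -> frozenset[int]:
        """1-based positions allowed to deviate from the classic base."""
        return frozenset(self.variable_alternatives)

    @property
    def core_positions(self) -> frozenset[int]:
        """1-based invariant positions (default {4, 6..14}: the 10-bp core)."""
        return frozenset(range(1, 16)) - self.variable_positions


@dataclass(frozen=True)
class MotifClassification:
    """Outcome of testing a 15-mer against the model."""

    admissible: bool
    substitution_class: int | None = None
    substituted_positions: frozenset[int] = frozenset()
    reason: str | None = None


@dataclass(frozen=True)
class CbsHit:
    """One admissible Cbs copy found in a genome.

    ``start`` is the 0-based coordinate of the 15-mer window on the forward
    strand of ``contig_id``; ``observed`` is the matching sequence in G-strand
    orientation (i.e. the admissible 15-mer itself, which for a ``-`` strand
    hit is the reverse complement of the forward-strand window).
    """

    contig_id: str
    start: int
    strand: str
    observed: str
    substitution_class: int
    substituted_positions: frozenset[int] = frozenset()

    @property
    def end(self) -> int:
        return self.start + 15


def enumerate_admissible(model: CbsMotifModel | None = None) -> frozenset[str]:
    """All 15-mers reachable from classic by <= max_substitutions allowed changes.

    With the default model this is C(5,0)+C(5,1)+C(5,2) = 16 sequences.
    """
    model = model or CbsMotifModel()
    out = set()
    positions = sorted(model.variable_alternatives)
    for k in range(model.max_substitutions + 1):
        for combo in itertools.combinations(positions, k):
            s = list(model.classic)
            for pos in combo:
                s[pos - 1] = model.variable_alternatives[pos]
            out.add("".join(s))
    return frozenset(out)


def classify_15mer(s: str, model: CbsMotifModel | None = None) -> MotifClassification:
    """Classify a 15-mer as a class-0/1/2 Cbs copy or reject it with a reason."""
    model = model or CbsMotifModel()
    if len(s) != model.length:
        raise ValueError(f"expected a 15-mer, got length {len(s)}")
    s = s.upper()
    if set(s) - set("ACGT"):
        return MotifClassification(False, reason="ambiguous base")
    subs = set()
    for pos in range(1, 16):
        base, ref = s[pos - 1], model.classic[pos - 1]
        if base == ref:
            continue
        alt = model.variable_alternatives.get(pos)
        if alt is None:
            return MotifClassification(False, reason="core mismatch")
        if base != alt:
            return MotifClassification(False, reason="disallowed alternative")
        subs.add(pos)
    if len(subs) > model.max_substitutions:
        return MotifClassification(False, reason="too many substitutions")
    return MotifClassification(True, len(subs), frozenset(subs))


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column base frequencies over a set of aligned 15-mers.

    ``matrix`` has shape (15, 4) with columns ordered A, C, G, T; every row
    sums to 1 (within floating tolerance).
    """

    matrix: np.ndarray
    pseudocount: float
    n_seqs: int
    alphabet: str = "ACGT"

    def frequency(self, position: int, base: str) -> float:
        """Frequency of ``base`` at 1-based ``position``."""
        return float(self.matrix[position - 1, self.alphabet.index(base)])

    def consensus(self) -> str:
        return "".join(self.alphabet[j] for j in self.matrix.argmax(axis=1))

    def log_odds_score(self, s: str, background: float = 0.25) -> float:
        """Log2-odds score of a 15-mer against a uniform background.

        This scoring mode is descriptive; admissibility in this package is
        decided by :func:`classify_15mer`, not by a score threshold.
        """
        if len(s) != self.matrix.shape[0]:
            raise ValueError("sequence length does not match matrix")
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / background)
        return float(sum(lo[i, self.alphabet.index(b)] for i, b in enumerate(s.upper())))


def build_pfm(
    seed_sequences: Sequence[str], pseudocount: float = 0.0
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix from aligned 15-mer seed sequences.

    Column frequency of base *b* is ``(count + pseudocount) / (n + 4 * pseudocount)``.
    """
    if not seed_sequences:
        raise ValueError("empty seed list")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    length = 15
    alphabet = "ACGT"
    counts = np.zeros((length, 4), dtype=float)
    for seq in seed_sequences:
        seq = seq.upper()
        if len(seq) != length:
            raise ValueError("seed sequences must be 15-mers")
        for i, base in enumerate(seq):
            if base not in alphabet:
                raise ValueError(f"seed contains non-ACGT base {base!r}")
            counts[i, alphabet.index(base)] += 1
    n = len(seed_sequences)
    matrix = (counts + pseudocount) / (n + 4 * pseudocount)
    return PositionFrequencyMatrix(matrix=matrix, pseudocount=pseudocount, n_seqs=n)


def _as_contig_items(genome) -> list[tuple[str, str]]:
    """Accept a mapping id->sequence, or an iterable of objects/tuples."""
    if isinstance(genome, Mapping):
        return list(genome.items())
    items = []
    for rec in genome:
        if isinstance(rec, tuple):
            items.append(rec)
        else:  # GenomeSequence-like or Bio.SeqRecord-like
            seq = getattr(rec, "sequence", None)
            if seq is None:
                seq = str(getattr(rec, "seq"))
            items.append((rec.id, seq))
    return items


def scan_genome(genome, model: CbsMotifModel | None = None) -> list[CbsHit]:
    """Find every admissible Cbs copy on either strand of every contig.

    Hits are reported once each, in G-strand orientation, sorted by
    (contig, start, strand).  Windows containing N can never match because
    admissible sequences are ACGT-only.  Overlapping hits are all reported.
    """
    model = model or CbsMotifModel()
    admissible = enumerate_admissible(model)
    hits: list[CbsHit] = []
    for contig_id, seq in _as_contig_items(genome):
        seq = seq.upper()
        seen: set[tuple[int, str]] = set()
        for pat in admissible:
            cls = classify_15mer(pat, model)
            for strand, needle in (("+", pat), ("-", revcomp(pat))):
                start = seq.find(needle)
                while start != -1:
                    if (start, strand) not in seen:
                        seen.add((start, strand))
                        hits.append(
                            CbsHit(
                                contig_id=contig_id,
                                start=start,
                                strand=strand,
                                observed=pat,
                                substitution_class=cls.substitution_class,
                                substituted_positions=cls.substituted_positions,
                            )
                        )
                    start = seq.find(needle, start + 1)
    hits.sort(key=lambda h: (h.contig_id, h.start, h.strand))
    return hits


def class_counts(hits: Iterable[CbsHit]) -> dict[int, int]:
    """Number of hits per substitution class (0, 1, 2, ...)."""
    out: dict[int, int] = {}
    for h in hits:
        out[h.substitution_class] = out.get(h.substitution_class, 0) + 1
    return out
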