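"""Copy-number dilution of a minichromosome across vegetative doublings.

After conjugation the somatic genome is endoduplicated to high copy number.
A minichromosome that stops replicating is passively halved at every cell
doubling relative to the replicating bulk; active degradation reduces it
further.  The model composes the two multiplicatively: with ``r`` copies
produced per existing copy per doubling (r in [1, 2]; 2 = full replication,
1 = none) and per-doubling survival ``delta`` (in [0, 1]), relative abundance
after ``d`` doublings is ``(r * delta / 2) ** d``.  A fully non-replicating,
non-degraded minichromosome (r=1, delta=1) is therefore 2**d-fold reduced —
64-fold after 6 doublings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DilutionModel",
    "relative_abundance",
    "fold_reduction",
    "trajectory",
    "simulate_copy_counts",
    "fit_elimination_window",
    "EliminationWindow",
]


@dataclass(frozen=True)
class DilutionModel:
    """Replication rate r (copies per copy per doubling) and survival delta."""

    r: float = 1.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not 1.0 <= self.r <= 2.0:
            raise ValueError("r must be in [1, 2]")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")

    @property
    def per_doubling_factor(self) -> float:
        return self.r * self.delta / 2.0


def relative_abundance(model: DilutionModel, d: int) -> float:
    """Abundance relative to the replicating bulk after ``d`` doublings."""
    if d < 0 or int(d) != d:
        raise ValueError("d must be a nonnegative integer")
    return model.per_doubling_factor ** d


def fold_reduction(model: DilutionModel, d: int) -> float:
    """Reciprocal of relative abundance (infinite if abundance is 0)."""
    a = relative_abundance(model, d)
    return float("inf") if a == 0 else 1.0 / a


def trajectory(model: DilutionModel, doublings: int) -> pd.DataFrame:
    """Relative abundance and fold reduction at 0..doublings."""
    ds = np.arange(doublings + 1)
    ab = model.per_doubling_factor ** ds
    with np.errstate(divide="ignore"):
        return pd.DataFrame(
            {"doubling": ds, "relative_abundance": ab, "fold_reduction": 1.0 / ab}
        )


def simulate_copy_counts(
    model: DilutionModel, doublings: int, n0: int, rng: np.random.Generator
) -> list[int]:
    """Stochastic per-doubling copy counts whose expectation matches the closed form.

    Each copy replicates with probability (r - 1), survives degradation with
    probability delta, and segregates to the followed daughter with
    probability 1/2.  Returns counts at doublings 0..doublings.
    """
    counts = [int(n0)]
    n = int(n0)
    for _ in range(doublings):
        n = n + rng.binomial(n, model.r - 1.0)  # replication shortfall
        n = rng.binomial(n, model.delta)        # degradation
        n = rng.binomial(n, 0.5)                # amitotic segregation
        counts.append(int(n))
    return counts


@dataclass(frozen=True)
class EliminationWindow:
    """Open interval (last doubling detected, first doubling undetected)."""

    last_detected: float    # -inf if never detected
    first_undetected: float  # +inf if always detected
    monotonic: bool = True


def fit_elimination_window(observations: Mapping[int, bool]) -> EliminationWindow:
    """Bracket the elimination time from detected/undetected observations.

    ``observations`` maps doubling number -> detected?.  With monotone data
    the window is (max detected, min undetected).  A detection after an
    earlier non-detection violates monotonicity; the window is then widened
    to (max detected, first undetected after it) and flagged.
    """
    if not observations:
        raise ValueError("no observations")
    detected = sorted(d for d, seen in observations.items() if seen)
    undetected = sorted(d for d, seen in observations.items() if not seen)
    last_det = detected[-1] if detected else float("-inf")
    monotonic = not (undetected and detected and undetected[0] < last_det)
    later = [u for u in undetected if u > last_det]
    first_undet = later[0] if later else float("inf")
    return EliminationWindow(last_det, first_undet, monotonic)
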