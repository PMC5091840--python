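"""Synthetic MIC/MAC genomes with planted breakage sites and full ground truth.

The generator emulates the statistical structure the analysis assumes so that
every pipeline stage can be exercised and validated without downloads:

* an AT-rich multi-contig germline (MIC) genome with planted Cbs copies of
  substitution classes 0/1/2 (default mix 95:90:24) on both strands;
* Cbs-delimited sections with retained/eliminated fates (default eliminated
  fraction 50/326) and planted IESs inside sections;
* somatic (MAC) scaffolds built from retained sections by IES removal,
  flank trimming with per-site 5'/3' losses (defaults N(18.8, 5.3) and
  N(23.9, 6.9) bp, rounded to nonnegative integers) and telomere addition
  (GGGGTT repeats);
* Poisson coverage tracks whose rate tracks section fate (eliminated DNA is
  covered at a small mismapping floor in mature samples but fully in the
  24-hpm conjugation sample);
* a category-structured ChIP enrichment track and a stage-restricted
  expression matrix for genes on eliminated minichromosomes.

All randomness derives from ``SimConfig.seed``; identical configurations
produce byte-identical outputs.  Chance (unplanted) admissible 15-mers are
removed by rescanning and mutating one core base, so the planted site list
is exactly the scanner's expected output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import (
    CLASSIC_CBS,
    CbsHit,
    CbsMotifModel,
    revcomp,
    scan_genome,
)
from .junctions import TELOMERE_UNIT, TelomerizedEnd
from .partition import Section, partition_genome
from .fate import CoverageTrack
from .categories import STAGES

__all__ = [
    "SimConfig",
    "PlantedCbs",
    "SimGene",
    "SimTruth",
    "MacSim",
    "SimData",
    "simulate_mic",
    "simulate_mac",
    "simulate_coverage",
    "simulate_chip",
    "simulate_expression",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters; ``seed`` fixes every source of randomness."""

    seed: int = 0
    # genome layout
    n_contigs: int = 20
    mean_contig_length: int = 250_000
    min_contig_length: int = 20_000
    at_fraction: float = 0.75
    # breakage sites
    n_cbs: int = 209
    class_mix: tuple[int, int, int] = (95, 90, 24)
    min_section_length: int = 150
    # fates and IES
    eliminated_fraction: float = 50 / 326
    ies_per_section_mean: float = 2.0
    ies_length_range: tuple[int, int] = (500, 2500)
    ies_margin: int = 100
    # breakage flank losses (bp), drawn per site
    flank_model: str = "independent"  # or "total_gap"
    five_prime_loss: tuple[float, float] = (18.8, 5.3)   # mean, sd
    three_prime_loss: tuple[float, float] = (23.9, 6.9)  # mean, sd
    total_gap: tuple[float, float] = (56.79, 8.84)       # mean, sd (total_gap mode)
    # telomeres and anchoring
    telomere_unit: str = TELOMERE_UNIT
    telomere_repeats: int = 10
    anchor_k: int = 30
    # coverage
    depth_mature: float = 119.0
    depth_24hpm: float = 46.0
    mismap_floor: float = 0.005
    # ChIP enrichment means by ground-truth category
    chip_means: Mapping[str, float] = field(
        default_factory=lambda: {"MDS": 0.04, "IES": 0.68, "EMC": 0.60, "BACKGROUND": 0.04}
    )
    chip_noise: float = 0.02
    # genes and expression
    gene_length: int = 1000
    emc_gene_rates: Mapping[str, float] = field(
        default_factory=lambda: {"8hpm": 1.6, "16hpm": 1.0, "2D": 0.25}
    )
    mds_genes_per_section: float = 1.0
    expression_level: float = 50.0

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator for one pipeline stage."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedCbs:
    """Ground truth for one planted breakage site."""

    contig_id: str
    start: int
    strand: str
    observed: str  # G-strand orientation
    substitution_class: int
    substituted_positions: frozenset[int]
    five_prime_loss: int | None = None
    three_prime_loss: int | None = None

    @property
    def end(self) -> int:
        return self.start + 15

    @property
    def left_gap(self) -> int | None:
        """Bases lost left of the site in forward coordinates."""
        if self.five_prime_loss is None:
            return None
        return self.five_prime_loss if self.strand == "+" else self.three_prime_loss

    @property
    def right_gap(self) -> int | None:
        if self.five_prime_loss is None:
            return None
        return self.three_prime_loss if self.strand == "+" else self.five_prime_loss

    def to_hit(self) -> CbsHit:
        return CbsHit(
            contig_id=self.contig_id,
            start=self.start,
            strand=self.strand,
            observed=self.observed,
            substitution_class=self.substitution_class,
            substituted_positions=self.substituted_positions,
        )


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    contig_id: str
    start: int
    end: int
    section_name: str
    stage: str | None  # None = control gene expressed at every stage


@dataclass
class SimTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    config: SimConfig
    contig_lengths: dict[str, int]
    cbs_sites: list[PlantedCbs]
    sections: list[Section]
    ies_by_section: dict[str, list[tuple[int, int]]]  # absolute MIC coordinates
    genes: list[SimGene] = field(default_factory=list)
    section_trims: dict[str, tuple[int, int]] = field(default_factory=dict)

    def hits(self) -> list[CbsHit]:
        return sorted(
            (p.to_hit() for p in self.cbs_sites),
            key=lambda h: (h.contig_id, h.start, h.strand),
        )

    def section_by_name(self) -> dict[str, Section]:
        return {s.name: s for s in self.sections}

    def fates(self) -> dict[str, str]:
        return {s.name: s.fate for s in self.sections}

    def ies_intervals(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        secs = self.section_by_name()
        for name, ivs in self.ies_by_section.items():
            out.setdefault(secs[name].contig_id, []).extend(ivs)
        for ivs in out.values():
            ivs.sort()
        return out

    def _section_minus_ies(self, fate: str) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for s in self.sections:
            if s.fate != fate or s.length == 0:
                continue
            pieces = _subtract(
                (s.start, s.end), self.ies_by_section.get(s.name, [])
            )
            out.setdefault(s.contig_id, []).extend(pieces)
        return out

    def mds_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Retained-section bases minus IES (MAC-destined sequence)."""
        return self._section_minus_ies("retained")

    def category_intervals(self) -> dict[str, dict[str, list[tuple[int, int]]]]:
        """Disjoint MDS/IES/EMC plus the CBS_RELATED superset (all sections)."""
        all_sections: dict[str, list[tuple[int, int]]] = {}
        for s in self.sections:
            if s.length:
                all_sections.setdefault(s.contig_id, []).append((s.start, s.end))
        return {
            "MDS": self.mds_intervals(),
            "IES": self.ies_intervals(),
            "EMC": self._section_minus_ies("eliminated"),
            "CBS_RELATED": all_sections,
        }

    def gene_to_section(self) -> dict[str, str]:
        return {g.gene_id: g.section_name for g in self.genes}


def _subtract(
    interval: tuple[int, int], cuts: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Subtract sorted, disjoint cut intervals from one interval."""
    start, end = interval
    out = []
    pos = start
    for s, e in sorted(cuts):
        if e <= pos or s >= end:
            continue
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < end:
        out.append((pos, end))
    return out


def _random_sequence(rng: np.random.Generator, length: int, at_fraction: float) -> np.ndarray:
    at = at_fraction / 2.0
    gc = (1.0 - at_fraction) / 2.0
    return rng.choice(_BASES, size=length, p=[at, gc, gc, at])


def _plant_site(
    arr: np.ndarray, pos: int, observed: str, strand: str
) -> None:
    s = observed if strand == "+" else revcomp(observed)
    arr[pos : pos + 15] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def simulate_mic(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate the germline genome with planted Cbs copies, fates, IESs and genes.

    Contig ids follow the ``2.<n>`` supercontig convention so that section
    names read ``echr2.<n>.<i>``.  After assembly the genome is rescanned and
    any chance admissible 15-mer not planted on purpose is destroyed by a
    single core-base mutation, so the scanner's expected output equals the
    planted site list exactly.
    """
    rng = config.rng(11)
    model = CbsMotifModel()
    msl = config.min_section_length
    block_min = 2 * msl + 15

    # contig lengths and per-contig site capacity
    lengths = {}
    for i in range(config.n_contigs):
        L = int(config.mean_contig_length * rng.uniform(0.6, 1.4))
        lengths[f"2.{i + 1}"] = max(config.min_contig_length, L)
    ids = list(lengths)
    caps = np.array([lengths[c] // block_min for c in ids])
    if caps.sum() < config.n_cbs:
        raise ValueError("contigs too short for the requested number of Cbs sites")
    weights = np.array([lengths[c] for c in ids], dtype=float)
    alloc = rng.multinomial(config.n_cbs, weights / weights.sum())
    # redistribute any excess over capacity
    for _ in range(1000):
        over = alloc - caps
        if (over <= 0).all():
            break
        excess = int(over[over > 0].sum())
        alloc = np.minimum(alloc, caps)
        room = caps - alloc
        order = np.argsort(-room)
        for j in order:
            take = min(int(room[j]), excess)
            alloc[j] += take
            excess -= take
            if excess == 0:
                break

    # substitution classes for all sites
    mix = np.array(config.class_mix, dtype=float)
    classes = rng.choice(len(mix), size=config.n_cbs, p=mix / mix.sum())
    var_positions = sorted(model.variable_alternatives)

    mic_arrays: dict[str, np.ndarray] = {}
    planted: list[PlantedCbs] = []
    site_i = 0
    for cid, k in zip(ids, alloc):
        L = lengths[cid]
        arr = _random_sequence(rng, L, config.at_fraction)
        if k > 0:
            block = L // int(k)
            for b in range(int(k)):
                lo = b * block + msl
                hi = (b + 1) * block - msl - 15
                pos = int(rng.integers(lo, hi + 1))
                klass = int(classes[site_i])
                subs = rng.choice(var_positions, size=klass, replace=False)
                seq = list(model.classic)
                for p in subs:
                    seq[p - 1] = model.variable_alternatives[int(p)]
                observed = "".join(seq)
                strand = "+" if rng.random() < 0.5 else "-"
                _plant_site(arr, pos, observed, strand)
                planted.append(
                    PlantedCbs(
                        contig_id=cid,
                        start=pos,
                        strand=strand,
                        observed=observed,
                        substitution_class=klass,
                        substituted_positions=frozenset(int(p) for p in subs),
                    )
                )
                site_i += 1
        mic_arrays[cid] = arr

    # destroy chance admissible 15-mers so truth == scan output
    planted_keys = {(p.contig_id, p.start, p.strand) for p in planted}
    planted_windows = {(p.contig_id, p.start) for p in planted}
    for _ in range(5):
        mic = {cid: arr.tobytes().decode("ascii") for cid, arr in mic_arrays.items()}
        spurious = [
            h
            for h in scan_genome(mic, model)
            if (h.contig_id, h.start, h.strand) not in planted_keys
        ]
        if not spurious:
            break
        for h in spurious:
            if any(
                (h.contig_id, s) in planted_windows
                for s in range(h.start - 14, h.start + 15)
            ):
                continue  # overlaps a planted site; leave untouched
            arr = mic_arrays[h.contig_id]
            mid = h.start + 7
            arr[mid] = ord("C") if arr[mid] != ord("C") else ord("G")
    mic = {cid: arr.tobytes().decode("ascii") for cid, arr in mic_arrays.items()}

    sections, _ = partition_genome(
        lengths, [p.to_hit() for p in planted]
    )
    for s in sections:
        s.fate = "eliminated" if rng.random() < config.eliminated_fraction else "retained"

    # plant IESs inside sections, clear of boundaries
    margin = config.ies_margin
    ies_by_section: dict[str, list[tuple[int, int]]] = {}
    lo_len, hi_len = config.ies_length_range
    for s in sections:
        n = int(rng.poisson(config.ies_per_section_mean))
        placed: list[tuple[int, int]] = []
        for _ in range(n):
            ilen = int(rng.integers(lo_len, hi_len + 1))
            if s.length < ilen + 2 * margin:
                continue
            for _attempt in range(20):
                st = int(rng.integers(s.start + margin, s.end - margin - ilen + 1))
                iv = (st, st + ilen)
                if all(iv[1] + 50 <= a or b + 50 <= iv[0] for a, b in placed):
                    placed.append(iv)
                    break
        if placed:
            ies_by_section[s.name] = sorted(placed)

    # genes: stage-restricted on eliminated sections, always-on controls on retained
    genes: list[SimGene] = []
    gi = 0
    for s in sections:
        ies = ies_by_section.get(s.name, [])
        free = _subtract((s.start + 50, s.end - 50), ies) if s.length > 100 else []
        free = [iv for iv in free if iv[1] - iv[0] >= config.gene_length]
        if not free:
            continue
        if s.fate == "eliminated":
            plan = [
                (stage, int(rng.poisson(rate)))
                for stage, rate in config.emc_gene_rates.items()
            ]
        else:
            plan = [(None, int(rng.poisson(config.mds_genes_per_section)))]
        for stage, count in plan:
            for _ in range(count):
                a, b = free[int(rng.integers(len(free)))]
                st = int(rng.integers(a, b - config.gene_length + 1))
                genes.append(
                    SimGene(
                        gene_id=f"g{gi:05d}",
                        contig_id=s.contig_id,
                        start=st,
                        end=st + config.gene_length,
                        section_name=s.name,
                        stage=stage,
                    )
                )
                gi += 1

    truth = SimTruth(
        config=config,
        contig_lengths=lengths,
        cbs_sites=planted,
        sections=sections,
        ies_by_section=ies_by_section,
        genes=genes,
    )
    return mic, truth


def _draw_losses(config: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    if config.flank_model == "independent":
        m5, s5 = config.five_prime_loss
        m3, s3 = config.three_prime_loss
        five = max(0, round(float(rng.normal(m5, s5))))
        three = max(0, round(float(rng.normal(m3, s3))))
    elif config.flank_model == "total_gap":
        mg, sg = config.total_gap
        gap = round(float(rng.normal(mg, sg)))
        while gap < 15:
            gap = round(float(rng.normal(mg, sg)))
        excess = gap - 15
        m5, m3 = config.five_prime_loss[0], config.three_prime_loss[0]
        five = int(rng.binomial(excess, m5 / (m5 + m3)))
        three = excess - five
    else:
        raise ValueError(f"unknown flank_model {config.flank_model!r}")
    return int(five), int(three)


@dataclass
class MacSim:
    """Somatic products of the simulated breakage program.

    ``mature`` holds only retained minichromosomes (the vegetative MAC);
    ``scaffolds_24hpm`` additionally contains the eliminated minichromosomes,
    which are still present at the 24-hpm conjugation stage.
    """

    mature: dict[str, str]
    scaffolds_24hpm: dict[str, str]
    emc_ends: list[TelomerizedEnd]
    scaffold_of_section: dict[str, str]


def simulate_mac(config: SimConfig, mic: Mapping[str, str], truth: SimTruth) -> MacSim:
    """Build telomerized MAC scaffolds from sections; records losses in truth.

    Every section yields a scaffold: the section sequence minus its planted
    IESs, trimmed at each Cbs boundary by that site's drawn flank loss, with
    telomere repeats appended at both ends.  Losses leaving fewer than
    ``anchor_k + 5`` interior bases are redrawn (logged).
    """
    rng = config.rng(22)
    for site in truth.cbs_sites:
        site.five_prime_loss, site.three_prime_loss = _draw_losses(config, rng)

    # redraw losses that would swallow a short section's interior
    site_by_key = {(p.contig_id, p.start): p for p in truth.cbs_sites}
    sites_by_contig: dict[str, list[PlantedCbs]] = {}
    for p in truth.cbs_sites:
        sites_by_contig.setdefault(p.contig_id, []).append(p)
    for sites in sites_by_contig.values():
        sites.sort(key=lambda p: p.start)

    def bounding(section: Section) -> tuple[PlantedCbs | None, PlantedCbs | None]:
        left = site_by_key.get((section.contig_id, section.start - 15))
        right = site_by_key.get((section.contig_id, section.end))
        return left, right

    min_interior = config.anchor_k + 5
    for _ in range(50):
        ok = True
        for s in truth.sections:
            left, right = bounding(s)
            lt = left.right_gap if left else 0
            rt = right.left_gap if right else 0
            if s.length - lt - rt < min_interior and s.length >= min_interior:
                ok = False
                logger.info("redrawing losses around short section %s", s.name)
                if left:
                    left.five_prime_loss, left.three_prime_loss = _draw_losses(config, rng)
                if right:
                    right.five_prime_loss, right.three_prime_loss = _draw_losses(config, rng)
        if ok:
            break

    unit = config.telomere_unit
    tel_left = revcomp(unit) * config.telomere_repeats
    tel_right = unit * config.telomere_repeats
    mature: dict[str, str] = {}
    all_scaffolds: dict[str, str] = {}
    emc_ends: list[TelomerizedEnd] = []
    scaffold_of: dict[str, str] = {}
    k = config.anchor_k
    for s in truth.sections:
        left, right = bounding(s)
        lt = left.right_gap if left else 0
        rt = right.left_gap if right else 0
        if s.length - lt - rt < min_interior:
            continue  # too short to produce an anchorable product
        truth.section_trims[s.name] = (lt, rt)
        pieces = _subtract(
            (s.start + lt, s.end - rt), truth.ies_by_section.get(s.name, [])
        )
        # If the retained sequence itself starts/ends with a telomere unit the
        # junction is ambiguous (the run detector would absorb it); mutate the
        # edge base so every planted junction is recoverable exactly.
        rc_unit = revcomp(config.telomere_unit)
        contig = mic[s.contig_id]
        left_edge, right_edge = pieces[0][0], pieces[-1][1]
        if contig[left_edge : left_edge + len(rc_unit)] == rc_unit:
            base = "T" if contig[left_edge] != "T" else "G"
            contig = contig[:left_edge] + base + contig[left_edge + 1 :]
        u = config.telomere_unit
        if contig[right_edge - len(u) : right_edge] == u:
            base = "A" if contig[right_edge - 1] != "A" else "C"
            contig = contig[: right_edge - 1] + base + contig[right_edge:]
        if contig is not mic[s.contig_id]:
            mic[s.contig_id] = contig  # type: ignore[index]
        interior = "".join(contig[a:b] for a, b in pieces)
        scaffold = tel_left + interior + tel_right
        sid = f"scf_{s.name}"
        scaffold_of[s.name] = sid
        all_scaffolds[sid] = scaffold
        if s.fate == "retained":
            mature[sid] = scaffold
        else:
            emc_ends.append(
                TelomerizedEnd(sid, "left", config.telomere_repeats, interior[:k])
            )
            emc_ends.append(
                TelomerizedEnd(sid, "right", config.telomere_repeats, interior[-k:])
            )
    return MacSim(mature, all_scaffolds, emc_ends, scaffold_of)


def simulate_coverage(
    config: SimConfig, truth: SimTruth, sample_label: str = "mature"
) -> CoverageTrack:
    """Per-base Poisson coverage over MIC coordinates for one sample.

    MAC-destined bases draw Poisson(lambda); IES bases and (in mature
    samples) eliminated sections draw Poisson(lambda * mismap_floor).  In the
    ``"24hpm"`` sample eliminated minichromosomes are still present and
    covered like retained ones.
    """
    import zlib

    early = sample_label == "24hpm"
    lam = config.depth_24hpm if early else config.depth_mature
    # distinct deterministic stream per sample label
    rng = np.random.default_rng(
        [config.seed, 33, zlib.crc32(sample_label.encode()) & 0x7FFFFFFF]
    )
    rates = {
        cid: np.full(n, lam * config.mismap_floor)
        for cid, n in truth.contig_lengths.items()
    }
    for s in truth.sections:
        present = s.fate == "retained" or early
        if not present:
            continue
        lt, rt = truth.section_trims.get(s.name, (0, 0))
        rates[s.contig_id][s.start + lt : s.end - rt] = lam
        for a, b in truth.ies_by_section.get(s.name, []):
            rates[s.contig_id][a:b] = lam * config.mismap_floor
    data = {cid: rng.poisson(r).astype(float) for cid, r in rates.items()}
    return CoverageTrack(data=data, sample_label=sample_label)


def simulate_chip(
    config: SimConfig,
    truth: SimTruth,
    categories: Mapping[str, Mapping[str, Sequence[tuple[int, int]]]] | None = None,
    means: Mapping[str, float] | None = None,
) -> CoverageTrack:
    """Category-structured per-base ChIP fold-enrichment track.

    By default the disjoint ground-truth categories are planted at
    ``config.chip_means``: IES bases highest, eliminated-minichromosome bases
    next, MAC-destined and background bases low.  Passing explicit
    ``categories``/``means`` plants arbitrary interval sets instead.  Bounded
    uniform noise (+-``chip_noise``) is added and values are clipped at 0.
    """
    rng = config.rng(44)
    mean_map = dict(means or config.chip_means)
    arrs = {
        cid: np.full(n, mean_map.get("BACKGROUND", 0.0))
        for cid, n in truth.contig_lengths.items()
    }
    if categories is None:
        categories = truth.category_intervals()
        order = ["MDS", "EMC", "IES"]  # IES last: overrides section fill
    else:
        order = [lab for lab in categories if lab in mean_map]
    for label in order:
        if label not in categories or label not in mean_map:
            continue
        for cid, ivs in categories[label].items():
            for a, b in ivs:
                arrs[cid][a:b] = mean_map[label]
    if config.chip_noise > 0:
        for cid in arrs:
            arrs[cid] = np.clip(
                arrs[cid] + rng.uniform(-config.chip_noise, config.chip_noise, len(arrs[cid])),
                0.0,
                None,
            )
    return CoverageTrack(data=arrs, sample_label="chip")


def simulate_expression(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Genes x stages expression matrix plus the gene->section map.

    Genes on eliminated minichromosomes are nonzero only at their configured
    conjugation stage (8 hpm / 16 hpm / 2 doublings by default) and zero
    during growth and at 2 hpm; control genes on retained sections are
    expressed at every stage.
    """
    rng = config.rng(55)
    rows = []
    for g in truth.genes:
        level = config.expression_level * rng.uniform(0.5, 1.5)
        if g.stage is None:
            row = {stage: level for stage in STAGES}
        else:
            row = {stage: (level if stage == g.stage else 0.0) for stage in STAGES}
        row["gene_id"] = g.gene_id
        rows.append(row)
    matrix = (
        pd.DataFrame(rows, columns=["gene_id", *STAGES]).set_index("gene_id")
        if rows
        else pd.DataFrame(columns=list(STAGES))
    )
    return matrix, truth.gene_to_section()


@dataclass
class SimData:
    """One complete simulated study."""

    config: SimConfig
    mic: dict[str, str]
    truth: SimTruth
    mac: MacSim


def simulate_dataset(config: SimConfig) -> SimData:
    """Convenience wrapper: germline genome plus somatic scaffolds and truth."""
    mic, truth = simulate_mic(config)
    mac = simulate_mac(config, mic, truth)
    return SimData(config=config, mic=mic, truth=truth, mac=mac)
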