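# Methods

This note documents the models, conventions and numerical choices behind
`minichrom`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and orientation

All coordinates are 0-based, half-open, on the forward strand of the MIC
assembly (BED convention). A Cbs hit on the `-` strand is reported at its
forward-strand window with the observed 15-mer given in G-strand orientation
(the strand on which it matches the classic sequence). Flank losses are
defined on the G strand: for a `-` strand copy the 5′ flank lies to the
right in forward coordinates, and the measurement code swaps sides
accordingly.

## Constrained motif model

The admissibility rule is combinatorial, not score-based: a 15-mer is a Cbs
copy iff its ten core positions ({4, 6–14}) match the classic sequence and
at most `max_substitutions` (default 2) of the five variable positions
({1, 2, 3, 5, 15}, the five A's) carry their single allowed alternative.
The variable set is fixed to the five A positions because only those are
described as tolerant; this also reconciles the "10-bp core" count with the
narrower 9-nt span (positions 6–14) used for core-distance measurements —
position 4 is invariant but not inside the contiguous span, so the
core-distance recheck defaults to the contiguous (6, 14) span while the
admissibility core is {4, 6–14}. The alternatives at positions 1, 5 and 15
are T, G and T; positions 2 and 3 default to T and are configurable because
their alternatives are less well constrained. Scanning matches the
enumerated admissible set (16 sequences by default) exactly on both strands
with `str.find`; windows containing N can never match. Overlapping hits are
all reported; the partitioner, not the scanner, resolves overlaps (keep the
leftmost, then the next non-overlapping hit), since near-tandem Cbs copies
separated by ~0–30 bp exist in repeat regions. A position frequency matrix
(`(count + pseudocount) / (n + 4·pseudocount)` per column) is provided as a
descriptive artifact and optional log-odds scorer against a uniform
background; it plays no part in admissibility.

## Telomere junctions and gap measurement

Telomerized ends are maximal tandem runs of the telomere unit (default
`GGGGTT`, the known *Tetrahymena* repeat; both the unit and its reverse
complement are tried at each scaffold end) of at least `min_repeats` = 3
units. The junction sequence is the `k` = 30 bp immediately interior to the
run; it is anchored in the MIC by exact match (a 2-bit-packed k-mer index;
an optional mismatch-tolerant scan exists but defaults to 0 mismatches since
junction sequence should be identical between assemblies). Only uniquely
anchoring ends are used downstream. Each unique end is assigned to the
nearest Cbs on its correct side within a window W = 50 bp — wider than the
historically quoted "within 30 bp" because a 3′ loss of mean 23.9 bp with
s.d. 6.9 bp exceeds 30 bp regularly; 50 bp covers ~4 s.d. A Cbs with at
least one assigned end is "functional"; measurements require both sides.
Flank loss is the count of MIC bases between the motif boundary and the
first retained base; `total_gap = 5′ + 15 + 3′` by construction, and the
identity is asserted per measurement. The flank-asymmetry test is Welch's
unequal-variance two-sample t-test (the choice of test is a package
decision; a permutation alternative is provided). Mean-gap conventions
disagree slightly in the source literature (56.79 vs 57.79 vs the
flank-implied 57.7 bp); the package reports all three rather than
reconciling them.

## Sections, naming, scaffold matching

`n` non-overlapping hits on a contig produce `n + 1` sections named
`echr<contig>.<i>` left to right; zero-length sections (adjacent copies) are
legal. Terminal sections (bounded by a contig end) are typed `cbs_terminal`,
fully Cbs-bounded ones `cbs_bounded`. Conservation — Σ section lengths +
15 × hits = contig length — is a tested invariant. Scaffold-to-section
matching requires telomeres at both scaffold ends and both telomere-stripped
ends anchoring uniquely inside the same section; it is positional (30-bp
end anchors), not a global alignment, because the claim being tested is
correspondence, not base identity. The length deficit
`delta = section − stripped scaffold` aggregates IES content plus the two
junction flank losses; deltas are exactly the planted IES totals in
zero-loss simulations, and a negative delta is flagged as a violation of
breakage-without-rearrangement.

## Coverage normalization and fate calls

Tracks are divided by their mean raw coverage over MDS bases, making the
operation idempotent and the MDS mean 1. Fate calls use the fraction of
non-IES bases below ε = 0.05 (normalized): eliminated if ≥ f_elim = 0.95,
retained if ≤ f_ret = 0.5, ambiguous between. The qualitative rule being
formalized is "totally devoid of reads"; ε > 0 tolerates a sporadic
mismapping floor, and the thresholds are explicit configuration. IES bases
are masked before the fraction is computed because they are absent from the
MAC regardless of section fate. With several mature samples a section is
eliminated only if eliminated in every one. EMC difference profiles split a
section into 100 equal integer-width bins (remainder absorbed by the last
bin; sections shorter than 100 bp fall back to 1-bp bins with a warning);
the width-weighted mean of bin means equals the section-wide mean
difference.

## Category statistics

ChIP enrichment is consumed as a precomputed per-base fold-enrichment track;
the per-category statistic is the base-weighted mean, so scaling the track
scales all means and leaves ratios unchanged. Genes are assigned to a
category by midpoint containment (avoids double counting across
boundaries); categories may overlap (IES lies inside Cbs-related sections),
so a gene can count in more than one category. Gene densities are reported
at full precision. Expression counting uses a strict `> threshold` rule with
threshold 0 by default (the expressed/not-expressed cut-off behind the
published per-stage counts is not stated); cluster rows sum their member
sections.

## Dilution model

Replication shortfall and degradation compose multiplicatively:
`(r·δ/2)^d`. The two published hypotheses — replication/segregation failure
versus active degradation — are nested as (r < 2, δ = 1) and (r = 2, δ < 1);
the forward model deliberately does not try to identify which, as the data
cannot distinguish them. A stochastic per-copy simulation (replicate with
probability r − 1, survive with δ, segregate with 1/2) matches the closed
form in expectation and is used as an independent check. The
elimination-window estimator simply brackets (last detected, first
undetected) and flags non-monotone detection patterns, widening to the
first non-detection after the last detection.

## Synthetic-data generator

The generator's defaults are the study conditions: class mix 95:90:24,
eliminated fraction 50/326, flank losses N(18.8, 5.3) and N(23.9, 6.9) bp
rounded to non-negative integers (truncation at ~3.5 s.d. is negligible),
total-gap mode N(56.79, 8.84) with the excess over 15 bp split binomially
between flanks in proportion to the flank means, telomere unit GGGGTT,
normalization depths 119× (mature) and 46× (24 hpm), ChIP means 0.04 (MDS) /
0.68 (IES) / 0.60 (EMC), AT fraction 0.75 (the genome is AT-rich; this
matters only for chance-hit rates), mismapping floor 0.005. Scale
parameters (contig count/length, number of sites) are chosen per analysis;
the default study runs at ~5 Mb with 209 sites, and the validation suite
includes a ~10-Mb round trip. All randomness derives from a single seed via
per-stage streams, so identical configurations are byte-identical.

Deliberate idealizations, and hence what passing tests do and do not show:

* Coverage is generated directly as per-base Poisson draws — no reads, no
  alignment, no GC or mappability structure. Fate-recovery accuracy of ~1.0
  here bounds only the statistical part of the problem, not mapping
  artifacts in real data.
* After assembly the genome is rescanned and any *chance* admissible 15-mer
  is destroyed by one core-base mutation, so the scanner's expected output
  equals the planted truth exactly; real genomes may contain Cbs-like
  sequences that never function.
* Junctions are made unambiguous: if the retained sequence adjacent to a
  junction itself begins (or ends) with a telomere unit, the run detector
  would absorb it, so the generator mutates that edge base. In real data
  such junctions are intrinsically ambiguous at unit resolution.
* The ChIP track is category means plus bounded uniform noise; the
  "Cbs-related section" mean is the length-weighted mixture of its MDS /
  IES / EMC constituents rather than an independently planted value.
* Each simulated gene is expressed at exactly one conjugation stage (or at
  all stages for retained-section controls); real stage profiles overlap.
* Spatial clustering of EMCs and tandem Cbs repeat families are not
  modelled.

## Problem sizes and tolerances

The default validation runs use: 10,000-junction simulations for flank-loss
recovery (sample s.e. ≈ 0.05 bp, asserted within ±0.2 bp of the generating
means, ±0.3 bp for the total gap); a ~10-Mb, 400-site genome for the full
round trip; 1,000 replicates for the Welch-test type-I calibration
(3σ binomial band). PFM columns sum to 1 within 1e-9; normalization
idempotence is asserted within 1e-9; fate-recovery accuracy is asserted at
≥ 0.99 with depth ≥ 20 and floor ≤ 0.01.
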