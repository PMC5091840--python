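"""Constrained Cbs model: enumeration, classification, PFM, genome scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minichrom import (
    CLASSIC_CBS,
    CbsMotifModel,
    build_pfm,
    class_counts,
    classify_15mer,
    enumerate_admissible,
    revcomp,
    scan_genome,
)


def _variant(*subs):
    model = CbsMotifModel()
    s = list(CLASSIC_CBS)
    for pos in subs:
        s[pos - 1] = model.variable_alternatives[pos]
    return "".join(s)


class TestEnumerate:
    def test_default_model_yields_16_admissible_15mers(self):
        # C(5,0) + C(5,1) + C(5,2) over the five variable positions
        admissible = enumerate_admissible()
        assert len(admissible) == 16
        assert CLASSIC_CBS in admissible
        assert all(classify_15mer(s).admissible for s in admissible)

    def test_zero_substitutions_is_identity(self):
        model = CbsMotifModel(max_substitutions=0)
        assert enumerate_admissible(model) == {CLASSIC_CBS}

    def test_single_variable_position(self):
        model = CbsMotifModel(variable_alternatives={1: "T"}, max_substitutions=1)
        assert enumerate_admissible(model) == {CLASSIC_CBS, _variant(1)}

    def test_brute_force_enumeration_agrees(self):
        # independent oracle: filter all strings over the per-position alphabets
        import itertools

        model = CbsMotifModel()
        alphabets = []
        for pos in range(1, 16):
            alt = model.variable_alternatives.get(pos)
            alphabets.append((CLASSIC_CBS[pos - 1],) if alt is None else (CLASSIC_CBS[pos - 1], alt))
        brute = {
            "".join(s)
            for s in itertools.product(*alphabets)
            if sum(a != b for a, b in zip(s, CLASSIC_CBS)) <= 2
        }
        assert enumerate_admissible(model) == brute


class TestClassify:
    @pytest.mark.parametrize(
        "seq,klass,positions",
        [
            (CLASSIC_CBS, 0, frozenset()),
            (_variant(1), 1, frozenset({1})),
            (_variant(5), 1, frozenset({5})),
            (_variant(1, 15), 2, frozenset({1, 15})),
        ],
    )
    def test_admissible_classes(self, seq, klass, positions):
        res = classify_15mer(seq)
        assert res.admissible
        assert res.substitution_class == klass
        assert res.substituted_positions == positions

    @pytest.mark.parametrize(
        "seq,reason",
        [
            ("AAAGCGGTTGGTTTA", "disallowed alternative"),  # pos 5 -> C
            (_variant(1, 2, 3), "too many substitutions"),
            ("AAACAGGTTGGTTTA", "core mismatch"),  # pos 4 altered
            ("AAAGAGGTTGGTTNA", "ambiguous base"),
        ],
    )
    def test_rejections_carry_reasons(self, seq, reason):
        res = classify_15mer(seq)
        assert not res.admissible
        assert res.reason == reason

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            classify_15mer("AAAG")


class TestPfm:
    def test_identical_seeds_give_unit_columns(self):
        pfm = build_pfm([CLASSIC_CBS] * 3, pseudocount=0)
        for pos, base in enumerate(CLASSIC_CBS, start=1):
            assert pfm.frequency(pos, base) == 1.0

    def test_mixed_seeds_split_frequency(self):
        pfm = build_pfm([CLASSIC_CBS, _variant(1)], pseudocount=0)
        assert pfm.frequency(1, "A") == 0.5
        assert pfm.frequency(1, "T") == 0.5

    def test_pseudocount_formula(self):
        pfm = build_pfm([CLASSIC_CBS], pseudocount=1.0)
        assert pfm.frequency(1, "A") == pytest.approx(2 / 5)
        assert pfm.frequency(1, "C") == pytest.approx(1 / 5)

    def test_core_columns_pure_for_any_admissible_seed_set(self):
        model = CbsMotifModel()
        pfm = build_pfm(sorted(enumerate_admissible(model)), pseudocount=0)
        for pos in model.core_positions:
            assert pfm.frequency(pos, CLASSIC_CBS[pos - 1]) == 1.0

    def test_columns_sum_to_one(self):
        pfm = build_pfm(sorted(enumerate_admissible()), pseudocount=0.37)
        assert np.allclose(pfm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_classic_has_maximal_log_odds(self):
        pfm = build_pfm(sorted(enumerate_admissible()), pseudocount=0.5)
        best = pfm.log_odds_score(CLASSIC_CBS)
        assert all(pfm.log_odds_score(s) <= best for s in enumerate_admissible())

    @pytest.mark.parametrize("seeds", [[], ["AAAG"]])
    def test_invalid_seeds_raise(self, seeds):
        with pytest.raises(ValueError):
            build_pfm(seeds)


def _random_seq(rng, n, p=(0.375, 0.125, 0.125, 0.375)):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestScan:
    def test_planted_classic_found_once(self, rng):
        seq = _random_seq(rng, 1000)
        seq = seq[:400] + CLASSIC_CBS + seq[415:]
        hits = scan_genome({"c": seq})
        planted = [h for h in hits if h.start == 400]
        assert len(planted) == 1
        assert planted[0].strand == "+"
        assert planted[0].substitution_class == 0

    def test_reverse_complement_planting(self, rng):
        seq = _random_seq(rng, 600)
        seq = seq[:200] + revcomp(CLASSIC_CBS) + seq[215:]
        hits = [h for h in scan_genome({"c": seq}) if h.start == 200]
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].observed == CLASSIC_CBS  # reported in G-strand orientation

    def test_poly_c_contig_is_empty(self):
        assert scan_genome({"c": "C" * 500}) == []

    def test_overlapping_adjacent_copies_all_reported(self):
        seq = "TTTT" + CLASSIC_CBS + CLASSIC_CBS + "TTTT"
        starts = {h.start for h in scan_genome({"c": seq})}
        assert {4, 19} <= starts

    def test_scan_matches_bruteforce_oracle(self, rng):
        # oracle: naive substring enumeration of every admissible 15-mer,
        # both strands, on a genome with planted variants
        seq = list(_random_seq(rng, 30_000))
        plant_at = [1000, 5000, 12_000, 12_015, 25_000]
        variants = [CLASSIC_CBS, _variant(1), _variant(5, 15), _variant(2), _variant(3, 5)]
        for pos, var in zip(plant_at, variants):
            s = var if pos % 2 == 0 else revcomp(var)
            seq[pos : pos + 15] = s
        seq = "".join(seq)
        expected = set()
        for pat in enumerate_admissible():
            for strand, needle in (("+", pat), ("-", revcomp(pat))):
                for i in range(len(seq) - 14):
                    if seq[i : i + 15] == needle:
                        expected.add((i, strand, pat))
        got = {(h.start, h.strand, h.observed) for h in scan_genome({"c": seq})}
        assert got == expected
        assert {(p, s) for p, s, _ in got} >= {
            (p, "+" if p % 2 == 0 else "-") for p in plant_at
        }

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 400))
    def test_strand_symmetry(self, seed, offset):
        rng = np.random.default_rng(seed)
        seq = _random_seq(rng, 500)
        seq = seq[:offset] + CLASSIC_CBS + seq[offset + 15 :]
        fwd = scan_genome({"c": seq})
        rev = scan_genome({"c": revcomp(seq)})
        L = len(seq)
        mapped = {(L - 15 - h.start, "+-"[h.strand == "+"], h.observed) for h in rev}
        assert {(h.start, h.strand, h.observed) for h in fwd} == mapped

    def test_class_counts_partition_hits(self, small_sim):
        hits = scan_genome(small_sim.mic)
        counts = class_counts(hits)
        assert sum(counts.values()) == len(hits)
        assert set(counts) <= {0, 1, 2}


class TestModelValidation:
    def test_variable_position_must_be_a(self):
        with pytest.raises(ValueError):
            CbsMotifModel(variable_alternatives={4: "T"})  # classic has G at 4

    def test_max_substitutions_bounded_by_variable_count(self):
        with pytest.raises(ValueError):
            CbsMotifModel(variable_alternatives={1: "T"}, max_substitutions=2)

    def test_core_and_variable_positions_partition_the_motif(self):
        model = CbsMotifModel()
        assert model.core_positions == frozenset({4, *range(6, 15)})
        assert len(model.core_positions) + len(model.variable_positions) == 15
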