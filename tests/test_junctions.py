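"""Telomerized-end detection, MIC anchoring, junction measurement and flank stats."""

import numpy as np
import pytest
from scipy import stats as sps

from minichrom import (
    CLASSIC_CBS,
    AnchoredEnd,
    CbsHit,
    FunctionalCbs,
    KmerIndex,
    TELOMERE_UNIT,
    TelomerizedEnd,
    anchor_end,
    anchor_ends,
    core_distance_recheck,
    find_telomerized_ends,
    flank_asymmetry_test,
    measure_junction,
    revcomp,
    validate_functional_cbs,
)

RNG = np.random.default_rng(42)
UNIQUE60 = "".join(RNG.choice(list("ACGT"), size=60, p=[0.375, 0.125, 0.125, 0.375]))


class TestFindTelomerizedEnds:
    def test_left_end_run_and_junction(self):
        scaffold = TELOMERE_UNIT * 10 + UNIQUE60
        ends = find_telomerized_ends({"s": scaffold}, min_repeats=3, k=30)
        assert len(ends) == 1
        (e,) = ends
        assert (e.side, e.repeat_count) == ("left", 10)
        assert e.junction_seq == UNIQUE60[:30]

    def test_right_end_with_complementary_units(self):
        scaffold = UNIQUE60 + revcomp(TELOMERE_UNIT) * 5
        ends = find_telomerized_ends({"s": scaffold})
        assert [(e.side, e.repeat_count) for e in ends] == [("right", 5)]
        assert ends[0].junction_seq == UNIQUE60[-30:]

    def test_single_unit_copy_not_reported(self):
        scaffold = TELOMERE_UNIT + UNIQUE60
        assert find_telomerized_ends({"s": scaffold}, min_repeats=3) == []

    def test_too_short_scaffold_skipped(self):
        scaffold = TELOMERE_UNIT * 4 + "ACGTACGT"  # < k interior bases
        assert find_telomerized_ends({"s": scaffold}, k=30) == []

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            find_telomerized_ends({}, telomere_unit="")
        with pytest.raises(ValueError):
            find_telomerized_ends({}, min_repeats=0)


def _mic_contig(n=2000, seed=5):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n, p=[0.375, 0.125, 0.125, 0.375]))


class TestAnchor:
    mic = {"m": _mic_contig()}

    def _end(self, side, junction):
        return TelomerizedEnd("s", side, 5, junction)

    def test_left_end_forward_match_retains_downstream(self):
        a = anchor_end(self._end("left", self.mic["m"][100:130]), self.mic)
        assert (a.unique, a.contig_id, a.junction_coord, a.retained_side) == (
            True, "m", 100, "downstream",
        )

    def test_left_end_reverse_match_retains_upstream(self):
        a = anchor_end(self._end("left", revcomp(self.mic["m"][100:130])), self.mic)
        assert (a.junction_coord, a.retained_side) == (129, "upstream")

    def test_right_end_forward_match_retains_upstream(self):
        a = anchor_end(self._end("right", self.mic["m"][100:130]), self.mic)
        assert (a.junction_coord, a.retained_side) == (129, "upstream")

    def test_duplicate_target_flagged_non_unique(self):
        seg = self.mic["m"][100:130]
        genome = {"m": self.mic["m"] + "TTTT" + seg}
        a = anchor_end(self._end("left", seg), genome)
        assert not a.unique
        assert a.n_matches == 2

    def test_absent_sequence_unanchored(self):
        a = anchor_end(self._end("left", "A" * 30), self.mic)
        assert not a.unique
        assert a.n_matches == 0

    def test_mismatch_tolerant_anchoring(self):
        seg = list(self.mic["m"][100:130])
        seg[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[10]]
        a = anchor_end(self._end("left", "".join(seg)), self.mic, max_mismatches=1)
        assert a.unique and a.junction_coord == 100

    def test_kmer_index_skips_n_windows(self):
        idx = KmerIndex({"m": "ACGTNACGTACGTA"}, k=4)
        # windows overlapping the N (positions 1-4) are excluded
        assert idx.find("ACGT") == [("m", 0), ("m", 5), ("m", 9)]
        assert idx.find("CGTN") == []
        with pytest.raises(ValueError):
            idx.find("ACGTA")


def _hit(start, strand="+", contig="m"):
    return CbsHit(contig, start, strand, CLASSIC_CBS, 0)


def _anchored(coord, retained, contig="m", unique=True):
    end = TelomerizedEnd("s", "left", 5, "N" * 30)
    return AnchoredEnd(end, contig if unique else None, coord if unique else None,
                       retained if unique else None, unique, 1 if unique else 0)


class TestValidateAndMeasure:
    def test_two_sided_assignment_and_measurement(self):
        hit = _hit(500)
        left = _anchored(500 - 18 - 1, "upstream")    # 18 bp 5' loss
        right = _anchored(515 + 24, "downstream")     # 24 bp 3' loss
        functional, unassigned = validate_functional_cbs([hit], [left, right])
        assert len(functional) == 1 and not unassigned
        m = measure_junction(functional[0])
        assert (m.five_prime_loss, m.three_prime_loss, m.total_gap) == (18, 24, 57)

    def test_one_sided_site_flagged(self):
        functional, _ = validate_functional_cbs(
            [_hit(500)], [_anchored(515 + 20, "downstream")]
        )
        assert functional[0].one_sided
        m = measure_junction(functional[0])
        assert m.five_prime_loss is None
        assert m.three_prime_loss == 20
        assert m.total_gap is None

    def test_flush_junctions_give_minimum_gap(self):
        functional, _ = validate_functional_cbs(
            [_hit(500)], [_anchored(499, "upstream"), _anchored(515, "downstream")]
        )
        m = measure_junction(functional[0])
        assert (m.five_prime_loss, m.three_prime_loss, m.total_gap) == (0, 0, 15)

    def test_minus_strand_swaps_flanks(self):
        hit = _hit(500, strand="-")
        functional, _ = validate_functional_cbs(
            [hit], [_anchored(500 - 10 - 1, "upstream"), _anchored(515 + 30, "downstream")]
        )
        m = measure_junction(functional[0])
        # left gap 10 is the 3' flank of the G (minus) strand
        assert (m.five_prime_loss, m.three_prime_loss) == (30, 10)

    def test_distant_end_left_unassigned(self):
        functional, unassigned = validate_functional_cbs(
            [_hit(500)], [_anchored(500 - 200, "upstream")], window=50
        )
        assert functional == [] and len(unassigned) == 1

    def test_non_unique_end_excluded(self):
        functional, unassigned = validate_functional_cbs(
            [_hit(500)], [_anchored(None, None, unique=False)]
        )
        assert functional == [] and len(unassigned) == 1

    def test_end_assigned_to_nearer_of_two_hits(self):
        near, far = _hit(500), _hit(600)
        end = _anchored(480, "upstream")  # 19 bp from 500, 119 from 600
        functional, _ = validate_functional_cbs([near, far], [end], window=150)
        assert [f.hit.start for f in functional] == [500]


class TestRecoveryOnSimulation:
    def test_gap_identity_holds_for_every_measurement(self, small_survey):
        for m in small_survey.two_sided:
            assert m.total_gap - m.five_prime_loss - m.three_prime_loss == 15

    def test_measured_losses_equal_planted_losses(self, small_sim, small_survey):
        site = {(p.contig_id, p.start): p for p in small_sim.truth.cbs_sites}
        assert small_survey.two_sided, "simulation produced no two-sided sites"
        for m in small_survey.two_sided:
            p = site[(m.contig_id, m.cbs_start)]
            assert (m.five_prime_loss, m.three_prime_loss) == (
                p.five_prime_loss, p.three_prime_loss,
            )

    def test_anchoring_injective_without_repeats(self, small_survey):
        coords = [
            (a.contig_id, a.junction_coord, a.retained_side)
            for a in small_survey.anchored if a.unique
        ]
        assert len(coords) == len(set(coords))
        assert all(a.unique for a in small_survey.anchored)


class TestAsymmetryStatistics:
    @staticmethod
    def _measurements(five, three):
        return [
            type("M", (), {"five_prime_loss": int(f), "three_prime_loss": int(t),
                           "two_sided": True})()
            for f, t in zip(five, three)
        ]

    def test_null_case_rarely_rejects(self, rng):
        five = np.round(rng.normal(20, 5, 500)).clip(0)
        three = np.round(rng.normal(20, 5, 500)).clip(0)
        res = flank_asymmetry_test(self._measurements(five, three))
        assert abs(res["difference"]) < 1.5
        assert res["p_value"] > 0.01

    def test_alternative_detected_at_study_parameters(self, rng):
        five = np.round(rng.normal(18.8, 5.3, 209)).clip(0)
        three = np.round(rng.normal(23.9, 6.9, 209)).clip(0)
        res = flank_asymmetry_test(self._measurements(five, three))
        assert res["difference"] == pytest.approx(5.1, abs=1.5)
        assert res["p_value"] < 1e-6

    def test_constant_equal_flanks_have_zero_difference(self):
        res = flank_asymmetry_test(self._measurements([10] * 5, [10] * 5))
        assert res["difference"] == 0.0

    def test_permutation_variant_agrees_on_clear_effect(self, rng):
        five = np.round(rng.normal(10, 2, 60)).clip(0)
        three = np.round(rng.normal(20, 2, 60)).clip(0)
        m = self._measurements(five, three)
        welch = flank_asymmetry_test(m)
        perm = flank_asymmetry_test(m, method="permutation", n_permutations=500, seed=0)
        assert welch["p_value"] < 1e-6
        assert perm["p_value"] < 0.01

    def test_fewer_than_two_observations_raise(self):
        with pytest.raises(ValueError):
            flank_asymmetry_test(self._measurements([3], [4]))

    def test_null_rejection_rate_matches_level(self, rng):
        # type-I error calibration of the Welch test over 1000 replicates
        a = rng.normal(20, 5, size=(1000, 30))
        b = rng.normal(20, 5, size=(1000, 30))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = (p < 0.05).mean()
        # 3-sigma binomial band around 0.05
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000)


class TestCoreDistance:
    def test_offsets_follow_core_span(self):
        m = TestAsymmetryStatistics._measurements([0, 0], [0, 0])
        res = core_distance_recheck(m, core_span=(6, 14))
        assert (res["offset5"], res["offset3"]) == (5, 1)
        # zero-loss junctions: distances equal the fixed motif-to-core offsets
        assert res["mean5_to_core"] == 5.0
        assert res["mean3_to_core"] == 1.0

    def test_asymmetry_vanishes_when_symmetric_about_core(self, rng):
        five = np.round(rng.normal(20, 3, 300)).clip(0)
        three = five + 4  # equal distances to a (6,14) core: 5' +5 == 3' +1
        res = core_distance_recheck(TestAsymmetryStatistics._measurements(five, three))
        assert res["difference_to_motif"] == pytest.approx(4.0)
        assert res["difference_to_core"] == pytest.approx(0.0)

    def test_invalid_core_span_raises(self):
        with pytest.raises(ValueError):
            core_distance_recheck([], core_span=(0, 14))
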