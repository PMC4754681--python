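import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psocid_id import (
    BarcodeLibrary,
    PairwiseAlignment,
    SequenceRecord,
    distance_matrix,
    gap_summary,
    global_align,
    k2p_distance,
    p_distance,
    welch_t_test,
)
from psocid_id.align_distance import DEFAULT_SCORES, K2PSaturationWarning

import oracles

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.seq_a_aligned == aln.seq_b_aligned == "ACGT"
        assert aln.score == 4.0

    def test_single_gap_opposite_c(self):
        aln = global_align("ACGT", "AGT", match=1, mismatch=-1,
                           gap_open=-2, gap_extend=-1)
        assert aln.seq_a_aligned == "ACGT"
        assert aln.seq_b_aligned == "A-GT"
        assert aln.score == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @settings(derandomize=True, max_examples=150)
    @given(dna, dna)
    def test_score_symmetry_and_gap_removal(self, a, b):
        f = global_align(a, b)
        r = global_align(b, a)
        assert f.score == pytest.approx(r.score)
        assert f.seq_a_aligned.replace("-", "") == a
        assert f.seq_b_aligned.replace("-", "") == b

    @settings(derandomize=True, max_examples=150)
    @given(dna, dna)
    def test_score_matches_recursive_oracle(self, a, b):
        aln = global_align(a, b)
        expected = oracles.nw_score(a, b, **DEFAULT_SCORES)
        assert aln.score == pytest.approx(expected)
        # and the reported path achieves the reported score
        assert oracles.alignment_score(
            aln.seq_a_aligned, aln.seq_b_aligned,
            **DEFAULT_SCORES) == pytest.approx(aln.score)

    def test_long_noisy_pair_path_is_score_consistent(self, rng):
        base = "".join(rng.choice(list("ACGT"), 400))
        noisy = list(base)
        for pos in rng.choice(400, 8, replace=False):
            noisy[pos] = "ACGT"[(("ACGT".index(noisy[pos])) + 1) % 4]
        noisy = "".join(noisy[:150] + ["TT"] + noisy[150:])  # one insertion
        aln = global_align(base, noisy)
        assert oracles.alignment_score(
            aln.seq_a_aligned, aln.seq_b_aligned,
            **DEFAULT_SCORES) == pytest.approx(aln.score)


class TestDistances:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("AC-T", "ACGT", 0.0),     # gap column excluded -> 0/3
    ])
    def test_p_distance(self, a, b, expected):
        aln = PairwiseAlignment(a, b, 0.0)
        assert p_distance(aln) == pytest.approx(expected)

    def test_p_distance_gap_column_denominator(self):
        aln = PairwiseAlignment("AC-T", "ACGA", 0.0)
        assert p_distance(aln) == pytest.approx(1 / 3)

    def test_k2p_closed_form(self):
        # P=0.25 transitions, Q=0: d = -0.5*ln(0.5)
        aln = PairwiseAlignment("AACC", "AGCC", 0.0)
        assert k2p_distance(aln) == pytest.approx(-0.5 * math.log(0.5), abs=1e-9)
        assert k2p_distance(aln) == pytest.approx(0.34657, abs=1e-5)

    def test_k2p_zero_for_identical(self):
        assert k2p_distance(PairwiseAlignment("ACGT", "ACGT", 0.0)) == 0.0

    def test_k2p_saturation_flagged(self):
        aln = PairwiseAlignment("AAAA", "GGGG", 0.0)  # P=1
        with pytest.warns(K2PSaturationWarning):
            assert math.isnan(k2p_distance(aln))

    @settings(derandomize=True, max_examples=150)
    @given(dna, dna)
    def test_k2p_dominates_p(self, a, b):
        aln = global_align(a, b)
        p = p_distance(aln)
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", K2PSaturationWarning)
                k = k2p_distance(aln)
        if not (math.isnan(p) or math.isnan(k)):
            assert k >= p - 1e-12

    def test_k2p_converges_to_p_for_small_distances(self):
        # one substitution over 1000 compared sites: agreement to 1e-6
        a = "ACGT" * 250
        b = "CCGT" + a[4:]
        aln = global_align(a, b)
        assert abs(k2p_distance(aln) - p_distance(aln)) < 1e-6


class TestDistanceMatrix:
    def test_identical_records_zero_matrix(self):
        lib = BarcodeLibrary([SequenceRecord("a", "ACGTACGT"),
                              SequenceRecord("b", "ACGTACGT")])
        dm = distance_matrix(lib, model="p")
        assert np.allclose(dm.d, 0.0)

    def test_divergent_record_dominates(self):
        lib = BarcodeLibrary([
            SequenceRecord("a", "ACGTACGTACGTACGTACGT"),
            SequenceRecord("b", "ACGTACGTACGTACGTACGA"),
            SequenceRecord("c", "TGCAGCTATGCATTACGGCA"),
        ])
        dm = distance_matrix(lib, model="p")
        flat = [(dm.d[i, j], {dm.ids[i], dm.ids[j]})
                for i in range(3) for j in range(i + 1, 3)]
        flat.sort(key=lambda x: -x[0])
        assert "c" in flat[0][1] and "c" in flat[1][1]

    def test_matches_pairwise_recomputation(self, rng):
        recs = [SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 30)))
                for i in range(6)]
        lib = BarcodeLibrary(recs)
        dm = distance_matrix(lib, model="p")
        for i in range(6):
            assert dm.d[i, i] == 0.0
            for j in range(i + 1, 6):
                aln = global_align(recs[i].seq, recs[j].seq)
                expected = oracles.p_distance(aln.seq_a_aligned, aln.seq_b_aligned)
                assert dm.d[i, j] == pytest.approx(expected)
        assert np.allclose(dm.d, dm.d.T)


class TestGapSummary:
    def test_two_clean_species(self, toy_library):
        dm = distance_matrix(toy_library, model="p")
        gs = gap_summary(dm, toy_library)
        assert (gs["intra_max"] == 0.0).all()
        assert (gs["inter_min"] > 0).all()
        assert gs["gap"].all()

    def test_single_species_degenerate(self):
        lib = BarcodeLibrary([SequenceRecord("a", "ACGTACGT", species="s"),
                              SequenceRecord("b", "ACGAACGT", species="s")])
        dm = distance_matrix(lib, model="p")
        gs = gap_summary(dm, lib)
        assert len(gs) == 1
        assert math.isnan(gs.loc["s", "inter_min"])

    def test_singleton_species_intra_undefined(self):
        lib = BarcodeLibrary([SequenceRecord("a", "ACGTACGT", species="s1"),
                              SequenceRecord("b", "ACGAACGT", species="s1"),
                              SequenceRecord("c", "TTTTACGG", species="s2")])
        dm = distance_matrix(lib, model="p")
        gs = gap_summary(dm, lib)
        assert math.isnan(gs.loc["s2", "intra_max"])
        assert gs.loc["s2", "inter_min"] > 0

    def test_extremes_match_label_multiset_bruteforce(self, rng):
        species = ["x", "x", "x", "y", "y", "z", "z", "z"]
        recs = [SequenceRecord(f"r{i}", "".join(rng.choice(list("ACGT"), 25)),
                               species=sp) for i, sp in enumerate(species)]
        lib = BarcodeLibrary(recs)
        dm = distance_matrix(lib, model="p")
        gs = gap_summary(dm, lib)
        for sp in "xyz":
            intra = [dm.d[i, j] for i in range(8) for j in range(i + 1, 8)
                     if species[i] == species[j] == sp]
            inter = [dm.d[i, j] for i in range(8) for j in range(8)
                     if i != j and (species[i] == sp) != (species[j] == sp)]
            assert gs.loc[sp, "intra_min"] == pytest.approx(min(intra))
            assert gs.loc[sp, "intra_max"] == pytest.approx(max(intra))
            assert gs.loc[sp, "inter_min"] == pytest.approx(min(inter))
            assert gs.loc[sp, "inter_max"] == pytest.approx(max(inter))


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = welch_t_test([1, 2, 3], [2, 3, 4])
        assert abs(res.t) == pytest.approx(math.sqrt(1.5), abs=1e-12)
        assert res.df == pytest.approx(4.0, abs=1e-12)

    def test_antisymmetry(self):
        a, b = [0.1, 0.4, 0.2, 0.3], [0.5, 0.9, 0.8]
        fwd = welch_t_test(a, b)
        rev = welch_t_test(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)
        # sign of t follows the mean difference
        assert fwd.t < 0

    def test_matches_textbook_formulas(self, rng):
        a = list(rng.normal(0, 1, 9))
        b = list(rng.normal(1, 2, 14))
        res = welch_t_test(a, b)
        t_exp, df_exp = oracles.welch(a, b)
        assert res.t == pytest.approx(t_exp)
        assert res.df == pytest.approx(df_exp)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            welch_t_test([1.0, 1.0], [1.0, 1.0])
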