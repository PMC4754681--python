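import pytest
from Bio.SeqUtils import MeltingTemp as mt

from psocid_id import (
    BarcodeLibrary,
    SequenceRecord,
    dg_3prime,
    enumerate_candidates,
    false_priming_score,
    gc_content,
    load_table1_fixture,
    max_complementary_stem,
    max_hairpin_stem,
    melting_temp,
    reverse_complement,
    select_optimal_pair,
    table1_pairs,
)
from psocid_id.msa_snp import MultipleAlignment
from psocid_id.primer_design import (
    NN_DH,
    NN_DS,
    DesignConfig,
    dg37_stack,
    three_prime_dimer_stem,
)

import oracles


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 100.0),
        ("ATAT", 0.0),
        ("GAAATGCACTAGAACCGAGA", 45.0),   # 9 of 20 by direct count
    ])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_rejected(self):
        with pytest.raises(ValueError):
            gc_content("ACGN")


class TestMeltingTemp:
    def test_strand_symmetry(self, rng):
        for _ in range(25):
            s = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 26))))
            assert melting_temp(s) == pytest.approx(
                melting_temp(reverse_complement(s)), abs=1e-9)

    def test_published_lbf_within_5c(self):
        assert melting_temp("CGCACATTGCCGAGCTAGGAT") == pytest.approx(62.3, abs=5)

    def test_total_enthalpy_is_stack_sum(self, rng):
        from psocid_id.primer_design import duplex_dh_ds, INIT_DH, INIT_DS
        s = "".join(rng.choice(list("ACGT"), 12))
        dh, ds = duplex_dh_ds(s)
        dh_exp = INIT_DH[s[0]] + INIT_DH[s[-1]] + sum(
            NN_DH[s[i:i + 2]] for i in range(11))
        ds_exp = INIT_DS[s[0]] + INIT_DS[s[-1]] + sum(
            NN_DS[s[i:i + 2]] for i in range(11))
        assert dh == pytest.approx(dh_exp)
        assert ds == pytest.approx(ds_exp)

    def test_agrees_with_independent_nn_implementation(self, rng):
        # Bio.SeqUtils.MeltingTemp with the same unified table and identical
        # solution conditions (C_T/4 = 62.5 nM, 50 mM Na+, entropic salt corr)
        for _ in range(30):
            s = "".join(rng.choice(list("ACGT"), int(rng.integers(10, 26))))
            expected = mt.Tm_NN(s, nn_table=mt.DNA_NN3, dnac1=125, dnac2=125,
                                Na=50, saltcorr=5)
            assert melting_temp(s) == pytest.approx(expected, abs=0.05)

    def test_short_oligo_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACG")


class TestDG3Prime:
    def test_at_end_weaker_than_gc_end(self):
        assert abs(dg_3prime("GCGCGCAAAAA")) < abs(dg_3prime("ATATAGCGCGC"))

    def test_stack_sum_for_ggcgc_end(self):
        seq = "ATATATGGCGC"
        expected = sum(dg37_stack(p) for p in ("GG", "GC", "CG", "GC"))
        assert dg_3prime(seq) == pytest.approx(expected)
        # the published ΔG37 magnitudes bound a pentamer below 9 kcal/mol
        assert abs(dg_3prime(seq)) < 9

    def test_negative_for_stable_ends(self):
        assert dg_3prime("AAAAAGCGCGC") < 0

    def test_short_rejected(self):
        with pytest.raises(ValueError):
            dg_3prime("ACGTA")


class TestStems:
    @pytest.mark.parametrize("a,b,expected", [
        ("AAAA", "AAAA", 0),    # A cannot pair A
        ("ACGT", "ACGT", 4),    # palindrome fully self-anneals
        ("AAAA", "TTTT", 4),
    ])
    def test_examples(self, a, b, expected):
        assert max_complementary_stem(a, b) == expected

    def test_matches_exhaustive_offset_scan(self, rng):
        for _ in range(120):
            a = "".join(rng.choice(list("ACGT"), 10))
            b = "".join(rng.choice(list("ACGT"), 10))
            assert max_complementary_stem(a, b) == oracles.max_stem(a, b)

    def test_three_prime_stem_bounded_by_full_stem(self, rng):
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), 12))
            b = "".join(rng.choice(list("ACGT"), 12))
            assert three_prime_dimer_stem(a, b) <= max_complementary_stem(a, b)

    def test_hairpin_requires_loop(self):
        # stem of 3 with a 3-base loop
        assert max_hairpin_stem("GGGAAATCCC", min_loop=3) >= 3
        # complementary ends too close for any loop
        assert max_hairpin_stem("GCGC", min_loop=3) == 0

    def test_published_panel_hairpins_within_cap(self):
        for f, r in table1_pairs().values():
            assert max_hairpin_stem(f.seq) <= 3
            assert max_hairpin_stem(r.seq) <= 3


class TestFalsePriming:
    def test_dissimilar_template_scores_low(self):
        primer = "GGGGGGGGGGGGGGGGGG"
        template = "ATATATATATATATATATATATATATATATAT"
        assert false_priming_score(primer, template) < 30

    def test_perfect_offtarget_duplicate_scores_100(self):
        primer = "ACGTACGTTGCAGGCTAA"
        template = "TTTTT" + primer + "TTTTT"
        assert false_priming_score(primer, template) == pytest.approx(100.0)

    def test_excluding_intended_site(self):
        primer = "ACGTACGTTGCAGGCTAA"
        template = "TTTTT" + primer + "TTTTT"
        score = false_priming_score(primer, template,
                                    exclude=(6, 5 + len(primer)))
        assert score < 100.0

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(40):
            primer = "".join(rng.choice(list("ACGT"), 18))
            template = "".join(rng.choice(list("ACGT"), 60))
            assert false_priming_score(primer, template) == pytest.approx(
                oracles.false_priming(primer, template))


def _toy_design_msa():
    """Two species x 2 rows, diverged block in the middle of a shared frame."""
    import numpy as np
    rng = np.random.default_rng(77)
    flank_l = "".join(rng.choice(list("ACGT"), 80))
    flank_r = "".join(rng.choice(list("ACGT"), 80))
    core_a = "".join(rng.choice(list("ACGT"), 160))
    core_b = "".join(
        "ACGT"[("ACGT".index(c) + 1 + int(rng.integers(0, 3))) % 4]
        if rng.random() < 0.4 else c for c in core_a)
    seq_a = flank_l + core_a + flank_r
    seq_b = flank_l + core_b + flank_r
    lib = BarcodeLibrary([
        SequenceRecord("a1", seq_a, species="spA"),
        SequenceRecord("a2", seq_a, species="spA"),
        SequenceRecord("b1", seq_b, species="spB"),
        SequenceRecord("b2", seq_b, species="spB"),
    ])
    msa = MultipleAlignment(["a1", "a2", "b1", "b2"],
                            [seq_a, seq_a, seq_b, seq_b])
    return lib, msa


class TestEnumerateAndSelect:
    def test_no_diagnostic_sites_empty_with_tally(self):
        lib, msa = _toy_design_msa()
        result = enumerate_candidates(msa, lib, [], "spA", DesignConfig())
        assert result.candidates == []
        assert result.tally["no_anchor"] > 0

    def test_candidates_repass_all_filters(self):
        from psocid_id import find_diagnostic_sites
        lib, msa = _toy_design_msa()
        cfg = DesignConfig()
        sites = find_diagnostic_sites(msa, lib, "spA")
        assert sites
        result = enumerate_candidates(msa, lib, sites, "spA", cfg)
        assert result.candidates
        site_cols = {s.column for s in sites}
        for c in result.candidates:
            assert cfg.primer_len[0] <= len(c.seq) <= cfg.primer_len[1]
            assert cfg.gc_range[0] <= gc_content(c.seq) <= cfg.gc_range[1]
            assert cfg.tm_range[0] <= melting_temp(c.seq) <= cfg.tm_range[1]
            assert abs(dg_3prime(c.seq)) <= cfg.dg3_abs_max
            assert three_prime_dimer_stem(c.seq, c.seq) <= cfg.max_stem
            assert max_hairpin_stem(c.seq) <= cfg.max_stem
            assert c.false_priming <= cfg.max_false_priming
            # the 3'-terminal window really covers a diagnostic site
            assert any(p <= cfg.anchor_window for p in c.diagnostic_positions)

    def test_determinism(self):
        from psocid_id import find_diagnostic_sites
        lib, msa = _toy_design_msa()
        sites = find_diagnostic_sites(msa, lib, "spA")
        r1 = enumerate_candidates(msa, lib, sites, "spA", DesignConfig())
        r2 = enumerate_candidates(msa, lib, sites, "spA", DesignConfig())
        assert r1.candidates == r2.candidates
        assert r1.tally == r2.tally

    def test_selection_matches_bruteforce_cost_minimization(self):
        from psocid_id import find_diagnostic_sites
        lib, msa = _toy_design_msa()
        sites = find_diagnostic_sites(msa, lib, "spA")
        cands = enumerate_candidates(msa, lib, sites, "spA",
                                     DesignConfig()).candidates
        pair = select_optimal_pair(cands, product_range=(80, 300), species="spA")
        # exhaustive re-derivation
        best = None
        for f in [c for c in cands if c.strand == "forward"]:
            for r in [c for c in cands if c.strand == "reverse"]:
                pl = r.cons_five_prime - f.cons_five_prime + 1
                if pl < len(f.seq) + len(r.seq) or not 80 <= pl <= 300:
                    continue
                if three_prime_dimer_stem(f.seq, r.seq) > 3:
                    continue
                key = (abs(f.tm - r.tm), f.false_priming + r.false_priming,
                       pl, f.cons_five_prime)
                if best is None or key < best[0]:
                    best = (key, f, r)
        assert best is not None
        assert (pair.forward, pair.reverse) == (best[1], best[2])

    def test_no_feasible_pair_is_error(self):
        with pytest.raises(ValueError):
            select_optimal_pair([], product_range=(100, 300))


class TestPublishedPanel:
    def test_gc_within_printed_criterion(self):
        values = [gc_content(r.seq) for r in load_table1_fixture()]
        assert min(values) >= 30.0
        assert max(values) <= 70.0
        # direct count: 319LDeR has 7 G+C of 20; LBF and LM60F 12 of 21
        assert min(values) == pytest.approx(35.0, abs=0.1)
        assert max(values) == pytest.approx(57.1, abs=0.1)

    def test_target_fragments_within_default_product_range(self):
        cfg = DesignConfig()
        fragments = {f.target_fragment for f, _ in table1_pairs().values()}
        assert min(fragments) == 128 and max(fragments) == 251
        assert all(cfg.product_range[0] <= x <= cfg.product_range[1]
                   for x in fragments)
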