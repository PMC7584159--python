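import numpy as np
import pytest

from invbreak.inversion_sim import SimConfig, simulate_ancestor
from invbreak.nonb_scan import (cruciform_dG, find_aphased, find_g4,
                                find_inverted_repeats, find_mirror_repeats,
                                find_tandem_repeats, find_zdna,
                                stacking_table, window_density)
from invbreak.seq_model import revcomp

from _oracles import brute_force_repeats, tandem_run


def random_dna(rng, n, p=None):
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestInvertedRepeats:
    def test_perfect_14bp_palindrome(self):
        hits = find_inverted_repeats("ATGAACTAGTTCAT", max_mismatch=0)
        assert len(hits) == 1
        ir = hits[0]
        assert (ir.arm_len, ir.spacer_len, ir.mismatches) == (7, 0, 0)
        assert 2 * ir.arm_len + ir.spacer_len == 14

    def test_at_rich_hairpin(self):
        hits = find_inverted_repeats("AATTTTAAAATT", max_mismatch=0)
        assert any(h.arm_len == 6 and h.spacer_len == 0 for h in hits)

    def test_small_arm_rejected(self):
        with pytest.raises(ValueError):
            find_inverted_repeats("ACGT" * 10, arm_range=(3, 20))

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        # AT-rich composition makes repeats plentiful
        seq = random_dna(rng, 200, p=[0.35, 0.15, 0.15, 0.35])
        got = {(h.interval.start, h.interval.end, h.arm_len, h.spacer_len,
                h.mismatches)
               for h in find_inverted_repeats(seq, (6, 20), 10, 1)}
        assert got == brute_force_repeats(seq, (6, 20), 10, 1)

    def test_strand_symmetry(self, rng):
        seq = random_dna(rng, 300, p=[0.3, 0.2, 0.2, 0.3])
        fw = find_inverted_repeats(seq)
        rv = find_inverted_repeats(revcomp(seq))
        n = len(seq)
        mirrored = {(n - h.interval.end, n - h.interval.start, h.arm_len,
                     h.spacer_len) for h in rv}
        assert {(h.interval.start, h.interval.end, h.arm_len, h.spacer_len)
                for h in fw} == mirrored


class TestMirrorRepeats:
    def test_planted_11nt_mirror_with_30nt_spacer(self, rng):
        arm = "ACCTGATCGGA"
        seq = random_dna(rng, 60) + arm + random_dna(rng, 30) + arm[::-1] \
            + random_dna(rng, 60)
        hits = find_mirror_repeats(seq, arm_range=(6, 20), max_spacer=50,
                                   max_mismatch=0)
        assert any(h.arm_len >= 11 and h.spacer_len == 30 for h in hits)

    def test_short_symmetric_run_below_arm_min(self):
        assert find_mirror_repeats("AAAA") == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_dna(rng, 150, p=[0.35, 0.15, 0.15, 0.35])
        got = {(h.interval.start, h.interval.end, h.arm_len, h.spacer_len,
                h.mismatches)
               for h in find_mirror_repeats(seq, (6, 12), 12, 1)}
        assert got == brute_force_repeats(seq, (6, 12), 12, 1, mirror=True)


class TestTandemRepeats:
    def test_heptamer_with_fractional_copies(self, rng):
        flanks = ("GCGTACGATCGA", "CGATCGTACGGC")
        seq = flanks[0] + "AATAAAT" * 8 + "AATAA" + flanks[1]
        hits = [h for h in find_tandem_repeats(seq) if h.period == 7]
        assert len(hits) == 1
        h = hits[0]
        assert h.consensus == "AATAAAT"
        assert h.copy_number == pytest.approx(8.71, abs=0.25)

    def test_dinucleotide_repeat(self):
        hits = find_tandem_repeats("ATATATATATATATATATAT")
        assert len(hits) == 1
        assert hits[0].period == 2
        assert hits[0].copy_number == 10

    @pytest.mark.parametrize("period", range(3, 11))
    def test_perfect_repeats_exact_copy_number(self, period):
        rng = np.random.default_rng(period)
        unit = random_dna(rng, period)
        if len(set(unit)) == 1:
            unit = "A" + unit[1:-1] + "C"
        copies = 6
        left = random_dna(rng, 30)
        right = random_dna(rng, 30)
        seq = left + unit * copies + right
        hits = [h for h in find_tandem_repeats(seq)
                if h.interval.start < 30 + period * copies
                and h.interval.end > 30]
        assert hits
        h = max(hits, key=lambda x: len(x.interval))
        # oracle: direct scan of the maximal run containing the plant
        lo, hi = tandem_run(seq, 30, h.period)
        assert (h.interval.start, h.interval.end) == (lo, hi)
        assert h.copy_number == pytest.approx((hi - lo) / h.period)


class TestOtherMotifs:
    def test_zdna_tract(self):
        hits = find_zdna("GCGCGCGCGCGC")
        assert len(hits) == 1
        assert len(hits[0].interval) == 12

    def test_zdna_weights_gc_steps(self):
        gc = find_zdna("GCGCGCGCGCGC")[0]
        at = find_zdna("ATATATATATAT")[0]
        assert gc.score > at.score

    def test_g4_telomeric(self):
        hits = find_g4("GGGTTAGGGTTAGGGTTAGGG")
        assert len(hits) == 1
        assert hits[0].interval.strand == "+"

    def test_g4_minus_strand(self):
        hits = find_g4(revcomp("GGGTTAGGGTTAGGGTTAGGG"))
        assert len(hits) == 1
        assert hits[0].interval.strand == "-"

    def test_aphased_tracts(self):
        seq = "AAAA" + "GCGTCG" + "AAAA" + "GCGTCG" + "AAAA" + "GC"
        hits = find_aphased(seq)
        assert len(hits) == 1
        assert hits[0].copy_number == 3

    def test_aphased_needs_phasing(self, rng):
        seq = "AAAA" + random_dna(rng, 30) + "AAAA" + random_dna(rng, 30) \
            + "AAAA"
        assert find_aphased(seq) == []


class TestCruciformScore:
    def test_longer_arm_scores_higher(self):
        # same base composition, arm 10 vs arm 6
        ir10 = find_inverted_repeats("ATGAACTGCATGCAGTTCAT",
                                     arm_range=(6, 20), max_mismatch=0)
        ir6 = find_inverted_repeats("ATGAACGTTCAT",
                                    arm_range=(6, 20), max_mismatch=0)
        s10 = cruciform_dG(max(ir10, key=lambda h: h.arm_len),
                           "ATGAACTGCATGCAGTTCAT")
        s6 = cruciform_dG(ir6[0], "ATGAACGTTCAT")
        assert s10 >= s6

    def test_non_ir_rejected(self):
        tr = find_tandem_repeats("ATATATATATAT")[0]
        with pytest.raises(ValueError):
            cruciform_dG(tr, "ATATATATATAT")

    def test_hand_summed_stacking_terms(self):
        # arm AATTTT: steps AA, AT, TT, TT, TT ->
        # -1.00 -0.88 -1.00 -1.00 -1.00 = -4.88; spacer 0 loop penalty
        # 2.0 + 1.0*ln(2); no mismatches
        import math
        hits = find_inverted_repeats("AATTTTAAAATT", max_mismatch=0)
        ir = next(h for h in hits if h.arm_len == 6 and h.spacer_len == 0)
        expected = 4.88 - (2.0 + math.log(2))
        assert cruciform_dG(ir, "AATTTTAAAATT") == pytest.approx(expected)

    def test_table_loaded_once(self):
        assert stacking_table() is stacking_table()


class TestWindowCensus:
    def test_ir_density_peaks_at_planted_cluster(self):
        """A breakpoint planted inside an AT-rich palindromic cluster shows
        the highest inverted-repeat density at the junction."""
        cfg = SimConfig(seed=50, at_rich_break=True)
        anc = simulate_ancestor(cfg)
        p = (cfg.genome_length - cfg.inversion_span) // 2
        lo, hi = p - 5000, p + 5000
        seq = anc.seq[lo:hi]
        hits = find_inverted_repeats(seq, max_mismatch=1)
        dens = window_density(hits, len(seq), window=300, step=150)
        best = max(dens, key=lambda row: row[2])
        center = (best[0] + best[1]) / 2
        assert abs(center - 5000) < 500
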