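import numpy as np
import pytest

from invbreak.regulome_scan import (PWM, compare_states, estimate_background,
                                    extract_upstream, read_gff3_genes,
                                    read_pwms, scan_pwm)
from invbreak.seq_model import Interval, LabeledSequence


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def one_hot_pwm(motif, pseudocount=0.01):
    m = np.zeros((4, len(motif)))
    for j, b in enumerate(motif):
        m["ACGT".index(b), j] = 100.0
    return PWM("onehot", m, pseudocount=pseudocount)


class TestScanPwm:
    def test_one_hot_hits_exact_match_only(self, rng):
        # under a flat background, a single mismatch against a one-hot PWM
        # already has tail p > 1e-3, so only the exact match is reported
        motif = "TGTTTAC"
        seq = random_dna(rng, 800) + motif + random_dna(rng, 800)
        hits = [h for h in scan_pwm(seq, one_hot_pwm(motif), 1e-3,
                                    background=np.full(4, 0.25))
                if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].interval.start == 800

    def test_uniform_pwm_no_hits(self, rng):
        # constant score under a flat background: p = 1 everywhere
        seq = random_dna(rng, 2000)
        pwm = PWM("uniform", np.full((4, 8), 25.0))
        assert scan_pwm(seq, pwm, 1e-3, background=np.full(4, 0.25)) == []

    def test_pwm_wider_than_sequence(self):
        assert scan_pwm("ACGTAC", one_hot_pwm("TGTTTACA"), 1e-3) == []

    def test_strand_symmetry(self, rng):
        from invbreak.seq_model import revcomp
        seq = random_dna(rng, 3000)
        pwm = PWM("r", np.array([[8, 1, 1, 9, 2, 1],
                                 [1, 9, 2, 1, 1, 8],
                                 [1, 1, 8, 1, 8, 1],
                                 [2, 1, 1, 1, 1, 2]], dtype=float))
        bg = np.full(4, 0.25)
        fw = scan_pwm(seq, pwm, 1e-2, background=bg)
        rv = scan_pwm(revcomp(seq), pwm, 1e-2, background=bg)
        n = len(seq)
        assert {(n - h.interval.end, "-" if h.strand == "+" else "+")
                for h in rv} == \
            {(h.interval.start, h.strand) for h in fw}

    def test_hit_rate_calibration_3sigma(self, rng):
        # i.i.d. background: per-position hit rate ~ 2*alpha (two strands)
        seq = random_dna(rng, 20_000)
        pwm = PWM("r", np.array([[12, 2, 7, 1, 3, 9, 2, 5],
                                 [3, 11, 2, 8, 9, 1, 6, 4],
                                 [4, 5, 10, 2, 6, 8, 3, 7],
                                 [6, 7, 6, 14, 7, 7, 14, 9]], dtype=float))
        alpha = 1e-3
        hits = scan_pwm(seq, pwm, alpha, background=np.full(4, 0.25))
        n_pos = len(seq) - pwm.width + 1
        expected = 2 * alpha * n_pos
        sigma = np.sqrt(2 * alpha * (1 - 2 * alpha) * n_pos)
        assert abs(len(hits) - expected) <= 3 * sigma


class TestPwmIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "m.pwm"
        p.write_text(">tf1\nA 1 2 3 4\nC 4 3 2 1\nG 2 2 2 2\nT 3 3 3 3\n"
                     ">tf2\nA: 5 0 0 5\nC: 0 5 0 0\nG: 0 0 5 0\nT: 0 0 0 0\n")
        pwms = read_pwms(p)
        assert [m.name for m in pwms] == ["tf1", "tf2"]
        assert pwms[0].width == 4

    def test_missing_row_rejected(self, tmp_path):
        p = tmp_path / "bad.pwm"
        p.write_text(">tf\nA 1 2\nC 2 1\nG 1 1\n")
        with pytest.raises(ValueError, match="missing"):
            read_pwms(p)

    def test_unequal_columns_rejected(self):
        with pytest.raises(ValueError, match="sums"):
            PWM("x", np.array([[1, 2, 3, 9], [1, 1, 1, 1],
                               [1, 1, 1, 1], [1, 1, 1, 1]], dtype=float))

    def test_background_estimation(self):
        bg = estimate_background("AAAA")
        assert bg[0] == max(bg)
        assert bg.sum() == pytest.approx(1.0)


class TestExtractUpstream:
    GENOME = LabeledSequence("chr", "ACGT" * 2500)

    def test_plus_strand_window(self):
        genes = [("g1", Interval("chr", 5000, 6000, "+"))]
        (w,) = extract_upstream(genes, self.GENOME, length=1000)
        assert (w.interval.start, w.interval.end) == (4000, 5000)
        assert not w.truncated
        assert w.seq.seq == self.GENOME.seq[4000:5000]

    def test_minus_strand_window_revcomped(self):
        from invbreak.seq_model import revcomp
        genes = [("g1", Interval("chr", 4000, 5000, "-"))]
        (w,) = extract_upstream(genes, self.GENOME, length=1000)
        assert (w.interval.start, w.interval.end) == (5000, 6000)
        assert w.seq.seq == revcomp(self.GENOME.seq[5000:6000])

    def test_truncated_window_flagged(self):
        genes = [("g1", Interval("chr", 200, 400, "+"))]
        (w,) = extract_upstream(genes, self.GENOME, length=1000)
        assert w.truncated
        assert (w.interval.start, w.interval.end) == (0, 200)

    def test_off_sequence_gene_named(self):
        genes = [("gX", Interval("chr", 9990, 10500, "+"))]
        with pytest.raises(ValueError, match="gX"):
            extract_upstream(genes, self.GENOME)

    def test_gff3_reader(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n"
                     "chr\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
                     "chr\tsrc\texon\t101\t150\t.\t+\t.\tID=exonA\n"
                     "chr\tsrc\tgene\t301\t400\t.\t-\t.\tID=geneB\n")
        genes = read_gff3_genes(p)
        assert [(g, iv.start, iv.end, iv.strand) for g, iv in genes] == \
            [("geneA", 100, 200, "+"), ("geneB", 300, 400, "-")]


class TestCompareStates:
    def _hit(self, tf, start, end):
        from invbreak.regulome_scan import MotifHit
        return MotifHit(tf, Interval("s", start, end), "+", 10.0, 1e-4)

    def test_gained_flag_for_newly_attached_sites(self):
        hitsets = {
            ("attA2a", "inverted"): [self._hit("dfoxo", 100, 110)],
            ("attA2a", "uninverted"): [],
        }
        attached = {("attA2a", "inverted"): [Interval("s", 50, 300)]}
        table = compare_states(hitsets, ["dfoxo"], attached)
        assert table.loc["dfoxo", "attA2a/inverted"] == "present(gained)"
        assert table.loc["dfoxo", "attA2a/uninverted"] == "absent"

    def test_identical_states_identical_rows(self):
        hits = [self._hit("rel", 10, 20)]
        table = compare_states({("g", "a"): hits, ("g", "b"): list(hits)},
                               ["rel"])
        assert table.loc["rel", "g/a"] == table.loc["rel", "g/b"]

    def test_tf_without_hits_retained(self):
        table = compare_states({("g", "a"): []}, ["rel", "srp"])
        assert list(table.index) == ["rel", "srp"]
        assert (table["g/a"] == "absent").all()
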