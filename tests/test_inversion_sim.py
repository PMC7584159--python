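from collections import Counter

import pytest

from invbreak.inversion_sim import (SimConfig, emit_dataset, o7_config,
                                    parse_truth, simulate, simulate_ancestor,
                                    truth_report)


class TestAncestor:
    def test_deterministic(self):
        cfg = SimConfig(seed=1)
        a = simulate_ancestor(cfg)
        b = simulate_ancestor(cfg)
        assert a.seq == b.seq

    def test_gc_content(self):
        cfg = SimConfig(seed=2, genome_length=100_000, inversion_span=30_000)
        a = simulate_ancestor(cfg)
        gc = (a.seq.count("G") + a.seq.count("C")) / len(a.seq)
        assert abs(gc - 0.438) < 0.01

    def test_zero_gc_is_all_at(self):
        cfg = SimConfig(seed=3, gc_content=0.0)
        a = simulate_ancestor(cfg)
        assert set(a.seq) <= {"A", "T"}

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_ancestor(SimConfig(genome_length=12_000,
                                        inversion_span=10_000))


class TestMechanismFootprints:
    def test_cut_and_paste_conserves_sequence(self):
        from invbreak.seq_model import revcomp
        cfg = SimConfig(mechanism="CUT_AND_PASTE", seed=4,
                        line_divergence=0.0, outgroup_divergence=0.0)
        inv, (l1, _), _, truth = simulate(cfg)
        assert len(inv.seq) == len(l1.seq)
        # double-stranded content is conserved: reversal complements the
        # segment, so A/T and C/G pools are unchanged
        ci, cl = Counter(inv.seq), Counter(l1.seq)
        assert ci["A"] + ci["T"] == cl["A"] + cl["T"]
        assert ci["C"] + ci["G"] == cl["C"] + cl["G"]
        p, q = truth.prox_break_uninv, truth.dist_break_uninv
        assert inv.seq[p:q] == revcomp(l1.seq[p:q])
        assert truth.duplications == []

    def test_staggered_gains_fill_in_length(self):
        cfg = SimConfig(mechanism="STAGGERED_ISO", seed=5,
                        line_divergence=0.0)
        inv, (l1, _), _, truth = simulate(cfg)
        assert len(inv.seq) == len(l1.seq) + cfg.d1_len + cfg.d2_len

    def test_staggered_duplications_are_exact_revcomps(self):
        from invbreak.seq_model import revcomp
        cfg = SimConfig(mechanism="STAGGERED_ISO", seed=6,
                        line_divergence=0.0)
        inv, _, _, truth = simulate(cfg)
        p = truth.prox_break_uninv
        d1 = cfg.d1_len
        copy_direct = inv.seq[p:p + d1]
        copy_inverted = inv.seq[truth.dist_junction_inv - d1:
                                truth.dist_junction_inv]
        assert copy_inverted == revcomp(copy_direct)

    def test_chromosome_loses_dd7(self):
        cfg = SimConfig(mechanism="CHROMOSOME", seed=7, line_divergence=0.0)
        inv, (l1, _), _, truth = simulate(cfg)
        assert len(inv.seq) == len(l1.seq) - cfg.dd7_len
        assert truth.dd7 is not None
        assert truth.dd7[1] - truth.dd7[0] == cfg.dd7_len

    def test_chromosome_needs_two_haplotypes(self):
        with pytest.raises(ValueError, match="haplotypes"):
            SimConfig(mechanism="CHROMOSOME", spacer_haplotypes=("+", "+"))

    def test_inverted_matches_line_outside_rearrangement(self):
        cfg = SimConfig(mechanism="STAGGERED_ISO", seed=8,
                        line_divergence=0.0)
        inv, (l1, _), _, truth = simulate(cfg)
        p = truth.prox_break_uninv
        assert inv.seq[:p] == l1.seq[:p]
        tail = len(l1.seq) - truth.dist_break_uninv
        assert inv.seq[-tail:] == l1.seq[-tail:]


class TestComplexProximal:
    def test_microinversion_span_from_printed_lengths(self):
        _, _, _, truth = simulate(o7_config(seed=9))
        lo, hi = truth.microinversion
        assert hi - lo == 59 + 534 + 1374 + 59 == 2026

    def test_insertion_total_length(self):
        cfg = o7_config(seed=10)
        _, _, _, truth = simulate(cfg)
        lo, hi = truth.insertion
        assert hi - lo == 2317

    def test_filler_microhomology_truth(self):
        """The 21-nt filler against the +D start leaves an 8-bp match with
        one mismatch."""
        _, _, _, truth = simulate(o7_config(seed=11))
        assert len(truth.filler) == 21
        length, mismatches, _ = truth.microhomology
        assert (length, mismatches) == (8, 1)

    def test_generated_filler_microhomology(self):
        cfg = SimConfig(mechanism="BIR_MMBIR", seed=12)
        _, _, _, truth = simulate(cfg)
        assert truth.bir_flag
        length, mismatches, _ = truth.microhomology
        assert length >= cfg.microhomology_len - 1
        assert mismatches <= 1


class TestEmitDataset:
    def test_file_set_and_determinism(self, tmp_path):
        cfg = SimConfig(seed=13)
        paths = emit_dataset(tmp_path / "a", cfg)
        assert len(paths) == 6
        emit_dataset(tmp_path / "b", cfg)
        for name in ("inverted.fasta", "truth.txt", "config.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()

    def test_nonempty_outdir_needs_force(self, tmp_path):
        out = tmp_path / "d"
        emit_dataset(out, SimConfig(seed=14))
        with pytest.raises(FileExistsError):
            emit_dataset(out, SimConfig(seed=14))
        emit_dataset(out, SimConfig(seed=15), force=True)

    def test_different_seed_different_sequence(self, tmp_path):
        a = emit_dataset(tmp_path / "a", SimConfig(seed=16))
        b = emit_dataset(tmp_path / "b", SimConfig(seed=17))
        assert a[0].read_bytes() != b[0].read_bytes()

    def test_truth_round_trip(self):
        _, _, _, truth = simulate(o7_config(seed=18))
        back = parse_truth(truth_report(truth))
        assert back.expected_label == truth.expected_label
        assert back.microinversion == truth.microinversion
        assert back.dd7 == truth.dd7
        assert back.filler == truth.filler
        assert back.microhomology == truth.microhomology
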