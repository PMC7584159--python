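import numpy as np
import pytest

from invbreak.inversion_sim import SimConfig, simulate
from invbreak.junction_arch import (DuplicationPair, call_duplications,
                                    call_microinversion,
                                    find_filler_microhomology,
                                    is_low_complexity, phase_spacer_mosaic)
from invbreak.pipeline import InferenceParams, _line_segment_map
from invbreak.seq_model import Interval, revcomp


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng, s, rate):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


class TestCallDuplications:
    def test_staggered_fill_in_pair(self):
        inv, lines, _, _ = simulate(SimConfig(mechanism="STAGGERED_ISO",
                                              seed=41))
        _, smap = _line_segment_map(inv, lines[0], InferenceParams())
        dups = call_duplications(smap, inv.seq,
                                 {l.id: l.seq for l in lines})
        by_name = {d.name: d for d in dups}
        prox = by_name["prox_overlap_dup"]
        dist = by_name["dist_overlap_dup"]
        assert prox.orientation == "inverted"
        assert prox.present_in == "inverted_only"
        assert abs(len(prox.copy_a) - 59) <= 3
        assert dist.present_in == "inverted_only"
        assert abs(len(dist.copy_a) - 534) <= 3

    def test_nahr_pair_present_in_both_states(self):
        inv, lines, _, _ = simulate(SimConfig(mechanism="NAHR", seed=42))
        _, smap = _line_segment_map(inv, lines[0], InferenceParams())
        dups = call_duplications(smap, inv.seq,
                                 {l.id: l.seq for l in lines})
        assert {d.present_in for d in dups} == {"both_states"}
        assert all(abs(len(d.copy_a) - 300) <= 3 for d in dups)

    def test_cut_and_paste_no_duplications(self):
        inv, lines, _, _ = simulate(SimConfig(mechanism="CUT_AND_PASTE",
                                              seed=43))
        _, smap = _line_segment_map(inv, lines[0], InferenceParams())
        assert call_duplications(smap, inv.seq,
                                 {l.id: l.seq for l in lines}) == []

    def test_low_complexity_guard(self):
        assert is_low_complexity("ATTT" * 10)
        assert is_low_complexity("AATAAAT" * 9)
        rng = np.random.default_rng(0)
        assert not is_low_complexity(random_dna(rng, 60))
        assert not is_low_complexity(random_dna(rng, 300))


class TestCallMicroinversion:
    @staticmethod
    def _pair(name, a, b, orientation="inverted"):
        return DuplicationPair(
            name, Interval("inv", *a),
            None if b is None else Interval("inv", *b),
            orientation, 0.98, "inverted_only")

    def test_printed_component_lengths_give_2026(self):
        # d1 copies (59 bp) bracketing d2A (534 bp) + 1,374-bp intervening
        d1 = self._pair("d1", (0, 59), (59 + 534 + 1374, 59 + 534 + 1374 + 59))
        d2 = self._pair("d2", (59, 59 + 534), None, "direct")
        interval, conflict = call_microinversion([d1, d2])
        assert not conflict
        assert len(interval) == 2026

    def test_no_layout_returns_none(self):
        d2 = self._pair("d2", (100, 634), None, "direct")
        interval, conflict = call_microinversion([d2])
        assert interval is None and not conflict

    def test_pair_without_inner_copy_returns_none(self):
        d1 = self._pair("d1", (0, 59), (2000, 2059))
        interval, _ = call_microinversion([d1])
        assert interval is None

    def test_conflicting_layouts_flagged(self):
        a = self._pair("a", (0, 59), (2000, 2059))
        b = self._pair("b", (10, 69), (3000, 3059))
        inner = self._pair("i", (100, 700), None, "direct")
        interval, conflict = call_microinversion([a, b, inner])
        assert interval is None and conflict


class TestPhaseSpacerMosaic:
    def _spacers(self, seed=0, spacer_len=400, dd7=150, div=0.02):
        rng = np.random.default_rng(seed)
        S = random_dna(rng, spacer_len)
        line1 = mutate(rng, revcomp(S), div)   # reversed-spacer haplotype
        line2 = mutate(rng, S, div)
        m0 = spacer_len // 2
        inv_spacer = line1[:m0] + line2[m0 + dd7:]
        return inv_spacer, m0, line1, line2

    def test_chromosome_layout_called_mosaic(self):
        inv_spacer, m0, line1, line2 = self._spacers()
        call = phase_spacer_mosaic(inv_spacer, m0,
                                   {"line1": line1, "line2": line2})
        assert call.mosaic
        assert call.upstream_line == "line1"
        assert call.downstream_line == "line2"
        assert abs(call.central_deletion_len - 150) <= 3

    def test_single_haplotype_skipped(self):
        inv_spacer, m0, line1, _ = self._spacers()
        call = phase_spacer_mosaic(inv_spacer, m0, {"line1": line1})
        assert not call.mosaic
        assert "insufficient" in call.note

    def test_same_haplotypes_no_mosaic(self, rng):
        S = random_dna(rng, 400)
        inv_spacer = mutate(rng, S, 0.02)
        call = phase_spacer_mosaic(inv_spacer, 200,
                                   {"a": mutate(rng, S, 0.02),
                                    "b": mutate(rng, S, 0.02)})
        assert not call.mosaic


class TestArchitectureRecovery:
    """Whole-chain recovery of planted architecture features.

    Boundary estimates carry an intrinsic +/- 1-2 bp ambiguity: a
    junction-adjacent base that happens to match the other flank cannot
    be attributed by any method.  The tolerances here are the measured
    precision of the boundary estimator under the default divergence
    model (see the methods note)."""

    def test_staggered_duplication_lengths_and_orientation(self):
        from invbreak.inversion_sim import simulate as sim
        good = 0
        n = 15
        for seed in range(1, n + 1):
            inv, lines, _, _ = sim(SimConfig(mechanism="STAGGERED_ISO",
                                             seed=seed))
            _, smap = _line_segment_map(inv, lines[0], InferenceParams())
            dups = {d.name: d for d in call_duplications(
                smap, inv.seq, {l.id: l.seq for l in lines})}
            if "prox_overlap_dup" not in dups or \
                    "dist_overlap_dup" not in dups:
                continue
            assert dups["prox_overlap_dup"].orientation == "inverted"
            assert dups["dist_overlap_dup"].orientation == "inverted"
            # each end carries ~+/-2 bp of intrinsic boundary ambiguity
            if abs(len(dups["prox_overlap_dup"].copy_a) - 59) <= 5 and \
                    abs(len(dups["dist_overlap_dup"].copy_a) - 534) <= 5:
                good += 1
        assert good >= 0.9 * n

    def test_dd7_length_recovered_within_tolerance(self):
        from invbreak.inversion_sim import simulate as sim
        from invbreak.pipeline import evaluate, infer
        n = 25
        errors = []
        for seed in range(1, n + 1):
            inv, lines, og, truth = sim(SimConfig(mechanism="CHROMOSOME",
                                                  seed=seed))
            m = evaluate(infer(inv, lines, og), truth)
            if m.get("dd7_len_error") is not None:
                errors.append(abs(m["dd7_len_error"]))
        assert len(errors) >= 0.9 * n
        assert sum(e <= 5 for e in errors) >= 0.9 * len(errors)
        assert sum(e <= 2 for e in errors) >= 0.7 * len(errors)


class TestFillerMicrohomology:
    def test_printed_filler_against_printed_flank(self):
        rec = find_filler_microhomology("GAGCACTCTCCACAGCAAAGT",
                                        "CATCAAAG", max_mismatch=1)
        assert rec.length == 8
        assert rec.mismatches == 1
        assert rec.filler_len == 21
        # the matching substring is the filler's CAGCAAAG tail
        assert rec.filler[rec.gap_offset:rec.gap_offset + 8] == "CAGCAAAG"

    def test_empty_gap_returns_none(self):
        assert find_filler_microhomology("", "CATCAAAG") is None

    def test_planted_exact_match(self, rng):
        flank = random_dna(rng, 40)
        gap = random_dna(rng, 7) + flank[:10] + random_dna(rng, 4)
        rec = find_filler_microhomology(gap, flank, max_mismatch=1)
        assert rec.length >= 10
        assert rec.mismatches <= 1

    def test_short_flank_rejected(self):
        with pytest.raises(ValueError):
            find_filler_microhomology("ACGTACGT", "ACG")
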