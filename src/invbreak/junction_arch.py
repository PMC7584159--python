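"""Reconstruction of breakpoint-junction architecture.

From a demarcated :class:`~invbreak.junction_map.SegmentMap` this module
derives the evidence the mechanism classifier consumes: duplication pairs
(with orientation and arrangement-state distribution), microinversions
nested at a breakpoint, spacer-haplotype mosaicism with its central
deletion, and filler DNA with templated microhomology.

All identity values reported here exclude gap columns, matching the
convention of comparative breakpoint studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .junction_map import SegmentMap, align_pair
from .seq_model import Interval, revcomp


@dataclass
class DuplicationPair:
    """Two near-identical sequence copies created by the rearrangement."""

    name: str
    copy_a: Interval
    copy_b: Interval | None
    orientation: str          # direct | inverted
    identity: float
    present_in: str           # inverted_only | both_states | ambiguous
    low_complexity: bool = False


@dataclass
class MicrohomologyRecord:
    """Filler DNA at a junction with its best match to the +D flank."""

    filler_len: int
    length: int
    mismatches: int
    gap_offset: int
    filler: str


@dataclass
class MosaicCall:
    mosaic: bool
    upstream_line: str | None = None
    downstream_line: str | None = None
    upstream_identities: dict = field(default_factory=dict)
    downstream_identities: dict = field(default_factory=dict)
    central_deletion: tuple[int, int] | None = None   # on the downstream line
    note: str = ""

    @property
    def central_deletion_len(self) -> int:
        if self.central_deletion is None:
            return 0
        return self.central_deletion[1] - self.central_deletion[0]


@dataclass
class JunctionArchitecture:
    """Everything the junctions tell us about how the inversion formed."""

    insertions: list[Interval] = field(default_factory=list)
    duplications: list[DuplicationPair] = field(default_factory=list)
    microinversion: Interval | None = None
    microinversion_conflict: bool = False
    mosaic: MosaicCall | None = None
    filler: str | None = None
    microhomology: MicrohomologyRecord | None = None
    prox_overlap: int = 0
    dist_overlap: int = 0
    prox_unassigned: int = 0
    dist_unassigned: int = 0
    resolved: bool = True


def sequence_complexity(seq: str, k: int = 8) -> float:
    """Fraction of distinct k-mers among all k-mer windows (1.0 = all
    distinct).  Simple repeats like (ATTT)n score near zero."""
    if len(seq) < k:
        return 1.0
    kmers = {seq[i:i + k] for i in range(len(seq) - k + 1)}
    return len(kmers) / (len(seq) - k + 1)


def is_low_complexity(seq: str) -> bool:
    """Simple-repeat guard for duplication evidence: a copy whose k-mer
    vocabulary is mostly repeated is satellite-like, and its occurrence
    count in the uninverted state says nothing about NAHR.  The 4-mer test
    only applies to short copies — on long sequences the 4-mer space
    saturates and the fraction drops for honest sequence too."""
    if sequence_complexity(seq, 8) < 0.5:
        return True
    return len(seq) <= 60 and sequence_complexity(seq, 4) < 0.75


def _count_occurrences(query: str, target: str, max_dist_frac: float = 0.15) -> int:
    """Non-overlapping occurrences of ``query`` in ``target`` (both
    orientations) within an edit-distance budget."""
    k = max(2, int(max_dist_frac * len(query)))
    locs: set[tuple[int, int]] = set()
    for probe in (query, revcomp(query)):
        res = edlib.align(probe, target, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        locs.update((s, e) for s, e in res["locations"])
    # count non-overlapping loci across both orientations, so that a
    # near-palindromic copy (which matches itself on both strands at the
    # same place) is counted once
    count = 0
    last_end = -1
    for s, e in sorted(locs):
        if s > last_end:
            count += 1
            last_end = e
    return count


def _identity(a: str, b: str) -> float:
    """Identity of ``a`` against its best placement in ``b``, with the
    *query length* as denominator.  Unlike identity-excluding-indels on a
    free-end-gap alignment (which a short unrelated query can inflate by
    aligning only a lucky core), this coverage-weighted identity stays low
    for non-homologous sequence, which is what the haplotype-assignment
    decision needs."""
    if not a or not b:
        return 0.0
    track = align_pair(a, b, semiglobal=True)
    matches = sum(1 for x, y in zip(track.x_aligned, track.y_aligned)
                  if x == y and x in "ACGT")
    return matches / len(a)


def call_duplications(segment_map: SegmentMap, inverted_seq: str,
                      uninv_seqs: dict[str, str],
                      second_pass: list[DuplicationPair] | None = None,
                      min_len: int = 20, min_identity: float = 0.85,
                      ) -> list[DuplicationPair]:
    """Duplication pairs at the junctions.

    The primary signal is segment-projection overlap: when segment A's
    end lies beyond segment B's start on the uninverted reference (and
    likewise C/D), the overlapping stretch is present twice in the
    inverted assembly — the fill-in footprint.  ``present_in`` is decided
    by counting occurrences of the copy in the uninverted assemblies: one
    occurrence means the duplication exists in the inverted state only,
    two (the second typically inverted) means both states carry it, as
    NAHR predicts.  Low-complexity copies are flagged and their state
    left ambiguous.  Second-pass homology links (duplications discovered
    inside unassigned sequence) are merged in.
    """
    ref = uninv_seqs[segment_map.ref_id]
    out: list[DuplicationPair] = []
    for name, lo, hi in (("prox_overlap_dup", segment_map.b_start,
                          segment_map.a_end),
                         ("dist_overlap_dup", segment_map.d_start,
                          segment_map.c_end)):
        if hi - lo < min_len:
            continue
        copy = ref[lo:hi]
        lowc = is_low_complexity(copy)
        n = _count_occurrences(copy, ref)
        if lowc or n > 3:
            present = "ambiguous"
        elif n >= 2:
            present = "both_states"
        else:
            present = "inverted_only"
        out.append(DuplicationPair(
            name=name,
            copy_a=Interval(segment_map.ref_id, lo, hi),
            copy_b=None,
            orientation="inverted",
            identity=1.0,
            present_in=present,
            low_complexity=lowc,
        ))
    for pair in second_pass or []:
        if pair.copy_a is None or len(pair.copy_a) < min_len:
            continue
        if pair.identity < min_identity:
            continue
        copy = inverted_seq[pair.copy_a.start:pair.copy_a.end]
        lowc = is_low_complexity(copy)
        n = max(_count_occurrences(copy, s) for s in uninv_seqs.values())
        present = "ambiguous" if (lowc or n > 3) else (
            "both_states" if n >= 2 else "inverted_only")
        out.append(DuplicationPair(
            name=pair.name, copy_a=pair.copy_a, copy_b=pair.copy_b,
            orientation=pair.orientation, identity=pair.identity,
            present_in=present, low_complexity=lowc,
        ))
    return out


def call_microinversion(duplications: list[DuplicationPair],
                        segment_map: SegmentMap | None = None,
                        max_span: int = 10_000,
                        ) -> tuple[Interval | None, bool]:
    """Microinversion nested at a breakpoint.

    The diagnostic layout is an inverted duplication pair (d1-like) whose
    copies bracket at least one further duplication copy (d2-like): the
    span from the first base of the upstream copy to the last base of the
    downstream copy is the microinversion, fill-in copies inclusive.
    Returns ``(interval, conflict)``; with conflicting layouts no span is
    auto-selected and ``conflict`` is set.
    """
    candidates: list[Interval] = []
    inv_pairs = [d for d in duplications
                 if d.orientation == "inverted" and d.copy_b is not None]
    for d in inv_pairs:
        a, b = sorted([d.copy_a, d.copy_b], key=lambda iv: iv.start)
        if a.seq_id != b.seq_id or b.end - a.start > max_span:
            continue
        inner = [o for o in duplications if o is not d
                 for iv in ([o.copy_a] if o.copy_b is None
                            else [o.copy_a, o.copy_b])
                 if iv is not None and iv.seq_id == a.seq_id
                 and a.end <= iv.start and iv.end <= b.start]
        if inner:
            candidates.append(Interval(a.seq_id, a.start, b.end))
    if not candidates:
        return None, False
    if len(candidates) > 1:
        spans = {(c.start, c.end) for c in candidates}
        if len(spans) > 1:
            return None, True
    return candidates[0], False


def find_filler_microhomology(junction_gap: str, flank_d: str,
                              max_mismatch: int = 1, min_len: int = 4,
                              ) -> MicrohomologyRecord | None:
    """Microhomology between junction filler and the +D flank.

    Finds the longest substring of the gap that aligns, gaplessly and
    with at most ``max_mismatch`` mismatches, to a window anchored at the
    start of ``flank_d``.  Returns ``None`` for an empty gap or when the
    best match is shorter than ``min_len``.
    """
    junction_gap = junction_gap.upper()
    flank_d = flank_d.upper()
    if not junction_gap:
        return None
    if len(flank_d) < min_len:
        raise ValueError("flank_d shorter than the minimum match length")
    best: tuple[int, int, int] | None = None
    for length in range(min(len(junction_gap), len(flank_d)), min_len - 1, -1):
        window = flank_d[:length]
        for i in range(len(junction_gap) - length + 1):
            sub = junction_gap[i:i + length]
            mism = sum(1 for a, b in zip(sub, window)
                       if a != b or a not in "ACGT")
            if mism <= max_mismatch:
                cand = (length, mism, i)
                if best is None or (-cand[0], cand[1], cand[2]) < \
                        (-best[0], best[1], best[2]):
                    best = cand
        if best is not None:
            break
    if best is None:
        return None
    return MicrohomologyRecord(
        filler_len=len(junction_gap),
        length=best[0], mismatches=best[1], gap_offset=best[2],
        filler=junction_gap,
    )


def phase_spacer_mosaic(inv_spacer: str, junction_offset: int,
                        uninv_spacers: dict[str, str],
                        identity_gap: float = 0.20,
                        slack: int = 40) -> MosaicCall:
    """Assign the two halves of an inverted-state spacer to uninverted
    haplotypes and measure the central deletion.

    Each half is compared against the positionally corresponding window
    (head for the upstream half, tail for the downstream half) of every
    uninverted spacer; identity excludes indels.  A mosaic is called when
    the halves assign to *different* lines with an identity gap of at
    least ``identity_gap`` (20 points by default) on at least one half.
    The unmatched central residue of the downstream line — bounded by the
    upstream half's end, mapped through the reverse-complement homology
    between the two haplotypes — is reported as the central deletion.
    With fewer than two haplotypes the test is skipped.
    """
    if len(uninv_spacers) < 2:
        return MosaicCall(False, note="insufficient haplotypes")
    up = inv_spacer[:junction_offset]
    down = inv_spacer[junction_offset:]
    if not up or not down:
        return MosaicCall(False, note="degenerate split")
    up_ids = {}
    down_ids = {}
    for line, sp in uninv_spacers.items():
        head = sp[:len(up) + slack]
        tail = sp[max(0, len(sp) - len(down) - slack):]
        up_ids[line] = _identity(up, head)
        down_ids[line] = _identity(down, tail)
    up_best = max(up_ids, key=up_ids.get)
    down_best = max(down_ids, key=down_ids.get)
    call = MosaicCall(False, upstream_line=up_best, downstream_line=down_best,
                      upstream_identities=up_ids, downstream_identities=down_ids)
    if up_best == down_best:
        return call
    gap_up = up_ids[up_best] - max(v for k, v in up_ids.items() if k != up_best)
    gap_down = down_ids[down_best] - max(v for k, v in down_ids.items()
                                         if k != down_best)
    if max(gap_up, gap_down) < identity_gap:
        return call
    call.mosaic = True
    s1 = uninv_spacers[up_best]
    s2 = uninv_spacers[down_best]
    # place the halves on their own haplotypes
    r1 = edlib.align(up, s1, mode="HW", task="locations")
    r2 = edlib.align(down, s2, mode="HW", task="locations")
    if r1["editDistance"] < 0 or r2["editDistance"] < 0:
        return call
    e1 = r1["locations"][0][1] + 1          # exclusive end of up within s1
    s2_start = r2["locations"][0][0]        # inclusive start of down within s2
    # map e1 onto s2 through the reverse-complement homology of s1 to s2
    nw = edlib.align(revcomp(s1), s2, mode="NW", task="path")
    if nw["editDistance"] < 0:
        return call
    pos_r = len(s1) - e1                    # e1 as a position in revcomp(s1)
    mapped = _map_through_cigar(nw["cigar"], pos_r)
    if mapped is not None and s2_start > mapped:
        call.central_deletion = (mapped, s2_start)
    return call


def _map_through_cigar(cigar: str, qpos: int) -> int | None:
    """Map a query position through an edlib NW cigar to target space."""
    import re
    q = t = 0
    for m in re.finditer(r"(\d+)([=XIDM])", cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "=XM":
            if q + n > qpos:
                return t + (qpos - q)
            q += n
            t += n
        elif op == "I":        # present in query only
            if q + n > qpos:
                return t
            q += n
        elif op == "D":        # present in target only
            t += n
    return t if qpos >= q else None
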