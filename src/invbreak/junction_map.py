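"""Base-pair fine-mapping of breakpoint junctions and segment demarcation.

The inverted-state junction region is compared against the two uninverted
flanks that should meet there (+A and -C at the proximal junction, -B and
+D at the distal one).  Homology support for each flank is located by
chaining exact k-mer anchors and extending the terminal anchor base by
base toward the junction, tolerating isolated substitutions.  The point
where support transfers from one flank to the other is the junction; a
gap supported by neither flank is cataloged as unassigned (candidate
insertion or filler), and overlapping support marks duplicated sequence.

A transition zone wider than ``point_tolerance`` is reported as an
interval, not a point: staggered or filled junctions have no single true
breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .seq_model import Interval, revcomp
from .synteny_scan import chain_blocks, find_anchors

MAX_ALIGN_LEN = 200_000


@dataclass
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -0.5


@dataclass
class AlignmentTrack:
    """A pairwise alignment as gapped strings plus summary accessors."""

    x_aligned: str
    y_aligned: str
    score: float

    def __len__(self) -> int:
        return len(self.x_aligned)

    def identity_excluding_indels(self) -> float | None:
        matches = total = 0
        for a, b in zip(self.x_aligned, self.y_aligned):
            if a == "-" or b == "-":
                continue
            total += 1
            if a == b and a in "ACGT":
                matches += 1
        return matches / total if total else None

    def window_identity(self, window: int = 11) -> np.ndarray:
        states = np.array([
            1.0 if a == b and a in "ACGT" else 0.0
            for a, b in zip(self.x_aligned, self.y_aligned)
        ])
        if len(states) < window:
            return np.array([states.mean()]) if len(states) else np.array([])
        kernel = np.ones(window) / window
        return np.clip(np.convolve(states, kernel, mode="valid"), 0.0, 1.0)


def _aligner(scoring: Scoring, semiglobal: bool = False) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    if semiglobal:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    return al


def align_pair(x: str, y: str, scoring: Scoring | None = None,
               semiglobal: bool = False) -> AlignmentTrack:
    """Global affine-gap alignment of two sequences.

    Gap convention: a gap of length L costs ``gap_open + (L-1) *
    gap_extend``.  With ``semiglobal`` set, end gaps on either sequence
    are free (overlap alignment), which is what segment demarcation needs
    when only part of the sequences is homologous.  Deterministic for
    fixed scoring.  Sequences over 200 kb are rejected: narrow the
    candidate region instead.
    """
    if len(x) > MAX_ALIGN_LEN or len(y) > MAX_ALIGN_LEN:
        raise ValueError("sequence over 200 kb: narrow the candidate region")
    scoring = scoring or Scoring()
    al = _aligner(scoring, semiglobal)
    x, y = x.upper(), y.upper()
    result = al.align(x, y)
    best = result[0]
    return AlignmentTrack(str(best[0]), str(best[1]), float(best.score))


def alignment_fasta(track: AlignmentTrack, x_id: str = "x", y_id: str = "y") -> str:
    """Aligned-FASTA export of a pairwise alignment."""
    return f">{x_id}\n{track.x_aligned}\n>{y_id}\n{track.y_aligned}\n"


# ---------------------------------------------------------------------------
# anchor-and-extend flank support


@dataclass
class FlankSupport:
    """Where one uninverted flank's homology ends within the junction
    window, plus the matching coordinate on the uninverted sequence."""

    found: bool
    vj_boundary: int = 0      # exclusive end (left flank) / inclusive start (right)
    u_boundary: int = 0       # matching boundary in uninverted coordinates
    n_anchors: int = 0
    diag: int = 0


@dataclass
class JunctionCall:
    """Demarcation of one junction of the inverted assembly."""

    left: FlankSupport
    right: FlankSupport
    junction_vj: int = 0
    width: int = 0            # |gap| between supports; >point_tolerance -> zone
    unassigned_vj: tuple[int, int] | None = None   # gap matching neither flank
    overlap_vj: tuple[int, int] | None = None      # support overlap (duplication)
    resolved: bool = True


def _match(a: str, b: str) -> bool:
    return a == b and a in "ACGT"


def _refine_boundary(match, j0: int, lo: int, hi: int, right: bool,
                     window: int = 12, span: int = 6) -> int:
    """Maximum-parsimony refinement of a support boundary.

    Candidate boundaries around the extension's stop point are scored by
    the number of mismatches they leave on the homology side plus the
    number of matches they leave on the junk side (each a rare event on
    the correct side: divergence ~1%/site vs chance identity ~25%/site).
    Ties break toward the conservative (shorter-support) side, so a
    trailing chance match does not drag the boundary outward.
    """
    best_j = j0
    best_cost = None
    candidates = range(max(lo, j0 - span), min(hi, j0 + span) + 1)
    for j in (candidates if right else reversed(candidates)):
        if right:
            homol = range(max(lo, j - window), j)
            junk = range(j, min(hi, j + window))
        else:
            homol = range(j, min(hi, j + window))
            junk = range(max(lo, j - window), j)
        cost = sum(0 if match(i) else 1 for i in homol) \
            + sum(1 if match(i) else 0 for i in junk)
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_j = j
    return best_j


def _extend_right(vj: str, flank: str, start: int, diag: int,
                  lookahead: int = 6, min_look_match: int = 4) -> int:
    """Extend matching rightward from ``start``; returns the exclusive end
    of support.  Isolated substitutions are stepped over as long as the
    lookahead window stays mostly matching; the stop point is then
    refined by maximum parsimony."""
    i = start
    last_good = start
    n_v, n_f = len(vj), len(flank)

    def match(i: int) -> bool:
        return 0 <= i < n_v and 0 <= i + diag < n_f \
            and _match(vj[i], flank[i + diag])

    while i < n_v and 0 <= i + diag < n_f:
        if match(i):
            last_good = i + 1
            i += 1
            continue
        look = [match(j) for j in range(i + 1, min(i + 1 + lookahead, n_v))]
        if sum(look) >= min_look_match:
            i += 1
            continue
        break
    hi = min(n_v, n_f - diag)
    return _refine_boundary(match, last_good, start, hi, right=True)


def _extend_left(vj: str, flank: str, start: int, diag: int,
                 lookahead: int = 6, min_look_match: int = 4) -> int:
    """Extend matching leftward; returns the inclusive start of support."""
    i = start
    last_good = start
    n_v, n_f = len(vj), len(flank)

    def match(i: int) -> bool:
        return 0 <= i < n_v and 0 <= i + diag < n_f \
            and _match(vj[i], flank[i + diag])

    while i >= 0 and 0 <= i + diag < n_f:
        if match(i):
            last_good = i
            i -= 1
            continue
        look = [match(j) for j in range(i - 1, max(i - 1 - lookahead, -1), -1)]
        if sum(look) >= min_look_match:
            i -= 1
            continue
        break
    lo = max(0, -diag)
    return _refine_boundary(match, last_good, lo, start + 1, right=False)


def _flank_support(vj: str, flank: str, side: str, k: int = 13,
                   max_gap: int = 600, expected_diag: int | None = None,
                   diag_tol: int = 100) -> tuple[FlankSupport, int]:
    """Locate the colinear anchor run between the junction window and one
    oriented flank, then extend its junction-facing end base by base.

    ``side``: "left" flanks support the upstream part of the window (the
    boundary of interest is their rightmost extent); "right" flanks
    support the downstream part (boundary = leftmost extent).  When
    ``expected_diag`` (from the synteny candidate) is given, anchors are
    restricted to that diagonal band first, which keeps duplication
    shards and dispersed repeats from hijacking the support; the
    unrestricted chain is the fallback.  Returns the support with
    ``vj_boundary`` in window coordinates and the raw flank coordinate of
    the boundary (mapping to uninverted coordinates is the caller's job,
    since it knows the flank's orientation).
    """
    if len(vj) < k or len(flank) < k:
        return FlankSupport(found=False), 0
    anchors = [a for a in find_anchors(vj, flank, k=k) if a.orientation == "+"]
    if not anchors:
        return FlankSupport(found=False), 0
    band = []
    if expected_diag is not None:
        band = [a for a in anchors
                if abs((a.t_pos - a.q_pos) - expected_diag) <= diag_tol]
    if band:
        # stray chance anchors can fall inside the band; keep only the
        # modal diagonal (substitution divergence never moves a diagonal)
        counts: dict[int, int] = {}
        for a in band:
            counts[a.t_pos - a.q_pos] = counts.get(a.t_pos - a.q_pos, 0) + 1
        modal = max(counts, key=lambda d: (counts[d], -abs(d - expected_diag)))
        chain_anchors = [a for a in band if a.t_pos - a.q_pos == modal]
        n_anchors = len(chain_anchors)
    else:
        blocks = chain_blocks(anchors, max_gap=max_gap, min_anchors=2,
                              q_id="vj", t_id="flank")
        blocks = [b for b in blocks if b.orientation == "+"]
        if not blocks:
            return FlankSupport(found=False), 0
        top = max(b.score for b in blocks)
        majors = [b for b in blocks if b.score >= 0.1 * top]
        if side == "left":
            blk = max(majors, key=lambda b: (b.q_interval.end, b.score))
        else:
            blk = min(majors, key=lambda b: (b.q_interval.start, -b.score))
        chain_anchors = [a for a in anchors
                         if blk.q_interval.start <= a.q_pos < blk.q_interval.end]
        n_anchors = blk.n_anchors
    if side == "left":
        a0 = max(chain_anchors, key=lambda a: a.q_pos)
        diag = a0.t_pos - a0.q_pos
        end = _extend_right(vj, flank, a0.q_pos + a0.k, diag)
        return (FlankSupport(True, vj_boundary=end, n_anchors=n_anchors,
                             diag=diag), end + diag)
    a0 = min(chain_anchors, key=lambda a: a.q_pos)
    diag = a0.t_pos - a0.q_pos
    start = _extend_left(vj, flank, a0.q_pos, diag)
    return (FlankSupport(True, vj_boundary=start, n_anchors=n_anchors,
                         diag=diag), start + diag)


def demarcate_junction(vj: str, left_flank: str, right_flank: str,
                       left_u: tuple[int, int] | None = None,
                       right_u: tuple[int, int] | None = None,
                       left_reversed: bool = False,
                       right_reversed: bool = False,
                       point_tolerance: int = 10,
                       k: int = 13,
                       expected_diag_left: int | None = None,
                       expected_diag_right: int | None = None) -> JunctionCall:
    """Demarcate one junction of the inverted assembly.

    ``left_flank`` and ``right_flank`` must already be oriented so that
    homologous sequence runs colinearly (+) with the window; ``left_u`` /
    ``right_u`` give the uninverted-coordinate interval each flank was cut
    from, with ``*_reversed`` recording whether it was reverse
    complemented.  Boundaries are mapped back to uninverted coordinates:
    for the left flank the boundary is an exclusive end, for the right an
    inclusive start (in window orientation).
    """
    left, left_f = _flank_support(vj, left_flank, "left", k=k,
                                  expected_diag=expected_diag_left)
    right, right_f = _flank_support(vj, right_flank, "right", k=k,
                                    expected_diag=expected_diag_right)
    if left.found and left_u is not None:
        lo, hi = left_u
        left.u_boundary = (hi - left_f) if left_reversed else (lo + left_f)
    if right.found and right_u is not None:
        lo, hi = right_u
        right.u_boundary = (hi - right_f) if right_reversed else (lo + right_f)
    call = JunctionCall(left=left, right=right)
    if not (left.found and right.found):
        call.resolved = False
        return call
    gap = right.vj_boundary - left.vj_boundary
    if abs(gap) <= 12:
        # near-blunt junction: both flanks carry signal on their side, so
        # a joint parsimony fit over the two of them locates the switch
        # point more precisely than either one-sided extension
        def match_l(i: int) -> bool:
            j = i + left.diag
            return 0 <= i < len(vj) and 0 <= j < len(left_flank) \
                and _match(vj[i], left_flank[j])

        def match_r(i: int) -> bool:
            j = i + right.diag
            return 0 <= i < len(vj) and 0 <= j < len(right_flank) \
                and _match(vj[i], right_flank[j])

        mid = (left.vj_boundary + right.vj_boundary) // 2
        window = 12
        best = None
        for j in range(max(0, mid - 14), min(len(vj), mid + 15)):
            cost = sum(0 if match_l(i) else 1
                       for i in range(max(0, j - window), j)) \
                + sum(0 if match_r(i) else 1
                      for i in range(j, min(len(vj), j + window)))
            key = (cost, abs(j - mid), j)
            if best is None or key < best[0]:
                best = (key, j)
        # accept only a clean fit: a short filler or unresolved zone makes
        # every candidate switch point leave junk in one window, and then
        # the one-sided boundaries (which expose the gap) are kept
        if best[0][0] <= 3:
            j_star = best[1]
            left.vj_boundary = j_star
            right.vj_boundary = j_star
            left_f = j_star + left.diag
            right_f = j_star + right.diag
            if left_u is not None:
                lo, hi = left_u
                left.u_boundary = (hi - left_f) if left_reversed \
                    else (lo + left_f)
            if right_u is not None:
                lo, hi = right_u
                right.u_boundary = (hi - right_f) if right_reversed \
                    else (lo + right_f)
            gap = 0
    call.width = abs(gap)
    call.junction_vj = (left.vj_boundary + right.vj_boundary) // 2
    if gap > 0:
        call.unassigned_vj = (left.vj_boundary, right.vj_boundary)
    elif gap < 0:
        call.overlap_vj = (right.vj_boundary, left.vj_boundary)
    return call


# ---------------------------------------------------------------------------
# segment map


@dataclass
class SegmentMap:
    """Segments A-D on the reference uninverted assembly plus the four
    junction calls.  ``a_end``/``b_start`` bound the proximal junction and
    ``c_end``/``d_start`` the distal one; overlap between A and B (or C
    and D) projections is duplicated sequence, a shortfall is deletion.
    Unassigned inverted-state intervals (insertions, fillers) are
    cataloged, never dropped.
    """

    ref_id: str
    a_end: int
    b_start: int
    c_end: int
    d_start: int
    prox_call: JunctionCall
    dist_call: JunctionCall
    # junction positions on the inverted assembly (absolute coordinates)
    junction_inv_prox: int = 0
    junction_inv_dist: int = 0
    unassigned: list[Interval] = field(default_factory=list)
    segments: dict = field(default_factory=dict)
    prox_window: tuple[int, int] = (0, 0)   # inverted-assembly window used
    dist_window: tuple[int, int] = (0, 0)

    @property
    def junction_uninv_prox(self) -> int:
        return (self.a_end + self.b_start) // 2

    @property
    def junction_uninv_dist(self) -> int:
        return (self.c_end + self.d_start) // 2


@dataclass
class HomologyLink:
    """A second-pass homology between unassigned sequence and a segment or
    another unassigned interval (duplication-pair candidate)."""

    name: str
    copy_a: Interval              # on the inverted assembly
    copy_b: Interval | None       # partner (inverted assembly or reference)
    orientation: str              # direct | inverted
    identity: float


_PAIRBASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pair_extend(x: str, y: str, i0: int, i1: int, posmap,
                 complement: bool = False, lookahead: int = 6,
                 min_look_match: int = 4) -> tuple[int, int, float]:
    """Extend a paired region ``x[i] ~ y[posmap(i)]`` outward from the seed
    ``[i0, i1)``; returns (start, end, identity) of the extended region."""
    def ok(i: int) -> bool:
        j = posmap(i)
        return 0 <= i < len(x) and 0 <= j < len(y)

    def match(i: int) -> bool:
        j = posmap(i)
        if complement:
            return _PAIRBASE.get(x[i]) == y[j] and x[i] in "ACGT"
        return x[i] == y[j] and x[i] in "ACGT"

    lo = i0
    i = i0 - 1
    while ok(i):
        if match(i):
            lo = i
            i -= 1
            continue
        look = [match(j) for j in range(i - 1, i - 1 - lookahead, -1) if ok(j)]
        if sum(look) >= min_look_match:
            i -= 1
            continue
        break
    hi = i1
    i = i1
    while ok(i):
        if match(i):
            hi = i + 1
            i += 1
            continue
        look = [match(j) for j in range(i + 1, i + 1 + lookahead) if ok(j)]
        if sum(look) >= min_look_match:
            i += 1
            continue
        break
    n_match = sum(1 for i in range(lo, hi) if match(i))
    ident = n_match / (hi - lo) if hi > lo else 0.0
    return lo, hi, ident


def _cluster_links(x: str, y: str, k: int, self_mode: bool,
                   min_len: int, min_identity: float,
                   ) -> list[tuple[int, int, int, int, str, float]]:
    """Anchor-clustered homologies between x and y (y may be x itself).

    Returns tuples ``(x_lo, x_hi, y_lo, y_hi, orientation, identity)``.
    Anchors are grouped by (anti)diagonal — substitution divergence does
    not move a diagonal — and each group's seed is extended base by base.
    """
    if len(x) < k or len(y) < k:
        return []
    try:
        anchors = find_anchors(x, y, k=k)
    except ValueError:
        return []
    groups: dict[tuple[str, int], list] = {}
    for a in anchors:
        if self_mode:
            if a.orientation == "+" and a.t_pos == a.q_pos:
                continue  # trivial self-diagonal
            if a.t_pos < a.q_pos:
                continue  # keep one of each symmetric pair
        key_val = (a.t_pos - a.q_pos if a.orientation == "+"
                   else a.t_pos + a.q_pos)
        groups.setdefault((a.orientation, key_val), []).append(a)
    # merge near-identical diagonals
    merged: dict[tuple[str, int], list] = {}
    for (orient, d), items in sorted(groups.items()):
        placed = False
        for (o2, d2), tgt in merged.items():
            if o2 == orient and abs(d2 - d) <= 2:
                tgt.extend(items)
                placed = True
                break
        if not placed:
            merged[(orient, d)] = list(items)
    out = []
    for (orient, d), items in merged.items():
        q_lo = min(a.q_pos for a in items)
        q_hi = max(a.q_pos + a.k for a in items)
        if orient == "+":
            posmap = lambda i, d=d: i + d
        else:
            A = d + items[0].k - 1
            posmap = lambda i, A=A: A - i
        lo, hi, ident = _pair_extend(x, y, q_lo, q_hi, posmap,
                                     complement=(orient == "-"))
        if self_mode and orient == "-":
            # arms must not cross the fold point
            A = d + items[0].k - 1
            hi = min(hi, (A + 1) // 2 + 1)
            if hi <= lo:
                continue
        if hi - lo < min_len or ident < min_identity:
            continue
        if orient == "+":
            y_lo, y_hi = lo + d, hi + d
        else:
            A = d + items[0].k - 1
            y_lo, y_hi = A - hi + 1, A - lo + 1
        out.append((lo, hi, y_lo, y_hi, orient, ident))
    out.sort()
    return out


def second_pass_homology(inverted_seq: str, smap: SegmentMap, uninv_seq: str,
                         min_len: int = 20, min_identity: float = 0.85,
                         k: int = 11, window: int = 800) -> list[HomologyLink]:
    """Second round of comparative analysis on unassigned sequence.

    Each unassigned interval is compared, in both orientations, against
    itself (nested inverted-duplication pairs), against the other
    unassigned intervals, and against the reference segments flanking the
    four junction boundaries.  Matches of at least ``min_len`` at
    ``min_identity`` are returned as duplication-pair links with parent
    and orientation recorded.
    """
    links: list[HomologyLink] = []
    unas = smap.unassigned
    inv_id = unas[0].seq_id if unas else "inverted"

    def side_of(iv: Interval) -> str:
        mid = (iv.start + iv.end) // 2
        return ("prox" if abs(mid - smap.junction_inv_prox)
                <= abs(mid - smap.junction_inv_dist) else "dist")

    seg_windows = {
        "A": (max(0, smap.a_end - window), smap.a_end + 50),
        "B": (max(0, smap.b_start - 50), smap.b_start + window),
        "C": (max(0, smap.c_end - window), smap.c_end + 50),
        "D": (max(0, smap.d_start - 50), smap.d_start + window),
    }
    for ui, u in enumerate(unas):
        useq = inverted_seq[u.start:u.end]
        side = side_of(u)
        # self: nested inverted pairs (microinversion fill-in copies)
        for x_lo, x_hi, y_lo, y_hi, orient, ident in _cluster_links(
                useq, useq, k, True, min_len, min_identity):
            if orient != "-" or y_lo < x_hi:
                continue
            links.append(HomologyLink(
                name=f"{side}_sp_self_{ui}",
                copy_a=Interval(inv_id, u.start + x_lo, u.start + x_hi),
                copy_b=Interval(inv_id, u.start + y_lo, u.start + y_hi),
                orientation="inverted",
                identity=ident,
            ))
        # against other unassigned intervals
        for vi in range(ui + 1, len(unas)):
            v = unas[vi]
            vseq = inverted_seq[v.start:v.end]
            for x_lo, x_hi, y_lo, y_hi, orient, ident in _cluster_links(
                    useq, vseq, k, False, min_len, min_identity):
                links.append(HomologyLink(
                    name=f"{side}_sp_cross_{ui}_{vi}",
                    copy_a=Interval(inv_id, u.start + x_lo, u.start + x_hi),
                    copy_b=Interval(inv_id, v.start + y_lo, v.start + y_hi),
                    orientation="direct" if orient == "+" else "inverted",
                    identity=ident,
                ))
        # against the segments bounding the junctions
        for seg, (w_lo, w_hi) in seg_windows.items():
            wseq = uninv_seq[w_lo:w_hi]
            for x_lo, x_hi, y_lo, y_hi, orient, ident in _cluster_links(
                    useq, wseq, k, False, min_len, min_identity):
                links.append(HomologyLink(
                    name=f"{side}_sp_seg{seg}_{ui}",
                    copy_a=Interval(inv_id, u.start + x_lo, u.start + x_hi),
                    copy_b=Interval(smap.ref_id, w_lo + y_lo, w_lo + y_hi),
                    orientation="direct" if orient == "+" else "inverted",
                    identity=ident,
                ))
    return links


def demarcate_segments(inverted_seq: str, uninv_seq: str,
                       prox_q: Interval, prox_t: Interval,
                       dist_q: Interval, dist_t: Interval,
                       pad: int = 400, flank: int = 1600,
                       ref_id: str = "uninverted",
                       inv_id: str = "inverted") -> SegmentMap:
    """Demarcate segments A-D around an inversion candidate.

    ``prox_q``/``dist_q`` are the candidate breakpoint regions on the
    inverted assembly, ``prox_t``/``dist_t`` their counterparts on the
    uninverted reference (from the synteny scan).  Four flank comparisons
    locate where homology switches at each inverted-state junction:

    - proximal window: +A (direct) versus -C (reverse complement of the
      sequence upstream of the distal break);
    - distal window: -B (reverse complement of the sequence downstream of
      the proximal break) versus +D (direct).
    """
    n_inv, n_u = len(inverted_seq), len(uninv_seq)

    def clamp(lo: int, hi: int, n: int) -> tuple[int, int]:
        return max(0, lo), min(n, hi)

    # windows on the inverted assembly
    pq0, pq1 = clamp(prox_q.start - pad, prox_q.end + pad, n_inv)
    dq0, dq1 = clamp(dist_q.start - pad, dist_q.end + pad, n_inv)
    vj_prox = inverted_seq[pq0:pq1]
    vj_dist = inverted_seq[dq0:dq1]

    # uninverted flank windows around each breakpoint region
    pa0, pa1 = clamp(prox_t.start - flank, prox_t.end + flank, n_u)
    da0, da1 = clamp(dist_t.start - flank, dist_t.end + flank, n_u)
    seg_a = uninv_seq[pa0:pa1]                 # covers A | B
    seg_c = revcomp(uninv_seq[da0:da1])        # covers (C | D) reversed

    # expected diagonals from the synteny candidate: the flanking blocks'
    # edges already sit on the correct homology diagonals, so shards at
    # shifted diagonals (junction-local duplications) are kept out of the
    # flank support.
    ed_prox_left = (prox_t.start - pa0) - (prox_q.start - pq0)
    ed_prox_right = (da1 - dist_t.start) - (prox_q.end - pq0)
    ed_dist_left = (pa1 - prox_t.end) - (dist_q.start - dq0)
    ed_dist_right = (dist_t.end - da0) - (dist_q.end - dq0)

    prox = demarcate_junction(vj_prox, seg_a, seg_c,
                              left_u=(pa0, pa1), right_u=(da0, da1),
                              right_reversed=True,
                              expected_diag_left=ed_prox_left,
                              expected_diag_right=ed_prox_right)
    dist = demarcate_junction(vj_dist, revcomp(uninv_seq[pa0:pa1]),
                              uninv_seq[da0:da1],
                              left_u=(pa0, pa1), right_u=(da0, da1),
                              left_reversed=True,
                              expected_diag_left=ed_dist_left,
                              expected_diag_right=ed_dist_right)

    a_end = prox.left.u_boundary if prox.left.found else prox_t.start
    c_end = prox.right.u_boundary if prox.right.found else dist_t.end
    b_start = dist.left.u_boundary if dist.left.found else prox_t.start
    d_start = dist.right.u_boundary if dist.right.found else dist_t.end

    unassigned = []
    if prox.unassigned_vj:
        lo, hi = prox.unassigned_vj
        if hi - lo >= 1:
            unassigned.append(Interval(inv_id, pq0 + lo, pq0 + hi))
    if dist.unassigned_vj:
        lo, hi = dist.unassigned_vj
        if hi - lo >= 1:
            unassigned.append(Interval(inv_id, dq0 + lo, dq0 + hi))

    smap = SegmentMap(
        ref_id=ref_id,
        a_end=a_end, b_start=b_start, c_end=c_end, d_start=d_start,
        prox_call=prox, dist_call=dist,
        junction_inv_prox=pq0 + prox.junction_vj,
        junction_inv_dist=dq0 + dist.junction_vj,
        unassigned=unassigned,
        prox_window=(pq0, pq1),
        dist_window=(dq0, dq1),
    )
    smap.segments = {
        "A": Interval(ref_id, max(0, pa0), max(a_end, pa0 + 1)),
        "B": Interval(ref_id, min(b_start, pa1 - 1), pa1),
        "C": Interval(ref_id, max(0, da0), max(c_end, da0 + 1)),
        "D": Interval(ref_id, min(d_start, da1 - 1), da1),
    }
    return smap
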