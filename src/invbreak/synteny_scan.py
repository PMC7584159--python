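"""Anchor-based conserved-synteny comparison of two chromosome sequences.

Inversions announce themselves as interrupted synteny: runs of colinear
exact-match anchors whose orientation flips and whose flanking gaps — the
anchor deserts — contain the breakpoints.  Anchors are k-mers unique in
the target, which suppresses repeat noise; breakpoint neighbourhoods
(typically repeat-rich) are therefore expected to be anchor deserts
bounded by unique flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_model import Interval, LabeledSequence, revcomp


@dataclass(frozen=True)
class Anchor:
    """Exact k-mer match between query and target.

    For ``-`` orientation the query k-mer matches the reverse complement
    of the target k-mer starting at ``t_pos`` (both positions are the
    leftmost base of the k-mer on their own sequence, forward strand).
    """

    q_pos: int
    t_pos: int
    k: int
    orientation: str


@dataclass
class SyntenyBlock:
    q_interval: Interval
    t_interval: Interval
    orientation: str
    n_anchors: int
    score: int  # summed anchor length, bp


@dataclass
class BreakpointCandidate:
    """An orientation flip bounded by unanchored breakpoint regions."""

    proximal_q: Interval
    proximal_t: Interval
    distal_q: Interval
    distal_t: Interval
    flipped_span: int


def _as_str(seq: str | LabeledSequence) -> str:
    return seq.seq if isinstance(seq, LabeledSequence) else seq.upper()


def find_anchors(query: str | LabeledSequence, target: str | LabeledSequence,
                 k: int = 15) -> list[Anchor]:
    """All exact k-mer matches (both orientations) against k-mers unique in
    the target; sorted by query position.  k-mers containing non-ACGT
    characters never match.  ``k < 11`` is rejected as below the
    spurious-match floor."""
    if k < 11:
        raise ValueError("k < 11: spurious-match floor")
    q = _as_str(query)
    t = _as_str(target)
    if len(q) < k or len(t) < k:
        raise ValueError("sequences shorter than k")
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(t) - k + 1):
        km = t[i:i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    unique = {km: p for km, p in pos.items()
              if counts[km] == 1 and "N" not in km}
    anchors: list[Anchor] = []
    for i in range(len(q) - k + 1):
        km = q[i:i + k]
        if "N" in km:
            continue
        tp = unique.get(km)
        if tp is not None:
            anchors.append(Anchor(i, tp, k, "+"))
        rp = unique.get(revcomp(km))
        if rp is not None:
            anchors.append(Anchor(i, rp, k, "-"))
    anchors.sort(key=lambda a: (a.q_pos, a.orientation, a.t_pos))
    return anchors


def chain_blocks(anchors: list[Anchor], max_gap: int = 2000,
                 min_anchors: int = 3,
                 q_id: str = "query", t_id: str = "target") -> list[SyntenyBlock]:
    """Greedy colinear chaining of anchors into synteny blocks.

    Anchors are processed in query order; each joins the live chain of its
    orientation whose diagonal it deviates from least, provided both the
    query and target gaps stay within ``max_gap`` and coordinates remain
    monotone (decreasing in target for ``-``).  Ties go to the earliest
    chain; no anchor is assigned twice.  Chains shorter than
    ``min_anchors`` are dropped.
    """
    live: list[dict] = []
    done: list[dict] = []
    for a in anchors:
        diag = a.t_pos - a.q_pos if a.orientation == "+" else a.t_pos + a.q_pos
        # retire chains too far behind to ever accept another anchor
        still = []
        for c in live:
            if a.q_pos - c["last_q"] > max_gap:
                done.append(c)
            else:
                still.append(c)
        live = still
        best = None
        best_dev = None
        for c in live:
            if c["orient"] != a.orientation or a.q_pos <= c["last_q"]:
                continue
            if a.orientation == "+":
                if a.t_pos <= c["last_t"] or a.t_pos - c["last_t"] > max_gap:
                    continue
            else:
                if a.t_pos >= c["last_t"] or c["last_t"] - a.t_pos > max_gap:
                    continue
            dev = abs(diag - c["diag"])
            if best is None or dev < best_dev:
                best, best_dev = c, dev
        if best is None:
            live.append({"orient": a.orientation, "anchors": [a],
                         "last_q": a.q_pos, "last_t": a.t_pos, "diag": diag})
        else:
            best["anchors"].append(a)
            best["last_q"] = a.q_pos
            best["last_t"] = a.t_pos
            best["diag"] = diag
    done.extend(live)
    blocks = []
    for c in done:
        if len(c["anchors"]) < min_anchors:
            continue
        chain = c["anchors"]
        k = chain[0].k
        q_lo = chain[0].q_pos
        q_hi = chain[-1].q_pos + k
        t_positions = [a.t_pos for a in chain]
        t_lo = min(t_positions)
        t_hi = max(t_positions) + k
        blocks.append(SyntenyBlock(
            q_interval=Interval(q_id, q_lo, q_hi),
            t_interval=Interval(t_id, t_lo, t_hi),
            orientation=c["orient"],
            n_anchors=len(chain),
            score=sum(a.k for a in chain),
        ))
    blocks.sort(key=lambda b: (b.q_interval.start, b.q_interval.end))
    return blocks


def _gap_interval(seq_id: str, lo: int, hi: int) -> Interval:
    """Inter-block gap as an Interval; a touching boundary becomes a 1-bp
    interval centred on the junction estimate."""
    if hi <= lo:
        mid = max(0, (lo + hi) // 2)
        return Interval(seq_id, mid, mid + 1)
    return Interval(seq_id, lo, hi)


def call_inversion_candidates(blocks: list[SyntenyBlock],
                              expected_span: int | None = None,
                              span_tolerance: float = 0.2,
                              min_score_fraction: float = 0.05,
                              ) -> list[BreakpointCandidate]:
    """One inversion candidate per ``-`` block bracketed by ``+`` blocks.

    Breakpoint regions are the unanchored gaps between the flanking ``+``
    blocks and the flipped block, on both sequences.  Small blocks (score
    below ``min_score_fraction`` of the largest) are ignored when choosing
    flanks, so repeat shards inside an anchor desert do not shrink the
    reported regions.  With ``expected_span`` given, candidates are kept
    only when the flipped span is within ``span_tolerance`` of it.
    """
    if not blocks:
        return []
    top = max(b.score for b in blocks)
    major = [b for b in blocks if b.score >= min_score_fraction * top]
    out: list[BreakpointCandidate] = []
    for blk in major:
        if blk.orientation != "-":
            continue
        before = [b for b in major if b.orientation == "+"
                  and b.q_interval.start < blk.q_interval.start]
        after = [b for b in major if b.orientation == "+"
                 and b.q_interval.end > blk.q_interval.end]
        if not before or not after:
            continue
        prev = max(before, key=lambda b: b.q_interval.end)
        nxt = min(after, key=lambda b: b.q_interval.start)
        span = len(blk.q_interval)
        if expected_span is not None and \
                abs(span - expected_span) > span_tolerance * expected_span:
            continue
        q_id = blk.q_interval.seq_id
        t_id = blk.t_interval.seq_id
        out.append(BreakpointCandidate(
            proximal_q=_gap_interval(q_id, prev.q_interval.end,
                                     blk.q_interval.start),
            proximal_t=_gap_interval(t_id, prev.t_interval.end,
                                     blk.t_interval.start),
            distal_q=_gap_interval(q_id, blk.q_interval.end,
                                   nxt.q_interval.start),
            distal_t=_gap_interval(t_id, blk.t_interval.end,
                                   nxt.t_interval.start),
            flipped_span=span,
        ))
    out.sort(key=lambda c: -c.flipped_span)
    return out


def anchors_to_tsv(anchors: list[Anchor]) -> str:
    """Anchor list as TSV (q_pos, t_pos, k, orientation) for dot plotting."""
    lines = ["q_pos\tt_pos\tk\torientation"]
    for a in anchors:
        lines.append(f"{a.q_pos}\t{a.t_pos}\t{a.k}\t{a.orientation}")
    return "\n".join(lines) + "\n"
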