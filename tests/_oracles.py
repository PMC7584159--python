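"""Independent brute-force reference implementations used as test oracles.

Each oracle recomputes a quantity by exhaustive enumeration or textbook
dynamic programming, sharing no code path with the package internals it
checks.
"""

from __future__ import annotations

import numpy as np

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def gotoh_global_score(x: str, y: str, match: float = 1.0,
                       mismatch: float = -1.0, gap_open: float = -4.0,
                       gap_extend: float = -0.5) -> float:
    """Textbook three-state affine-gap global alignment score.

    Gap convention: a gap of length L costs gap_open + (L-1)*gap_extend.
    """
    n, m = len(x), len(y)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)   # gap in y (consumes x)
    Y = np.full((n + 1, m + 1), neg)   # gap in x (consumes y)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if x[i - 1] == y[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1],
                          Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def brute_force_anchors(query: str, target: str, k: int) -> set[tuple]:
    """All unique-in-target exact k-mer matches by direct double loop."""
    def rc(s):
        return "".join(_PAIR[c] for c in reversed(s))

    out = set()
    t_kmers = [target[j:j + k] for j in range(len(target) - k + 1)]
    for i in range(len(query) - k + 1):
        qk = query[i:i + k]
        if "N" in qk:
            continue
        fwd = [j for j, tk in enumerate(t_kmers) if tk == qk]
        if len(fwd) == 1 and "N" not in t_kmers[fwd[0]] \
                and t_kmers.count(t_kmers[fwd[0]]) == 1:
            out.add((i, fwd[0], k, "+"))
        rk = rc(qk) if set(qk) <= set("ACGT") else None
        if rk is not None:
            rev = [j for j, tk in enumerate(t_kmers) if tk == rk]
            if len(rev) == 1 and t_kmers.count(rk) == 1:
                out.add((i, rev[0], k, "-"))
    return out


def _arm_mismatches(seq: str, start: int, arm: int, spacer: int,
                    mirror: bool) -> int | None:
    """Mismatch count of the candidate repeat with left arm at ``start``;
    None if out of bounds."""
    if start < 0 or start + 2 * arm + spacer > len(seq):
        return None
    left = seq[start:start + arm]
    right = seq[start + arm + spacer:start + 2 * arm + spacer]
    mism = 0
    for i in range(arm):
        a = left[i]
        b = right[arm - 1 - i]
        if mirror:
            ok = a == b and a in "ACGT"
        else:
            ok = _PAIR.get(a) == b and a in "ACGT"
        if not ok:
            mism += 1
    return mism


def _tip_matches(seq: str, start: int, arm: int, spacer: int,
                 mirror: bool) -> bool:
    a = seq[start]
    b = seq[start + 2 * arm + spacer - 1]
    if mirror:
        return a == b and a in "ACGT"
    return _PAIR.get(a) == b and a in "ACGT"


def brute_force_repeats(seq: str, arm_range: tuple[int, int],
                        max_spacer: int, max_mismatch: int,
                        mirror: bool = False) -> set[tuple]:
    """All maximal inverted (or mirror) repeats by full enumeration of
    (start, arm, spacer) triples; returns {(start, end, arm, spacer,
    mismatches)} after per-interval deduplication."""
    seq = seq.upper()
    arm_min, arm_max = arm_range
    found = []
    for spacer in range(max_spacer + 1):
        for arm in range(arm_min, arm_max + 1):
            for start in range(len(seq) - 2 * arm - spacer + 1):
                mism = _arm_mismatches(seq, start, arm, spacer, mirror)
                if mism is None or mism > max_mismatch:
                    continue
                if not _tip_matches(seq, start, arm, spacer, mirror):
                    continue
                # maximality: no larger tip-matching arm within budget/caps
                maximal = True
                for arm2 in range(arm + 1, arm_max + 1):
                    start2 = start - (arm2 - arm)
                    m2 = _arm_mismatches(seq, start2, arm2, spacer, mirror)
                    if m2 is not None and m2 <= max_mismatch and \
                            _tip_matches(seq, start2, arm2, spacer, mirror):
                        maximal = False
                        break
                if maximal:
                    found.append((start, start + 2 * arm + spacer, arm,
                                  spacer, mism))
    best: dict[tuple[int, int], tuple] = {}
    for start, end, arm, spacer, mism in found:
        cur = best.get((start, end))
        if cur is None or (-arm, mism, spacer) < (-cur[2], cur[4], cur[3]):
            best[(start, end)] = (start, end, arm, spacer, mism)
    return set(best.values())


def tandem_run(seq: str, start: int, period: int) -> tuple[int, int]:
    """Maximal run of seq[i] == seq[i+period] containing ``start``,
    by direct scanning; returns the (lo, hi) span of the repeat."""
    lo = start
    while lo - 1 >= 0 and lo - 1 + period < len(seq) \
            and seq[lo - 1] == seq[lo - 1 + period] and seq[lo - 1] in "ACGT":
        lo -= 1
    hi = start
    while hi < len(seq) - period and seq[hi] == seq[hi + period] \
            and seq[hi] in "ACGT":
        hi += 1
    return lo, hi + period


def pwm_exact_scan(seq: str, counts: np.ndarray, pseudocount: float,
                   background: np.ndarray, p_cutoff: float,
                   bin_size: float = 0.01) -> set[tuple]:
    """PWM hits by per-window rescoring with exact p-values from full
    enumeration of all 4^w windows (independent of the convolution code).

    Returns {(start, strand)} of hits at p <= cutoff.
    """
    from itertools import product

    w = counts.shape[1]
    freqs = counts + pseudocount
    freqs = freqs / freqs.sum(axis=0, keepdims=True)
    lodds = np.log2(freqs / background[:, None])
    int_lodds = np.round(lodds / bin_size).astype(int)

    probs: dict[int, float] = {}
    for word in product(range(4), repeat=w):
        score = sum(int(int_lodds[b, j]) for j, b in enumerate(word))
        p = 1.0
        for j, b in enumerate(word):
            p *= background[b]
        probs[score] = probs.get(score, 0.0) + p
    scores_sorted = sorted(probs)
    tail = {}
    acc = 0.0
    for s in reversed(scores_sorted):
        acc += probs[s]
        tail[s] = acc

    def pval(int_score: int) -> float:
        candidates = [s for s in scores_sorted if s >= int_score]
        return tail[candidates[0]] if candidates else 0.0

    def rc(s):
        return "".join(_PAIR[c] for c in reversed(s))

    idx = {b: i for i, b in enumerate("ACGT")}
    hits = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", rc(seq))):
        for i in range(n - w + 1):
            window = s[i:i + w]
            if any(c not in idx for c in window):
                continue
            score = sum(int(int_lodds[idx[c], j])
                        for j, c in enumerate(window))
            if pval(score) <= p_cutoff:
                start = i if strand == "+" else n - i - w
                hits.add((start, strand))
    return hits
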