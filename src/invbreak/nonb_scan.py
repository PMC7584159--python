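"""Scanners for non-B DNA-forming motifs.

Covers the motif classes implicated in breakpoint fragility: inverted
repeats (hairpin/cruciform), mirror repeats (triplex), tandem/direct
repeats (slipped strands), alternating purine-pyrimidine tracts (Z-DNA),
G4 motifs (tetraplex), and A-phased repeats (static bending).

Inverted and mirror repeats are reported *maximally*: a motif is emitted
when its arms cannot be extended by one base without exceeding the
mismatch budget, the arm-length ceiling, or the sequence bounds.  Nested
and overlapping motifs are retained — dense palindromic clusters are the
signal of interest, and collapsing them would hide it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources

from .seq_model import Interval, revcomp

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class NonBMotif:
    kind: str  # IR | MIRROR | TANDEM | ZDNA | G4 | APHASED
    interval: Interval
    arm_len: int | None = None
    spacer_len: int | None = None
    mismatches: int | None = None
    copy_number: float | None = None
    period: int | None = None
    consensus: str | None = None
    dG_cruciform: float | None = None
    score: float | None = None


def _complement_match(a: str, b: str) -> bool:
    # N never matches anything in exact-match scanners.
    return _PAIR.get(a) == b and b in "ACGT"


def find_inverted_repeats(seq: str, arm_range: tuple[int, int] = (6, 20),
                          max_spacer: int = 10, max_mismatch: int = 1,
                          seq_id: str = "seq") -> list[NonBMotif]:
    """All maximal inverted repeats satisfying the arm/spacer/mismatch bounds.

    A motif is parameterized by the spacer placement: left arm ends at
    ``s`` (exclusive), spacer occupies ``[s, s+g)``, right arm starts at
    ``s+g``.  For each placement the arm is grown outward while the
    mismatch budget holds; the maximal arm within ``arm_range`` is
    reported.  Deterministic, sorted by start.
    """
    arm_min, arm_max = arm_range
    if arm_min < 4:
        raise ValueError("arm_min < 4: spurious-match floor")
    seq = seq.upper()
    n = len(seq)
    if n < 2 * arm_min:
        return []
    out: list[NonBMotif] = []
    for s in range(1, n):
        for g in range(0, max_spacer + 1):
            arm = 0
            mism = 0
            best = None
            while True:
                li = s - 1 - arm
                ri = s + g + arm
                if li < 0 or ri >= n or arm >= arm_max:
                    break
                if not _complement_match(seq[li], seq[ri]):
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                if arm >= arm_min:
                    best = (arm, mism)
            if best is not None:
                a, m = best
                # trailing mismatch at the arm tip is not counted as arm
                while a >= arm_min and not _complement_match(seq[s - a], seq[s + g + a - 1]):
                    a -= 1
                    m -= 1
                if a >= arm_min:
                    out.append(NonBMotif(
                        kind="IR",
                        interval=Interval(seq_id, s - a, s + g + a),
                        arm_len=a, spacer_len=g, mismatches=m,
                    ))
    return _dedupe_repeats(out)


def _dedupe_repeats(motifs: list[NonBMotif]) -> list[NonBMotif]:
    """Collapse same-interval parameterizations (e.g. a perfect palindrome
    re-read as shorter arms around a wider spacer), keeping the longest-arm,
    fewest-mismatch call per interval.  Nested/overlapping motifs with
    distinct intervals are all retained."""
    best: dict[tuple[int, int], NonBMotif] = {}
    for mo in motifs:
        key = (mo.interval.start, mo.interval.end)
        cur = best.get(key)
        if cur is None or (-mo.arm_len, mo.mismatches, mo.spacer_len) < \
                (-cur.arm_len, cur.mismatches, cur.spacer_len):
            best[key] = mo
    return sorted(best.values(), key=lambda mo: (mo.interval.start, mo.interval.end))


def find_mirror_repeats(seq: str, arm_range: tuple[int, int] = (6, 20),
                        max_spacer: int = 50, max_mismatch: int = 1,
                        seq_id: str = "seq") -> list[NonBMotif]:
    """Maximal mirror repeats (arm matches the *reversed*, not complemented,
    arm).  Same maximality convention as :func:`find_inverted_repeats`; the
    default spacer ceiling is wider because triplex-forming mirrors tolerate
    long loops."""
    arm_min, arm_max = arm_range
    if arm_min < 4:
        raise ValueError("arm_min < 4: spurious-match floor")
    seq = seq.upper()
    n = len(seq)
    out: list[NonBMotif] = []
    for s in range(1, n):
        for g in range(0, max_spacer + 1):
            arm = 0
            mism = 0
            best = None
            while True:
                li = s - 1 - arm
                ri = s + g + arm
                if li < 0 or ri >= n or arm >= arm_max:
                    break
                match = seq[li] == seq[ri] and seq[li] in "ACGT"
                if not match:
                    mism += 1
                    if mism > max_mismatch:
                        break
                arm += 1
                if arm >= arm_min:
                    best = (arm, mism)
            if best is not None:
                a, m = best
                while a >= arm_min and not (seq[s - a] == seq[s + g + a - 1]
                                            and seq[s - a] in "ACGT"):
                    a -= 1
                    m -= 1
                if a >= arm_min:
                    out.append(NonBMotif(
                        kind="MIRROR",
                        interval=Interval(seq_id, s - a, s + g + a),
                        arm_len=a, spacer_len=g, mismatches=m,
                    ))
    return _dedupe_repeats(out)


def _load_stacking_table() -> dict:
    table: dict = {}
    text = resources.files("invbreak.data").joinpath("stacking_dg.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, value = line.split("\t")
        table[key] = float(value)
    return table


_STACKING: dict | None = None


def stacking_table() -> dict:
    global _STACKING
    if _STACKING is None:
        _STACKING = _load_stacking_table()
    return _STACKING


def cruciform_dG(ir: NonBMotif, seq: str, table: dict | None = None,
                 mismatch_penalty: float = 1.5) -> float:
    """Cruciform-forming propensity of an inverted repeat.

    Scores the free-energy difference between the linear duplex and the
    extruded cruciform as the stem stacking energy recovered on intrastrand
    annealing minus a logarithmic loop penalty for the spacer:

        score = -sum(dG_step over the arm) - loop_base
                - loop_slope * ln(spacer + 2) - mismatch_penalty * mismatches

    Higher means higher propensity, so hits can be ranked.  The parameter
    table ships with the package (``data/stacking_dg.tsv``) and can be
    overridden.
    """
    if ir.kind != "IR":
        raise ValueError(f"cruciform_dG requires an IR motif, got {ir.kind}")
    if not ir.arm_len:
        raise ValueError("zero-length arm")
    if table is None:
        table = stacking_table()
    arm = seq[ir.interval.start:ir.interval.start + ir.arm_len].upper()
    stack = 0.0
    for i in range(len(arm) - 1):
        step = arm[i:i + 2]
        if step in table:
            stack += table[step]
        else:
            stack += table.get(revcomp(step), 0.0)
    loop = table["loop_base"] + table["loop_slope"] * math.log(ir.spacer_len + 2)
    return -stack - loop - mismatch_penalty * (ir.mismatches or 0)


def find_tandem_repeats(seq: str, min_copies: float = 1.9,
                        max_period: int = 50,
                        seq_id: str = "seq") -> list[NonBMotif]:
    """Tandem repeats with fractional copy number.

    For each candidate period ``p`` the scan marks positions where
    ``seq[i] == seq[i+p]``; a maximal run of agreement from ``a`` to ``b``
    covers the repeat span ``[a, b+p)`` with ``(b+p-a)/p`` copies.
    Overlapping calls across periods are resolved to the call with the
    largest spanned length (copies x period), preferring the shortest
    period on ties.  The consensus is the per-phase majority over the span.
    """
    if max_period > 50:
        raise ValueError("max_period > 50 unsupported")
    seq = seq.upper()
    n = len(seq)
    candidates: list[tuple[int, int, int]] = []  # (start, end, period)
    for p in range(1, min(max_period, n - 1) + 1):
        i = 0
        while i < n - p:
            if seq[i] == seq[i + p] and seq[i] in "ACGT":
                j = i
                while j < n - p and seq[j] == seq[j + p] and seq[j] in "ACGT":
                    j += 1
                span = (j - i) + p
                if span / p >= min_copies:
                    candidates.append((i, i + span, p))
                i = j + 1
            else:
                i += 1
    # longest span wins among overlapping candidates; shortest period on ties
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    accepted: list[tuple[int, int, int]] = []
    for start, end, p in candidates:
        if any(start < e and s < end for s, e, _ in accepted):
            continue
        accepted.append((start, end, p))
    out = []
    for start, end, p in sorted(accepted):
        span = seq[start:end]
        consensus = "".join(
            max("ACGT", key=lambda b: sum(1 for k in range(phase, len(span), p)
                                          if span[k] == b))
            for phase in range(p)
        )
        out.append(NonBMotif(
            kind="TANDEM",
            interval=Interval(seq_id, start, end),
            period=p, copy_number=len(span) / p, consensus=consensus,
        ))
    return out


def find_zdna(seq: str, min_len: int = 12, seq_id: str = "seq") -> list[NonBMotif]:
    """Maximal alternating purine-pyrimidine tracts of at least ``min_len``.

    The reported score weights GC/CG dinucleotide steps (3.0) over the
    weaker AT-containing alternations (1.0)."""
    seq = seq.upper()
    n = len(seq)
    out = []
    i = 0
    while i < n - 1:
        if ((seq[i] in _PURINES and seq[i + 1] in _PYRIMIDINES)
                or (seq[i] in _PYRIMIDINES and seq[i + 1] in _PURINES)):
            j = i + 1
            while j < n - 1 and (
                (seq[j] in _PURINES and seq[j + 1] in _PYRIMIDINES)
                or (seq[j] in _PYRIMIDINES and seq[j + 1] in _PURINES)
            ):
                j += 1
            length = j - i + 1
            if length >= min_len:
                tract = seq[i:j + 1]
                score = sum(3.0 if tract[k:k + 2] in ("GC", "CG") else 1.0
                            for k in range(length - 1))
                out.append(NonBMotif(
                    kind="ZDNA", interval=Interval(seq_id, i, j + 1), score=score,
                ))
            i = j + 1
        else:
            i += 1
    return out


_G4_RE = re.compile(r"G{3,}(?:[ACGT]{1,7}G{3,}){3}")


def find_g4(seq: str, seq_id: str = "seq") -> list[NonBMotif]:
    """Canonical G4 motifs G{3,}(N1-7 G{3,}){3} on both strands."""
    seq = seq.upper()
    n = len(seq)
    out = []
    for m in _G4_RE.finditer(seq):
        out.append(NonBMotif(kind="G4",
                             interval=Interval(seq_id, m.start(), m.end(), "+")))
    rc = revcomp(seq)
    for m in _G4_RE.finditer(rc):
        start = n - m.end()
        end = n - m.start()
        out.append(NonBMotif(kind="G4", interval=Interval(seq_id, start, end, "-")))
    out.sort(key=lambda mo: (mo.interval.start, mo.interval.strand))
    return out


def find_aphased(seq: str, min_tracts: int = 3, seq_id: str = "seq") -> list[NonBMotif]:
    """A-phased repeats: >=3 A-tracts (3-9 bp, A- or T-runs) whose centers
    are spaced one helical turn (10 +/- 1 bp) apart."""
    seq = seq.upper()
    tracts = []
    for m in re.finditer(r"A{3,9}|T{3,9}", seq):
        # skip runs embedded in longer homopolymers
        if (m.start() > 0 and seq[m.start() - 1] == seq[m.start()]) or \
           (m.end() < len(seq) and seq[m.end()] == seq[m.end() - 1]):
            continue
        tracts.append((m.start(), m.end(), (m.start() + m.end() - 1) / 2))
    out = []
    i = 0
    while i < len(tracts):
        chain = [tracts[i]]
        j = i
        for k in range(i + 1, len(tracts)):
            spacing = tracts[k][2] - chain[-1][2]
            if 9 <= spacing <= 11:
                chain.append(tracts[k])
                j = k
            elif spacing > 11:
                break
        if len(chain) >= min_tracts:
            out.append(NonBMotif(
                kind="APHASED",
                interval=Interval(seq_id, chain[0][0], chain[-1][1]),
                copy_number=float(len(chain)),
            ))
            i = j + 1
        else:
            i += 1
    return out


def window_density(motifs: list[NonBMotif], seq_len: int,
                   window: int = 100, step: int = 50) -> list[tuple[int, int, int]]:
    """Per-window motif counts (start, end, count), for density profiles."""
    rows = []
    for start in range(0, max(1, seq_len - window + 1), step):
        end = start + window
        count = sum(1 for m in motifs
                    if m.interval.start < end and m.interval.end > start)
        rows.append((start, end, count))
    return rows
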