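"""PWM-based transcription-factor binding-site scanning of upstream regions.

Log-odds scanning of both strands with *exact* p-values obtained by
convolving the per-position score distributions under a 0-order background
model (score discretization 0.01 log-odds units), in the spirit of FIMO.
No multiple-testing correction is applied; hit counts are reported so
users can apply their own.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seq_model import Interval, LabeledSequence, revcomp

_BASES = "ACGT"
_SCORE_BIN = 0.01


@dataclass
class PWM:
    """Position weight matrix (counts or frequencies, 4 x width)."""

    name: str
    matrix: np.ndarray  # shape (4, width), rows A C G T
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 4:
            raise ValueError(f"PWM {self.name}: need 4 rows and width >= 4")
        totals = self.matrix.sum(axis=0)
        if not np.allclose(totals, totals[0], rtol=1e-6):
            raise ValueError(f"PWM {self.name}: column sums differ")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        freqs = self.matrix + self.pseudocount
        freqs = freqs / freqs.sum(axis=0, keepdims=True)
        return np.log2(freqs / background[:, None])


@dataclass
class MotifHit:
    pwm_name: str
    interval: Interval
    strand: str
    score: float
    p_value: float


def read_pwms(path: str | os.PathLike) -> list[PWM]:
    """Read PWMs from the 4-row count matrix dialect::

        >motif_name
        A  10  0  3 ...
        C   0 12  4 ...
        G   2  0  5 ...
        T   0  0  0 ...
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(_assemble_pwm(name, rows))
                name = line[1:].split()[0]
                rows = {}
            else:
                fields = line.replace(":", " ").split()
                base = fields[0].upper()
                if base not in _BASES:
                    raise ValueError(f"PWM {name}: unexpected row label {base!r}")
                rows[base] = [float(v) for v in fields[1:]]
    if name is not None:
        pwms.append(_assemble_pwm(name, rows))
    if not pwms:
        raise ValueError(f"{path}: no PWM records found")
    return pwms


def _assemble_pwm(name: str, rows: dict[str, list[float]]) -> PWM:
    missing = [b for b in _BASES if b not in rows]
    if missing:
        raise ValueError(f"PWM {name}: missing rows {missing}")
    return PWM(name, np.array([rows[b] for b in _BASES]))


def estimate_background(seq: str) -> np.ndarray:
    """0-order base frequencies with a pseudocount, in ACGT order."""
    counts = np.array([seq.count(b) for b in _BASES], dtype=float) + 1.0
    return counts / counts.sum()


def score_distribution(log_odds: np.ndarray, background: np.ndarray,
                       bin_size: float = _SCORE_BIN) -> tuple[np.ndarray, int]:
    """Exact distribution of the discretized window score under the
    background model, via position-by-position convolution.

    Returns ``(tail, offset)`` where ``tail[k]`` is ``P(score_int >= k +
    offset)`` over integer score bins.
    """
    int_scores = np.round(log_odds / bin_size).astype(np.int64)
    lo = int(int_scores.min(axis=0).sum())
    hi = int(int_scores.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    pmf[-lo if lo < 0 else 0] = 0.0
    # start with a point mass at score 0, tracked relative to `lo`
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(int_scores.shape[1]):
        col = int_scores[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift:shift + len(cur)] += background[b] * cur
        cur = new
        cur_lo = new_lo
    pmf = np.zeros(hi - lo + 1)
    pmf[cur_lo - lo:cur_lo - lo + len(cur)] = cur
    tail = np.cumsum(pmf[::-1])[::-1]
    return tail, lo


def _window_scores(seq: str, log_odds: np.ndarray) -> np.ndarray:
    w = log_odds.shape[1]
    n = len(seq)
    idx = np.full(n, -1, dtype=np.int64)
    for b, base in enumerate(_BASES):
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = b
    scores = np.full(n - w + 1, -np.inf)
    valid = np.ones(n - w + 1, dtype=bool)
    acc = np.zeros(n - w + 1)
    for j in range(w):
        col_idx = idx[j:n - w + 1 + j]
        bad = col_idx < 0
        valid &= ~bad
        safe = np.where(bad, 0, col_idx)
        acc += log_odds[safe, j]
    scores[valid] = acc[valid]
    return scores


def scan_pwm(seq: str | LabeledSequence, pwm: PWM, p_cutoff: float = 1e-3,
             background: np.ndarray | None = None,
             seq_id: str | None = None) -> list[MotifHit]:
    """Scan both strands, reporting hits with exact tail p <= ``p_cutoff``.

    The background is estimated from the scanned sequence (0-order) unless
    supplied.  Windows containing ``N`` are skipped.  Returns hits sorted
    by position; an over-wide PWM yields an empty list.
    """
    if isinstance(seq, LabeledSequence):
        seq_id = seq_id or seq.id
        seq = seq.seq
    seq = seq.upper()
    seq_id = seq_id or "seq"
    n = len(seq)
    w = pwm.width
    if w > n:
        return []
    if background is None:
        background = estimate_background(seq)
    background = np.asarray(background, dtype=float)
    lodds = pwm.log_odds(background)
    tail, offset = score_distribution(lodds, background)
    # score windows on the same per-position-discretized grid the null
    # distribution is built on, so p-values are exactly calibrated
    int_lodds = np.round(lodds / _SCORE_BIN).astype(np.int64)

    def pval(int_score: int) -> float:
        k = min(max(int_score - offset, 0), len(tail) - 1)
        return float(tail[k])

    hits: list[MotifHit] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        scores = _window_scores(s, int_lodds.astype(float))
        for i in np.nonzero(np.isfinite(scores))[0]:
            p = pval(int(round(scores[i])))
            if p <= p_cutoff:
                if strand == "+":
                    iv = Interval(seq_id, int(i), int(i) + w, "+")
                else:
                    iv = Interval(seq_id, n - int(i) - w, n - int(i), "-")
                hits.append(MotifHit(pwm.name, iv, strand,
                                     float(scores[i]) * _SCORE_BIN, p))
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


@dataclass
class UpstreamWindow:
    gene_id: str
    seq: LabeledSequence
    interval: Interval
    truncated: bool


def read_gff3_genes(path: str | os.PathLike,
                    feature: str = "gene") -> list[tuple[str, Interval]]:
    """Gene records from a GFF3 file as ``(gene_id, Interval)`` tuples.

    GFF3 is 1-based inclusive; intervals are converted to the internal
    0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"])
    genes = []
    for _, row in df[df["type"] == feature].iterrows():
        attrs = dict(kv.split("=", 1) for kv in str(row.attributes).split(";")
                     if "=" in kv)
        gene_id = attrs.get("ID") or attrs.get("Name") or f"{row.seqid}:{row.start}"
        genes.append((gene_id,
                      Interval(row.seqid, int(row.start) - 1, int(row.end),
                               row.strand)))
    return genes


def extract_upstream(genes: list[tuple[str, Interval]],
                     genome: dict[str, LabeledSequence] | LabeledSequence,
                     length: int = 1000) -> list[UpstreamWindow]:
    """Strand-aware upstream windows of ``length`` bp from each gene's TSS.

    Windows are truncated (and flagged) at sequence ends; the extracted
    sequence reads 5'->3' relative to the gene.  A gene lying off its
    sequence raises an error naming the gene.
    """
    if isinstance(genome, LabeledSequence):
        genome = {genome.id: genome}
    out: list[UpstreamWindow] = []
    for gene_id, iv in genes:
        parent = genome.get(iv.seq_id)
        if parent is None:
            raise ValueError(f"gene {gene_id}: unknown sequence {iv.seq_id}")
        n = len(parent.seq)
        if iv.start >= n or iv.end > n:
            raise ValueError(f"gene {gene_id}: lies off sequence {iv.seq_id}")
        if iv.strand == "+":
            start, end = iv.start - length, iv.start
        else:
            start, end = iv.end, iv.end + length
        truncated = start < 0 or end > n
        start, end = max(0, start), min(n, end)
        if start >= end:
            raise ValueError(f"gene {gene_id}: empty upstream window")
        window = parent.seq[start:end]
        if iv.strand == "-":
            window = revcomp(window)
        out.append(UpstreamWindow(
            gene_id,
            LabeledSequence(f"{gene_id}_upstream", window, offset=start),
            Interval(iv.seq_id, start, end, iv.strand),
            truncated,
        ))
    return out


def compare_states(hitsets: dict[tuple[str, str], list[MotifHit]],
                   tf_names: list[str],
                   newly_attached: dict[tuple[str, str], list[Interval]] | None = None,
                   ) -> pd.DataFrame:
    """Per-TF presence/absence across (gene, chromosome-state) pairs.

    Rows are TF names (all of ``tf_names`` retained, hits or not); columns
    are the (gene, state) pairs.  When ``newly_attached`` intervals are
    given for a pair, a TF whose hits there *all* fall inside newly
    attached sequence gets ``gained`` appended to its cell, flagging a
    binding site contributed by the rearrangement.
    """
    columns = sorted(hitsets)
    data = {}
    for col in columns:
        hits = hitsets[col]
        cell = {}
        for tf in tf_names:
            tf_hits = [h for h in hits if h.pwm_name == tf]
            if not tf_hits:
                cell[tf] = "absent"
                continue
            label = "present"
            if newly_attached and col in newly_attached:
                regions = newly_attached[col]
                if all(any(h.interval.start >= r.start and h.interval.end <= r.end
                           for r in regions) for h in tf_hits):
                    label = "present(gained)"
            cell[tf] = label
        data["/".join(col)] = cell
    return pd.DataFrame(data, index=tf_names)
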