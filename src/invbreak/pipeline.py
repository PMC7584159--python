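"""End-to-end inference: synteny scan -> junction demarcation -> junction
architecture -> mechanism call, plus truth-based evaluation.

The reference for demarcation is the first uninverted assembly; every
additional uninverted line is demarcated independently, and cross-line
asymmetries in junction support provide the haplotype-mosaic evidence
that distinguishes in-trans (chromosome-model) repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .inversion_sim import SimTruth
from .junction_arch import (JunctionArchitecture, MosaicCall,
                            call_duplications, call_microinversion,
                            find_filler_microhomology)
from .junction_map import SegmentMap, demarcate_segments, second_pass_homology
from .mechanism_call import MechanismCall, classify
from .seq_model import Interval, LabeledSequence
from .synteny_scan import (BreakpointCandidate, call_inversion_candidates,
                           chain_blocks, find_anchors)


@dataclass
class InferenceParams:
    k: int = 15
    max_gap: int = 2000
    min_anchors: int = 3
    pad: int = 400
    flank: int = 1600
    expected_span: int | None = None
    mosaic_margin: int = 30
    mosaic_identity_gap: float = 0.20


@dataclass
class InferenceResult:
    no_inversion: bool
    candidate: BreakpointCandidate | None = None
    segment_map: SegmentMap | None = None
    per_line_maps: dict = field(default_factory=dict)
    architecture: JunctionArchitecture | None = None
    call: MechanismCall | None = None


def _line_segment_map(inverted: LabeledSequence, line: LabeledSequence,
                      params: InferenceParams,
                      ) -> tuple[BreakpointCandidate | None, SegmentMap | None]:
    anchors = find_anchors(inverted, line, k=params.k)
    blocks = chain_blocks(anchors, max_gap=params.max_gap,
                          min_anchors=params.min_anchors,
                          q_id=inverted.id, t_id=line.id)
    cands = call_inversion_candidates(blocks, expected_span=params.expected_span)
    if not cands:
        return None, None
    cand = cands[0]
    smap = demarcate_segments(inverted.seq, line.seq,
                              cand.proximal_q, cand.proximal_t,
                              cand.distal_q, cand.distal_t,
                              pad=params.pad, flank=params.flank,
                              ref_id=line.id, inv_id=inverted.id)
    return cand, smap


def _abs_boundaries(smap: SegmentMap) -> dict:
    """Junction-support boundaries in absolute inverted-assembly coords."""
    out = {}
    pq0 = smap.prox_window[0]
    dq0 = smap.dist_window[0]
    pc, dc = smap.prox_call, smap.dist_call
    out["a_vj"] = pq0 + pc.left.vj_boundary if pc.left.found else None
    out["c_vj"] = pq0 + pc.right.vj_boundary if pc.right.found else None
    out["b_vj"] = dq0 + dc.left.vj_boundary if dc.left.found else None
    out["d_vj"] = dq0 + dc.right.vj_boundary if dc.right.found else None
    return out


def _piece_identity(piece: str, target: str) -> float:
    if not piece or len(target) < len(piece) // 2:
        return 0.0
    res = edlib.align(piece, target, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return max(0.0, 1.0 - res["editDistance"] / len(piece))


def _phase_mosaic(inverted_seq: str, maps: dict[str, SegmentMap],
                  line_seqs: dict[str, str],
                  params: InferenceParams) -> MosaicCall:
    """Chromosome-model evidence from cross-line junction support.

    At the distal junction, the line whose +D homology reaches closest to
    the junction is the downstream-half donor; at the proximal junction
    the line whose -C homology reaches closest is the upstream donor.  A
    mosaic needs the two donors to differ, with support margins of at
    least ``mosaic_margin`` bp and an identity gap of at least 20 points
    on the disputed stretch.  The central deletion is measured on the
    downstream donor, mapping the upstream donor's homology end through
    the reverse-complement correspondence between the two haplotypes'
    spacers.
    """
    if len(maps) < 2:
        return MosaicCall(False, note="insufficient haplotypes")
    bounds = {line: _abs_boundaries(m) for line, m in maps.items()}
    usable = {line: b for line, b in bounds.items()
              if b["c_vj"] is not None and b["d_vj"] is not None}
    if len(usable) < 2:
        return MosaicCall(False, note="unresolved junction support")
    up_line = min(usable, key=lambda l: usable[l]["c_vj"])
    down_line = min(usable, key=lambda l: usable[l]["d_vj"])
    call = MosaicCall(False, upstream_line=up_line, downstream_line=down_line)
    if up_line == down_line:
        return call
    margin_up = min(usable[l]["c_vj"] for l in usable if l != up_line) \
        - usable[up_line]["c_vj"]
    margin_down = min(usable[l]["d_vj"] for l in usable if l != down_line) \
        - usable[down_line]["d_vj"]
    if margin_up < params.mosaic_margin or margin_down < params.mosaic_margin:
        return call
    # identity audit on the disputed upstream stretch
    c_fav = usable[up_line]["c_vj"]
    c_other = min(usable[l]["c_vj"] for l in usable if l != up_line)
    piece = inverted_seq[c_fav:min(c_fav + 250, c_other)]
    from .seq_model import revcomp as _rc
    piece = _rc(piece)  # -C orientation back to uninverted orientation
    for line, smap in maps.items():
        lo = max(0, smap.c_end - 600)
        call.upstream_identities[line] = _piece_identity(
            piece, line_seqs[line][lo:smap.c_end + 600])
    others = [v for l, v in call.upstream_identities.items() if l != up_line]
    if (call.upstream_identities.get(up_line, 0.0)
            - max(others, default=0.0)) < params.mosaic_identity_gap:
        return call
    call.mosaic = True
    # central deletion via the reverse-complement haplotype correspondence
    sm_up, sm_dn = maps[up_line], maps[down_line]
    w1_lo = max(0, sm_up.c_end - 150)
    w1 = line_seqs[up_line][w1_lo:sm_up.d_start + 150]
    w2_lo = max(0, sm_dn.c_end - 150)
    w2 = line_seqs[down_line][w2_lo:sm_dn.d_start + 150]
    try:
        anchors = [a for a in find_anchors(w1, w2, k=13)
                   if a.orientation == "-"]
    except ValueError:
        anchors = []
    if len(anchors) >= 3:
        antidiag = int(np.median(
            [w1_lo + a.q_pos + w2_lo + a.t_pos + a.k - 1 for a in anchors]))
        mapped = antidiag - sm_up.c_end + 1
        if sm_dn.d_start > mapped:
            call.central_deletion = (mapped, sm_dn.d_start)
    return call


def infer(inverted: LabeledSequence, uninverted: list[LabeledSequence],
          outgroup: LabeledSequence | None = None,
          params: InferenceParams | None = None) -> InferenceResult:
    """Run the full inference chain on one four-assembly comparison set."""
    params = params or InferenceParams()
    ref = uninverted[0]
    cand, smap = _line_segment_map(inverted, ref, params)
    if cand is None:
        return InferenceResult(no_inversion=True)

    links = second_pass_homology(inverted.seq, smap, ref.seq)
    uninv_seqs = {line.id: line.seq for line in uninverted}
    dups = call_duplications(smap, inverted.seq, uninv_seqs,
                             second_pass=links)
    microinv, conflict = call_microinversion(dups)

    per_line = {ref.id: smap}
    for line in uninverted[1:]:
        _, m = _line_segment_map(inverted, line, params)
        if m is not None:
            per_line[line.id] = m
    mosaic = _phase_mosaic(inverted.seq, per_line, uninv_seqs, params)

    # distal junction gap: best-supported +D boundary across lines
    bounds = {line: _abs_boundaries(m) for line, m in per_line.items()}
    d_candidates = [b["d_vj"] for b in bounds.values() if b["d_vj"] is not None]
    b_candidates = [b["b_vj"] for b in bounds.values() if b["b_vj"] is not None]
    filler = None
    microhomology = None
    dist_gap = 0
    if d_candidates and b_candidates:
        d_vj = min(d_candidates)
        b_vj = max(b_candidates)
        if d_vj > b_vj:
            gap_lo = b_vj
            # subtract gap prefix already relabeled as duplication copies
            for link in links:
                iv = link.copy_a
                if iv.seq_id == inverted.id and iv.start <= gap_lo + 10 \
                        and iv.end > gap_lo and iv.end <= d_vj:
                    gap_lo = max(gap_lo, iv.end)
            gap_str = inverted.seq[gap_lo:d_vj]
            dist_gap = len(gap_str)
            if gap_str:
                flank_d = inverted.seq[d_vj:d_vj + 60]
                microhomology = find_filler_microhomology(gap_str, flank_d)
                filler = gap_str
    prox_gap = sum(len(u) for u in smap.unassigned
                   if abs((u.start + u.end) // 2 - smap.junction_inv_prox)
                   < abs((u.start + u.end) // 2 - smap.junction_inv_dist))

    arch = JunctionArchitecture(
        insertions=[u for u in smap.unassigned if len(u) >= 40],
        duplications=dups,
        microinversion=microinv,
        microinversion_conflict=conflict,
        mosaic=mosaic,
        filler=filler,
        microhomology=microhomology,
        prox_overlap=smap.a_end - smap.b_start,
        dist_overlap=smap.c_end - smap.d_start,
        prox_unassigned=prox_gap,
        dist_unassigned=dist_gap,
        resolved=smap.prox_call.resolved and smap.dist_call.resolved,
    )
    call = classify(arch)
    return InferenceResult(False, cand, smap, per_line, arch, call)


def result_report(result: InferenceResult) -> dict:
    """JSON-serializable summary of an inference run."""
    if result.no_inversion:
        return {"no_inversion_candidate": True}
    smap = result.segment_map
    arch = result.architecture
    call = result.call
    out = {
        "no_inversion_candidate": False,
        "flipped_span": result.candidate.flipped_span,
        "segment_map": {
            "ref": smap.ref_id,
            "a_end": smap.a_end, "b_start": smap.b_start,
            "c_end": smap.c_end, "d_start": smap.d_start,
            "junction_uninv_prox": smap.junction_uninv_prox,
            "junction_uninv_dist": smap.junction_uninv_dist,
            "junction_inv_prox": smap.junction_inv_prox,
            "junction_inv_dist": smap.junction_inv_dist,
            "unassigned": [[u.seq_id, u.start, u.end] for u in smap.unassigned],
        },
        "duplications": [
            {"name": d.name, "orientation": d.orientation,
             "present_in": d.present_in, "identity": round(d.identity, 4),
             "copy_a": [d.copy_a.seq_id, d.copy_a.start, d.copy_a.end],
             "copy_b": (None if d.copy_b is None else
                        [d.copy_b.seq_id, d.copy_b.start, d.copy_b.end]),
             "low_complexity": d.low_complexity}
            for d in arch.duplications
        ],
        "microinversion": (None if arch.microinversion is None else
                           [arch.microinversion.start, arch.microinversion.end]),
        "mosaic": (None if arch.mosaic is None else {
            "mosaic": arch.mosaic.mosaic,
            "upstream_line": arch.mosaic.upstream_line,
            "downstream_line": arch.mosaic.downstream_line,
            "central_deletion": arch.mosaic.central_deletion,
        }),
        "filler": arch.filler,
        "microhomology": (None if arch.microhomology is None else {
            "filler_len": arch.microhomology.filler_len,
            "length": arch.microhomology.length,
            "mismatches": arch.microhomology.mismatches,
            "gap_offset": arch.microhomology.gap_offset,
        }),
        "mechanism": {
            "label": call.label,
            "proximal": call.proximal_label,
            "distal": call.distal_label,
            "bir_mmbir_compatible": call.bir_mmbir_compatible,
            "evidence": call.evidence,
            "notes": call.notes,
        },
    }
    return out


def evaluate(result: InferenceResult, truth: SimTruth) -> dict:
    """Recovery metrics of an inference against simulation ground truth."""
    metrics: dict = {"label_match": False, "bir_match": False}
    if result.no_inversion or result.call is None:
        metrics["label"] = "NO_CANDIDATE"
        return metrics
    call = result.call
    smap = result.segment_map
    metrics["label"] = call.label
    metrics["expected_label"] = truth.expected_label
    metrics["label_match"] = call.label == truth.expected_label
    metrics["bir_flag"] = call.bir_mmbir_compatible
    metrics["bir_match"] = call.bir_mmbir_compatible == truth.bir_flag
    metrics["prox_offset"] = smap.junction_inv_prox - truth.prox_junction_inv
    metrics["dist_offset"] = smap.junction_inv_dist - truth.dist_junction_inv
    if truth.microinversion is not None:
        arch = result.architecture
        if arch.microinversion is not None:
            span = len(arch.microinversion)
            metrics["microinversion_span_error"] = span - (
                truth.microinversion[1] - truth.microinversion[0])
        else:
            metrics["microinversion_span_error"] = None
    if truth.dd7 is not None:
        mos = result.architecture.mosaic
        if mos is not None and mos.central_deletion is not None:
            metrics["dd7_len_error"] = mos.central_deletion_len - (
                truth.dd7[1] - truth.dd7[0])
        else:
            metrics["dd7_len_error"] = None
    return metrics
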