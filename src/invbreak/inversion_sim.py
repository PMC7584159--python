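"""Mechanism-aware simulator of paracentric inversion formation.

Generates a desk-scale chromosome (default 30 kb, GC 43.8%) carrying a
planted inversion formed under one of the classic mechanism models, and
emits the four-assembly comparison set (inverted line, two uninverted
lines, outgroup) together with machine-readable ground truth:

- ``NAHR``: recombination between planted inverted repeats; the repeats
  remain at both junctions and in both arrangement states.
- ``CUT_AND_PASTE``: blunt double-strand breaks, clean junctions, no gain
  or loss of sequence.
- ``STAGGERED_ISO`` / ``STAGGERED_CHROMATID``: staggered breaks whose
  filled-in overhangs become inverted duplications at the ends of the
  inverted state only (the two staggering models leave identical
  footprints and are simulated identically).
- ``CHROMOSOME``: repair in trans across the two homologous chromosomes;
  the uninverted lines segregate for a spacer microinversion between long
  inverted repeats, and the inverted line's distal junction is a mosaic of
  the two haplotypes around a central deletion (dd7).
- ``BIR_MMBIR``: as STAGGERED plus a junction filler copied (with one
  mismatch) from a template at the start of the +D flank, leaving a
  microhomology footprint.

The ``complex_proximal`` flag reproduces the published proximal-junction
anatomy: a 2,445-bp insertion present only in the inverted state, opening
with a 153-bp direct repeat of the upstream flank (R1-2), two inverted
duplication pairs d1 (59 bp) and d2 (534/540 bp), a 1,374-bp intervening
sequence, and a 2,026-bp microinversion spanning d1A..d1B.

All randomness comes from a single numpy Generator seeded from the
config; draws happen in a fixed documented order (ancestor, planted
features, inversion-specific content, then divergence for line 1, line 2,
outgroup, inverted line), so identical configs give identical bytes.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seq_model import LabeledSequence, format_report, revcomp, write_fasta

MECHANISMS = ("NAHR", "CUT_AND_PASTE", "STAGGERED_ISO", "STAGGERED_CHROMATID",
              "CHROMOSOME", "BIR_MMBIR")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for one simulated inversion dataset."""

    mechanism: str = "STAGGERED_ISO"
    genome_length: int = 30_000
    gc_content: float = 0.438
    inversion_span: int = 10_000
    # proximal-junction anatomy (complex mode)
    d1_len: int = 59
    d2_len: int = 534
    d2b_len: int = 540
    d2b_novel_len: int = 128
    intervening_len: int = 1374
    r12_len: int = 153
    r12_gap: int = 138          # inter-element spacer inside the insertion
    d2_divergence: float = 0.02  # construction-time divergence of the d2 pair
    complex_proximal: bool = False
    # distal-junction anatomy (chromosome model)
    spacer_len: int = 400
    dd7_len: int = 150
    distal_ir_len: int = 1000
    spacer_haplotypes: tuple[str, str] = ("-", "+")
    # NAHR
    nahr_repeat_len: int = 300
    # BIR/MMBIR filler
    filler: str | int | None = None
    filler_len: int = 21
    microhomology_len: int = 8
    d_flank_motif: str | None = None
    # divergence (substitutions/site, Jukes-Cantor-style, no indels)
    line_divergence: float = 0.01
    outgroup_divergence: float = 0.03
    # non-B bait at the proximal break
    at_rich_break: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0 < self.inversion_span < self.genome_length):
            raise ValueError("inversion_span must lie inside the genome")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be a fraction")
        for name in ("line_divergence", "outgroup_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.2):
                raise ValueError(f"{name} outside [0, 0.2]")
        if self.mechanism == "CHROMOSOME":
            if self.spacer_haplotypes[0] == self.spacer_haplotypes[1]:
                raise ValueError(
                    "CHROMOSOME model needs two opposite spacer haplotypes")
            if self.dd7_len > self.spacer_len // 2:
                raise ValueError("dd7_len must fit in half the spacer")

    @property
    def uses_distal_spacer(self) -> bool:
        return self.mechanism == "CHROMOSOME"


def o7_config(seed: int = 0, **overrides) -> SimConfig:
    """The published-inversion demo: chromosome-model distal junction with
    the 21-nt filler, plus the complex staggered proximal insertion."""
    params = dict(
        mechanism="CHROMOSOME",
        complex_proximal=True,
        filler="GAGCACTCTCCACAGCAAAGT",
        d_flank_motif="CATCAAAG",
        at_rich_break=True,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset (all coordinates 0-based)."""

    mechanism: str
    expected_label: str
    bir_flag: bool
    prox_break_uninv: int
    dist_break_uninv: int
    prox_junction_inv: int
    dist_junction_inv: int
    duplications: list[dict] = field(default_factory=list)
    microinversion: tuple[int, int] | None = None
    dd7: tuple[int, int] | None = None
    filler: str | None = None
    microhomology: tuple[int, int, int] | None = None  # (len, mismatches, gap offset)
    insertion: tuple[int, int] | None = None
    spacer_haplotype: dict = field(default_factory=dict)
    spacer_region_uninv: tuple[int, int] | None = None


@dataclass
class _Layout:
    p: int              # proximal break on the uninverted backbone
    q: int              # distal break on the uninverted backbone
    spacer_start: int | None
    m0: int | None      # break offset within the spacer (= spacer_len // 2)


def _layout(config: SimConfig) -> _Layout:
    p = (config.genome_length - config.inversion_span) // 2
    q = p + config.inversion_span
    if config.uses_distal_spacer:
        m0 = config.spacer_len // 2
        return _Layout(p, q, q - m0, m0)
    return _Layout(p, q, None, None)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site independently with probability ``rate``
    (uniform to one of the three other bases; no indels)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = np.full(arr.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        idx[arr == b] = i
    mask = (rng.random(arr.shape) < rate) & (idx >= 0)
    shifts = rng.integers(1, 4, size=int(mask.sum()))
    new_idx = (idx[mask].astype(np.int64) + shifts) % 4
    arr[mask] = _BASES[new_idx]
    return arr.tobytes().decode()


def _at_rich_cluster(rng: np.random.Generator) -> str:
    """A ~150-bp AT-rich palindromic bait: (ATTT)n simple repeat carrying
    hairpin-capable inverted repeats, an AATAAAT tandem, and a short
    mirror repeat — the motif cocktail seen at fragile breakpoints."""
    parts = [
        "AATTTTAAAATT",              # perfect 6-bp-arm palindrome
        "ATTT" * 6,
        "AATAAAT" * 4,
        "TTAAATAAATTT",              # mirror-symmetric stretch
        "ATTT" * 5,
        "AATTTTAAAATT",
    ]
    s = "".join(parts)
    return s[:150] if len(s) >= 150 else s + _random_seq(rng, 150 - len(s), 0.1)


def simulate_ancestor(config: SimConfig,
                      rng: np.random.Generator | None = None) -> LabeledSequence:
    """The uninverted ancestral backbone with planted features.

    i.i.d. sequence at the requested GC content; plants (per config) the
    NAHR inverted-repeat pair at the future breakpoints, the long inverted
    repeat + spacer at the future distal break, and an AT-rich IR cluster
    at the future proximal break.  Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lay = _layout(config)
    needed = 0
    if config.mechanism == "NAHR":
        needed += 2 * config.nahr_repeat_len
    if config.uses_distal_spacer:
        needed += 2 * config.distal_ir_len + config.spacer_len
    if config.genome_length < config.inversion_span + needed + 4000:
        raise ValueError("genome_length too small for the planted features")
    seq = list(_random_seq(rng, config.genome_length, config.gc_content))

    def plant(start: int, s: str) -> None:
        seq[start:start + len(s)] = list(s)

    if config.at_rich_break:
        cluster = _at_rich_cluster(rng)
        plant(lay.p - len(cluster) // 2, cluster)
    if config.mechanism == "NAHR":
        rep = _random_seq(rng, config.nahr_repeat_len, config.gc_content)
        plant(lay.p - config.nahr_repeat_len, rep)
        plant(lay.q, revcomp(rep))
    if config.uses_distal_spacer:
        arm = _random_seq(rng, config.distal_ir_len, config.gc_content)
        spacer = _random_seq(rng, config.spacer_len, config.gc_content)
        if config.d_flank_motif:
            off = lay.m0 + config.dd7_len
            spacer = (spacer[:off] + config.d_flank_motif
                      + spacer[off + len(config.d_flank_motif):])
        plant(lay.spacer_start - config.distal_ir_len, arm)
        plant(lay.spacer_start, spacer)
        plant(lay.spacer_start + config.spacer_len, revcomp(arm))
    return LabeledSequence("ancestor", "".join(seq))


def _scan_microhomology(gap: str, flank_d: str, max_mismatch: int = 1,
                        min_len: int = 4) -> tuple[int, int, int] | None:
    """Longest substring of ``gap`` matching a window anchored at the start
    of ``flank_d`` with at most ``max_mismatch`` mismatches (no gaps)."""
    best = None
    for length in range(min(len(gap), len(flank_d)), min_len - 1, -1):
        for i in range(len(gap) - length + 1):
            mism = sum(1 for a, b in zip(gap[i:i + length], flank_d[:length])
                       if a != b or a not in "ACGT")
            if mism <= max_mismatch:
                cand = (length, mism, i)
                if best is None or (-cand[0], cand[1], cand[2]) < \
                        (-best[0], best[1], best[2]):
                    best = cand
        if best is not None:
            break
    return best


def apply_mechanism(ancestor: LabeledSequence, config: SimConfig,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[LabeledSequence, list[LabeledSequence],
                               LabeledSequence, SimTruth]:
    """Break-and-repair the ancestor under the configured mechanism.

    Returns ``(inverted_line, [uninverted_1, uninverted_2], outgroup,
    truth)``.  Divergence is applied independently per emitted line after
    the rearrangement, so planted duplication copies are exact (reverse-)
    complements before divergence.
    """
    if rng is None:
        # rebuild the seeded stream and replay the ancestor draws so the
        # stream position matches a fresh ``simulate_ancestor`` call
        rng = np.random.default_rng(config.seed)
        simulate_ancestor(config, rng=rng)
    anc = ancestor.seq
    lay = _layout(config)
    p, q = lay.p, lay.q
    mech = config.mechanism

    # line-1-type backbone: reversed spacer under the chromosome model
    if config.uses_distal_spacer:
        ss = lay.spacer_start
        spacer = anc[ss:ss + config.spacer_len]
        backbone1 = anc[:ss] + revcomp(spacer) + anc[ss + config.spacer_len:]
    else:
        backbone1 = anc

    truth = SimTruth(
        mechanism=mech,
        expected_label="",
        bir_flag=False,
        prox_break_uninv=p,
        dist_break_uninv=q,
        prox_junction_inv=-1,
        dist_junction_inv=-1,
    )

    # ---- proximal side -------------------------------------------------
    dup_records: list[dict] = []
    if config.complex_proximal:
        if mech in ("NAHR", "CUT_AND_PASTE"):
            raise ValueError("complex_proximal requires a staggered or "
                             "chromosome-model mechanism")
        d1 = _random_seq(rng, config.d1_len, config.gc_content)
        novel = _random_seq(rng, config.d2b_novel_len, config.gc_content)
        ivs = _random_seq(rng, config.intervening_len, config.gc_content)
        gap_fill = _random_seq(rng, config.r12_gap, config.gc_content)
        shared_len = config.d2b_len - config.d2b_novel_len
        d2b = novel + anc[p:p + shared_len]
        d2a = _mutate(d2b[:config.d2_len], config.d2_divergence, rng)
        r12 = anc[p - config.r12_len:p]
        ins_a = r12 + gap_fill + d1 + d2a + ivs + revcomp(d1)
        prox_insert = ins_a
        m_prefix = novel
        micro_start = p + config.r12_len + config.r12_gap
        micro_len = (2 * config.d1_len + config.d2_len
                     + config.intervening_len)
        truth.microinversion = (micro_start, micro_start + micro_len)
        truth.insertion = (p, p + len(ins_a))
        d1a_start = micro_start
        d1b_start = micro_start + config.d1_len + config.d2_len + config.intervening_len
        dup_records.append({"name": "d1", "orientation": "inverted",
                            "present_in": "inverted_only",
                            "len": config.d1_len,
                            "inv_a": (d1a_start, d1a_start + config.d1_len),
                            "inv_b": (d1b_start, d1b_start + config.d1_len)})
        d2a_start = micro_start + config.d1_len
        dup_records.append({"name": "d2", "orientation": "direct",
                            "present_in": "inverted_only",
                            "len": config.d2_len,
                            "inv_a": (d2a_start, d2a_start + config.d2_len)})
    elif mech in ("STAGGERED_ISO", "STAGGERED_CHROMATID", "BIR_MMBIR"):
        prox_insert = anc[p:p + config.d1_len]
        m_prefix = ""
        dup_records.append({"name": "dup_prox", "orientation": "inverted",
                            "present_in": "inverted_only",
                            "len": config.d1_len,
                            "uninv": (p, p + config.d1_len)})
    elif mech == "NAHR":
        prox_insert = ""
        m_prefix = ""
        rl = config.nahr_repeat_len
        dup_records.append({"name": "nahr_repeat", "orientation": "inverted",
                            "present_in": "both_states", "len": rl,
                            "uninv": (p - rl, p)})
    else:  # CUT_AND_PASTE, CHROMOSOME proximal side
        prox_insert = ""
        m_prefix = ""

    # ---- distal side ---------------------------------------------------
    filler_seq = ""
    if mech == "CHROMOSOME":
        m_end = q
        d_start = q + config.dd7_len
        truth.dd7 = (q, q + config.dd7_len)
        truth.spacer_haplotype = {"uninverted_1": config.spacer_haplotypes[0],
                                  "uninverted_2": config.spacer_haplotypes[1]}
        truth.spacer_region_uninv = (lay.spacer_start,
                                     lay.spacer_start + config.spacer_len)
    elif mech in ("STAGGERED_ISO", "STAGGERED_CHROMATID", "BIR_MMBIR"):
        m_end = q + config.d2_len
        d_start = q
        dup_records.append({"name": "dup_dist", "orientation": "inverted",
                            "present_in": "inverted_only",
                            "len": config.d2_len,
                            "uninv": (q, q + config.d2_len)})
    else:  # NAHR, CUT_AND_PASTE
        m_end = q
        d_start = q
        if mech == "NAHR":
            rl = config.nahr_repeat_len
            dup_records.append({"name": "nahr_repeat_dist",
                                "orientation": "inverted",
                                "present_in": "both_states", "len": rl,
                                "uninv": (q, q + rl)})

    d_side = anc[d_start:]
    if mech == "BIR_MMBIR" or (mech == "CHROMOSOME" and config.filler):
        if isinstance(config.filler, str):
            filler_seq = config.filler
        else:
            flen = config.filler if isinstance(config.filler, int) else config.filler_len
            mh = config.microhomology_len
            template = d_side[:mh]
            pos = int(rng.integers(0, mh))
            base = template[pos]
            alt = rng.choice([b for b in "ACGT" if b != base])
            mutated = template[:pos] + str(alt) + template[pos + 1:]
            filler_seq = _random_seq(rng, flen - mh, config.gc_content) + mutated

    segment = m_prefix + backbone1[p:m_end]
    inverted = anc[:p] + prox_insert + revcomp(segment) + filler_seq + d_side

    truth.prox_junction_inv = p + len(prox_insert)
    truth.dist_junction_inv = p + len(prox_insert) + len(segment)
    if filler_seq:
        truth.filler = filler_seq
        truth.microhomology = _scan_microhomology(filler_seq, d_side[:40])
        truth.bir_flag = True
    if config.complex_proximal:
        d2b_full_start = truth.dist_junction_inv - config.d2b_len
        dup_records[1]["inv_b"] = (d2b_full_start,
                                   d2b_full_start + config.d2b_len)
    truth.duplications = dup_records

    labels = {
        "NAHR": "NAHR",
        "CUT_AND_PASTE": "NHEJ_CUT_AND_PASTE",
        "STAGGERED_ISO": "NHEJ_STAGGERED",
        "STAGGERED_CHROMATID": "NHEJ_STAGGERED",
        "BIR_MMBIR": "NHEJ_STAGGERED",
        "CHROMOSOME": "CHROMOSOME_MODEL",
    }
    truth.expected_label = labels[mech]
    if mech == "CHROMOSOME" and config.complex_proximal:
        truth.expected_label = "NHEJ_STAGGERED+CHROMOSOME_MODEL"

    line1 = LabeledSequence("uninverted_1",
                            _mutate(backbone1, config.line_divergence, rng))
    line2 = LabeledSequence("uninverted_2",
                            _mutate(anc, config.line_divergence, rng))
    outgroup = LabeledSequence("outgroup",
                               _mutate(anc, config.outgroup_divergence, rng))
    inv = LabeledSequence("inverted",
                          _mutate(inverted, config.line_divergence, rng))
    return inv, [line1, line2], outgroup, truth


def simulate(config: SimConfig) -> tuple[LabeledSequence, list[LabeledSequence],
                                         LabeledSequence, SimTruth]:
    """Convenience wrapper: one seeded stream through ancestor + mechanism."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(config, rng=rng)
    return apply_mechanism(ancestor, config, rng=rng)


def truth_report(truth: SimTruth) -> str:
    rec = {
        "mechanism": truth.mechanism,
        "expected_label": truth.expected_label,
        "bir_flag": truth.bir_flag,
        "prox_break_uninv": truth.prox_break_uninv,
        "dist_break_uninv": truth.dist_break_uninv,
        "prox_junction_inv": truth.prox_junction_inv,
        "dist_junction_inv": truth.dist_junction_inv,
        "microinversion": truth.microinversion,
        "dd7": truth.dd7,
        "filler": truth.filler,
        "microhomology": truth.microhomology,
        "insertion": truth.insertion,
        "spacer_haplotype": truth.spacer_haplotype,
        "n_duplications": len(truth.duplications),
    }
    dup_recs = [{f"dup_{k}": v for k, v in d.items()}
                for d in truth.duplications]
    return format_report("simulation truth", [rec] + dup_recs)


def parse_truth(text: str) -> SimTruth:
    """Parse a truth report written by :func:`truth_report`."""
    import ast

    from .seq_model import parse_report
    records = parse_report(text)
    head = records[0]

    def lit(key):
        v = head.get(key, "None")
        try:
            return ast.literal_eval(v)
        except (ValueError, SyntaxError):
            return v

    truth = SimTruth(
        mechanism=head["mechanism"],
        expected_label=head["expected_label"],
        bir_flag=head["bir_flag"] == "True",
        prox_break_uninv=int(head["prox_break_uninv"]),
        dist_break_uninv=int(head["dist_break_uninv"]),
        prox_junction_inv=int(head["prox_junction_inv"]),
        dist_junction_inv=int(head["dist_junction_inv"]),
        microinversion=lit("microinversion"),
        dd7=lit("dd7"),
        filler=None if head.get("filler") in (None, "None") else head["filler"],
        microhomology=lit("microhomology"),
        insertion=lit("insertion"),
        spacer_haplotype=lit("spacer_haplotype") or {},
    )
    for rec in records[1:]:
        truth.duplications.append(
            {k.removeprefix("dup_"): v for k, v in rec.items()})
    return truth


def emit_dataset(outdir: str | os.PathLike, config: SimConfig,
                 force: bool = False) -> list[Path]:
    """Write the four FASTA files, the truth report, and the resolved
    config.  Refuses a non-empty output directory unless ``force``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    inv, (l1, l2), og, truth = simulate(config)
    paths = []
    for seq, name in ((inv, "inverted"), (l1, "uninverted_1"),
                      (l2, "uninverted_2"), (og, "outgroup")):
        path = outdir / f"{name}.fasta"
        write_fasta([seq], path)
        paths.append(path)
    truth_path = outdir / "truth.txt"
    truth_path.write_text(truth_report(truth))
    paths.append(truth_path)
    config_path = outdir / "config.yaml"
    cfg = dataclasses.asdict(config)
    cfg["spacer_haplotypes"] = list(config.spacer_haplotypes)
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths.append(config_path)
    return paths
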