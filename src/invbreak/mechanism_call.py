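"""Classification of the inversion-formation mechanism from junction
architecture evidence.

The decision table encodes the classic footprints:

- duplications present in both arrangement states -> NAHR between
  inverted repeats;
- no duplications and clean junctions -> NHEJ by blunt cut-and-paste;
- inverted duplications in the inverted state only -> NHEJ after
  staggered breaks (the isochromatid and chromatid variants leave the
  same duplication pattern and are deliberately not distinguished);
- a spacer-haplotype mosaic around a central deletion -> repair in trans
  with the homologous chromosome (chromosome model);
- templated filler / microhomology at a junction adds a BIR/MMBIR-
  compatible flag — replication-based repair can mimic the staggered
  footprint, so this is never emitted as a sole label.

Junctions are classified independently and the labels combined, so mixed
events (e.g. staggered proximal + chromosome-model distal) come out as
composite labels.  The full evidence vector ships with the label so
borderline calls can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .junction_arch import JunctionArchitecture

UNRESOLVED = "UNRESOLVED"


@dataclass
class MechanismCall:
    label: str
    proximal_label: str
    distal_label: str
    bir_mmbir_compatible: bool
    evidence: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def _junction_label(dup_states: list[str], has_inverted_only_dups: bool,
                    clean: bool, mosaic: bool, central_deletion: bool,
                    insertion: bool) -> str:
    if mosaic and central_deletion:
        return "CHROMOSOME_MODEL"
    if "both_states" in dup_states:
        return "NAHR"
    if has_inverted_only_dups:
        return "NHEJ_STAGGERED"
    if clean:
        return "NHEJ_CUT_AND_PASTE"
    if insertion:
        return "NHEJ_STAGGERED"
    return UNRESOLVED


def classify(architecture: JunctionArchitecture | None,
             nonb_hits: list | None = None,
             clean_tolerance: int = 20,
             min_unassigned: int = 40) -> MechanismCall:
    """Apply the mechanism decision table to a junction architecture.

    ``clean_tolerance`` is the largest segment-projection overlap (bp)
    still treated as a blunt junction; ``min_unassigned`` the smallest
    unassigned stretch treated as a structural insertion rather than
    demarcation slop.  An empty architecture gives ``UNRESOLVED``.
    """
    if architecture is None:
        return MechanismCall(UNRESOLVED, UNRESOLVED, UNRESOLVED, False)
    arch = architecture

    def dup_side(name_prefix: str, nahr_min_len: int = 50) -> tuple[list[str], bool]:
        states, inv_only = [], False
        for d in arch.duplications:
            at_side = d.name.startswith(name_prefix) or (
                name_prefix == "prox" and not d.name.startswith("dist"))
            if not at_side or d.present_in == "ambiguous":
                continue
            if d.present_in == "both_states" and len(d.copy_a) < nahr_min_len:
                # ectopic recombination needs substantial homology; a short
                # repeated motif in both states is not an NAHR footprint
                continue
            states.append(d.present_in)
            if d.present_in == "inverted_only" and d.orientation == "inverted":
                inv_only = True
        return states, inv_only

    prox_states, prox_inv_only = dup_side("prox")
    dist_states, dist_inv_only = dup_side("dist")

    mosaic = bool(arch.mosaic and arch.mosaic.mosaic)
    deletion = bool(arch.mosaic and arch.mosaic.central_deletion_len > 0)
    prox_clean = (abs(arch.prox_overlap) <= clean_tolerance
                  and arch.prox_unassigned < min_unassigned)
    dist_clean = (abs(arch.dist_overlap) <= clean_tolerance
                  and arch.dist_unassigned < min_unassigned)
    prox_insertion = arch.prox_unassigned >= min_unassigned
    dist_insertion = arch.dist_unassigned >= min_unassigned

    prox_label = _junction_label(prox_states, prox_inv_only
                                 or (arch.microinversion is not None),
                                 prox_clean, False, False, prox_insertion)
    dist_label = _junction_label(dist_states, dist_inv_only, dist_clean,
                                 mosaic, deletion, dist_insertion)

    bir = bool(arch.microhomology and arch.microhomology.length >= 4)

    labels = [lab for lab in (prox_label, dist_label) if lab != UNRESOLVED]
    if not labels or not arch.resolved:
        label = UNRESOLVED
    else:
        distinct = []
        for lab in labels:
            if lab not in distinct:
                distinct.append(lab)
        informative = [lab for lab in distinct if lab != "NHEJ_CUT_AND_PASTE"]
        if not informative:
            label = "NHEJ_CUT_AND_PASTE"
        elif len(informative) == 1:
            label = informative[0]
        else:
            # composite label in proximal-then-distal order
            label = "+".join(informative)

    evidence = {
        "dups_both_states": "both_states" in prox_states + dist_states,
        "inverted_dups_inverted_only": prox_inv_only or dist_inv_only,
        "clean_junctions": prox_clean and dist_clean,
        "mosaic_spacer": mosaic,
        "central_deletion": deletion,
        "microhomology_filler": bir,
        "multibreak": arch.microinversion is not None,
        "nonb_at_breaks": bool(nonb_hits),
        "prox_overlap": arch.prox_overlap,
        "dist_overlap": arch.dist_overlap,
        "prox_unassigned": arch.prox_unassigned,
        "dist_unassigned": arch.dist_unassigned,
    }
    notes = []
    if "NHEJ_STAGGERED" in (prox_label, dist_label):
        notes.append("isochromatid and chromatid staggering are "
                     "indistinguishable from the duplication pattern")
    if bir:
        notes.append("microhomology-templated filler: footprints compatible "
                     "with BIR/MMBIR repair rather than staggered breakage")
    if arch.microinversion_conflict:
        notes.append("conflicting microinversion layouts; none auto-selected")
    return MechanismCall(label, prox_label, dist_label, bir, evidence, notes)
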