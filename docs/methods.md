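# Methods

`invbreak` reconstructs how a paracentric chromosomal inversion formed,
from nothing but assembled sequences of the inverted state, two or more
uninverted lines, and an outgroup. This note records the models, the
defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic benchmark demonstrates.

## The inference problem

Write the uninverted arrangement as `+A|+B ... +C|+D` and the inverted
one as `+A|-C ... -B|+D` (letters are the flanking segments, bars the
breakpoint junctions, signs the orientation). Each formation mechanism
leaves a distinctive sequence footprint at the junctions:

| mechanism | footprint |
|---|---|
| NAHR between inverted repeats | the repeat pair is present at both junctions **and in both arrangement states** |
| NHEJ, blunt cut-and-paste | clean junctions; no sequence gained or lost |
| NHEJ, staggered breaks (isochromatid or chromatid) | the filled-in overhangs become **inverted duplications in the inverted state only** |
| chromosome model (repair in trans) | the inverted junction is a **mosaic of the two homologous haplotypes** around a central deletion |
| BIR/MMBIR (replication-based repair) | junction **filler DNA with short templated microhomology** to the +D flank; mimics the staggered footprint |

The two staggering variants leave identical duplication patterns and are
never reported as distinct labels. BIR/MMBIR is reported as a
compatibility *flag*, never a sole label, because the staggered-break and
replication-repair interpretations of the same footprint cannot be
separated by sequence alone.

## Inference chain

1. **Interrupted synteny** (`synteny_scan`). Anchors are exact k-mers
   (default k = 15) unique in the target, matched in both orientations
   and chained greedily into colinear blocks (gap ceiling 2,000 bp, at
   least 3 anchors). An inversion candidate is a `-` block bracketed by
   `+` blocks; the unanchored gaps between blocks are the breakpoint
   regions. Unique-k-mer anchoring makes repeat-rich breakpoints anchor
   deserts bounded by unique flanks, which is exactly where the
   junctions are expected.
2. **Junction demarcation** (`junction_map`). Each inverted-state
   junction window is compared against the two uninverted flanks that
   should meet there. Flank support is an anchor run on the diagonal
   implied by the candidate (k = 13, tolerance 100 bp, modal diagonal
   within the band), extended base by base toward the junction; the
   extension steps over isolated substitutions (continuing while at
   least 4 of the next 6 bases match) and stops at non-homologous
   sequence. Support overlap is duplicated sequence, a support gap is
   unassigned sequence (insertion or filler), and the junction is the
   midpoint of the transition, reported as an interval when the zone
   exceeds 10 bp. A second pass compares unassigned sequence against
   itself, the other unassigned intervals, and the segments (both
   orientations, k = 11 seeds) to recover duplication copies missed in
   the first round.
3. **Architecture** (`junction_arch`). Duplication pairs get an
   orientation, an identity (gap columns excluded, the field's
   convention), and a `present_in` state decided by counting
   non-overlapping approximate occurrences (edlib, 15% distance budget)
   of the copy in the uninverted assemblies — one occurrence means the
   duplication is inversion-specific, two mean both states carry it.
   Low-complexity copies (simple-repeat k-mer vocabulary) are flagged
   and excluded from mechanism evidence. A microinversion is called when
   an inverted pair brackets a further duplication copy; its span runs
   from the first base of the upstream copy to the last base of the
   downstream copy, fill-in copies inclusive — the convention that
   reproduces a 2,026-bp span from components 59 + 534 + 1,374 + 59.
   Mosaicism is tested by comparing junction support across uninverted
   lines: the upstream and downstream junction halves must assign to
   *different* lines with support margins of at least 30 bp and an
   identity gap of at least 20 points; the central deletion is measured
   on the downstream line after mapping the upstream line's homology end
   through the reverse-complement correspondence of the two haplotypes.
   Filler microhomology is the longest gapless match between the
   junction gap and a window anchored at the start of the +D flank
   (minimum 4 bp, at most 1 mismatch).
4. **Classification** (`mechanism_call`). The decision table above is
   applied per junction and the labels combined, so mixed events come
   out composite (e.g. `NHEJ_STAGGERED+CHROMOSOME_MODEL`). A
   `both_states` duplication only counts as NAHR evidence at >= 50 bp of
   copy length: ectopic recombination needs substantial homology, and
   short palindromic motifs recur in both states by chance. The full
   evidence vector ships with the label.

## Synthetic data

The simulator is the benchmark's ground-truth generator, not a toy: it
plants one inversion per dataset under an explicit mechanism and emits
the four-assembly comparison set plus machine-readable truth.

Defaults (one choice, applied throughout): 30-kb chromosome, GC 43.8%
(the studied region's composition), 10-kb inversion, line divergence 1%
per line and 3% for the outgroup (i.i.d. substitutions, no indels —
pairwise line identities ~98% and duplication-copy identities ~98%,
matching the reported values for the real junction copies), NAHR repeat
arms 300 bp, distal inverted-repeat arms 1,000 bp flanking a 400-bp
spacer whose central 150 bp are deleted under the chromosome model
(giving a 250-bp inverted-state spacer against ~400-bp uninverted ones).
The complex proximal insertion reproduces the published anatomy exactly:
a 153-bp direct repeat of the upstream flank, a 138-bp spacer, inverted
duplications d1 (59/59 bp) and d2 (534/540 bp, 128 bp of the B copy
being insertion-specific), a 1,374-bp intervening sequence — 2,317 bp on
the +A side of a 2,445-bp insertion present only in the inverted state —
and an optional 21-nt junction filler copied with one mismatch from the
+D start. All randomness flows from a single seeded generator in a
documented draw order, so identical configs give identical bytes.

What the simulator does **not** emulate: indel divergence (optional but
off by default; the inference chain's diagonal bookkeeping assumes
substitution-only divergence at desk scale), transposable-element
insertion dynamics, segregating polymorphism within lines, assembly
error, and megabase genome scale. Passing benchmarks therefore show that
the footprint logic is recovered under clean assemblies and modest
divergence — not that the pipeline is robust to assembly artifacts or
deep divergence.

## Estimator precision

A base adjacent to a junction that happens to match the other flank
(probability ~1/4 per base, more in biased composition) cannot be
attributed by any method; junction boundaries therefore carry an
intrinsic +/- 1-2 bp ambiguity, which compounds in derived quantities
that difference two boundaries. Measured under the default conditions:
clean-junction positions are exact in nearly all runs (a two-flank
parsimony fit resolves blunt junctions to the base), fill-in duplication
lengths are within +/- 5 bp (usually +/- 2), the microinversion span is
within +/- 2 bp in most runs, and the central-deletion (dd7) length is
within +/- 2 bp in ~85% and +/- 5 bp in ~95% of runs. Mechanism labels are robust to this slop:
recovery is 100/100 per mechanism in the benchmark, with BIR-flag
sensitivity ~95% and no false flags observed.

## Non-B DNA scans

Inverted and mirror repeats are enumerated maximally (arms 6-20 nt,
spacer <= 10 nt for IRs and <= 50 for mirrors, <= 1 mismatch, arm tips
must pair); nested and overlapping motifs are retained — dense clusters
are the fragility signal. Cruciform propensity is scored as the stem's
nearest-neighbor stacking free energy recovered on intrastrand annealing
minus a logarithmic loop penalty (packaged table
`data/stacking_dg.tsv`, overridable); only rank order is meaningful, as
published absolute values depend on unpublished tool parameters. Tandem
repeats use period-wise self-comparison with fractional copy number
(span/period) and per-phase majority consensus; Z-DNA tracts are maximal
purine-pyrimidine alternations >= 12 bp with GC-step weighting; G4
motifs follow `G{3,}(N1-7 G{3,}){3}` on both strands; A-phased repeats
need >= 3 A/T tracts (3-9 bp) at helical spacing (10 +/- 1 bp).

## PWM scanning

Log-odds scanning of both strands with exact p-values: per-position
scores are discretized at 0.01 log-odds units and the null score
distribution is built by convolution under a 0-order background
(estimated from the scanned sequence unless supplied). Window scores are
accumulated on the same discrete grid, so `P(p <= alpha) <= alpha` holds
exactly and the empirical hit rate on i.i.d. background matches the
cutoff to binomial tolerance. No multiple-testing correction is applied
(a raw cutoff is this analysis design's convention); hit counts are
reported so users can correct as they see fit. TSSs are inputs (GFF3),
never predicted.

## Molecular-evolution statistics

Identity excluding indels is matches/(matches+mismatches) over columns
where neither sequence gaps. Tajima's relative-rate test counts sites
uniquely derived in each of two lineages against an outgroup
(gap-free, unambiguous columns only) and refers `(m1-m2)^2/(m1+m2)` to
chi-square with 1 df; its null p-values are uniform to KS tolerance.
The effective number of codons uses Wright's estimator with the
small-sample homozygosity correction, `Nc = 2 + 9/F2 + 1/F3 + 5/F4 +
3/F6`, degeneracy-class means over observed families, class-mean
imputation for unobserved families, clamped to [20, 61]. Published Nc
values for the real genes are not reproduction targets: they depend on
accession data and on an "improved" estimator variant whose exact
formula the source does not print. The concerted-evolution test is
ordinal: `concerted` when every within-species paralog distance is
below every cross-species distance, `escaped` when a designated
relocated copy is farther from all others than its stay-in-place
partner, `undetermined` otherwise.

## Not reproducible at desk scale

Genome-assembly statistics, the real inversion's 9,936,431-bp length and
gene counts, the printed junction identity percentages, Nc = 51.2/50.7,
and the cruciform scores 2.64/2.05 all require the original assemblies
and/or an external tool's unpublished energy table. They are documented
here as non-targets; the package reproduces the junction-level worked
examples (the 14-bp palindrome; the 21-nt filler with its 8-bp, one-
mismatch microhomology; the 2,026-bp microinversion arithmetic) and the
mechanism-recovery benchmark instead.
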