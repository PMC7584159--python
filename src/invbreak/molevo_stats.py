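"""Small molecular-evolution statistics for breakpoint-region genes.

Identity excluding indels, Tajima's relative-rate test, the effective
number of codons (Nc), and a qualitative concerted-evolution pattern test
on a paralog/ortholog distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .seq_model import revcomp  # noqa: F401  (re-exported convenience)

GAP_CHARS = frozenset("-.")
_UNAMBIGUOUS = frozenset("ACGT")

# standard genetic code, DNA codons
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# synonymous families: amino acid + serine split kept as one 6-fold family
_FAMILIES: dict[str, list[str]] = {}
for codon, aa in CODON_TABLE.items():
    if aa == "*":
        continue
    _FAMILIES.setdefault(aa, []).append(codon)


@dataclass
class RateTestResult:
    """Tajima relative-rate test: counts of uniquely derived sites."""

    m1: int
    m2: int
    chi2: float
    p: float


@dataclass
class CodonUsageStat:
    nc: float
    family_f: dict = field(default_factory=dict)


def identity_excluding_indels(x_aln: str, y_aln: str) -> float | None:
    """Fraction of matching columns among columns where neither sequence is
    gapped.  Returns ``None`` when no such column exists."""
    if len(x_aln) != len(y_aln):
        raise ValueError("aligned sequences differ in length")
    matches = 0
    total = 0
    for a, b in zip(x_aln.upper(), y_aln.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        total += 1
        if a == b:
            matches += 1
    if total == 0:
        return None
    return matches / total


def tajima_rrt(seq1: str, seq2: str, outgroup: str) -> RateTestResult:
    """Tajima's relative-rate test on three aligned sequences.

    Uses only columns where all three sequences carry unambiguous bases.
    ``m1`` counts sites where seq1 differs from both seq2 and the outgroup
    (uniquely derived in lineage 1); ``m2`` likewise for seq2.  Under rate
    equality m1 and m2 are exchangeable and
    ``chi2 = (m1-m2)^2 / (m1+m2)`` has 1 df.
    """
    if not (len(seq1) == len(seq2) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    m1 = m2 = used = 0
    for a, b, c in zip(seq1.upper(), seq2.upper(), outgroup.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS or c not in _UNAMBIGUOUS:
            continue
        used += 1
        if a != b:
            if b == c:
                m1 += 1
            elif a == c:
                m2 += 1
    if used == 0:
        raise ValueError("no gap-free unambiguous columns shared by all three")
    if m1 + m2 == 0:
        return RateTestResult(0, 0, 0.0, 1.0)
    stat = (m1 - m2) ** 2 / (m1 + m2)
    return RateTestResult(m1, m2, stat, float(chi2.sf(stat, df=1)))


def _family_homozygosity(counts: dict[str, int]) -> float | None:
    """Wright's codon homozygosity with the small-sample correction:
    F = (n * sum(p_i^2) - 1) / (n - 1)."""
    n = sum(counts.values())
    if n <= 1:
        return None
    s = sum((c / n) ** 2 for c in counts.values())
    return (n * s - 1) / (n - 1)


def effective_number_of_codons(cds: str) -> CodonUsageStat:
    """Effective number of codons (Nc) of a coding sequence.

    Wright's estimator: per synonymous family the codon homozygosity F is
    computed from observed frequencies with the small-sample correction;
    Nc sums the harmonic contributions of the degeneracy classes::

        Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

    with class means taken over the families observed in the sequence.
    Families without observations (or with a single codon) are imputed
    from their degeneracy-class mean; an entirely missing class falls back
    on the neighboring classes' mean.  The result is clamped to [20, 61].
    Internal stop codons raise an error naming the codon position.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    counts: dict[str, dict[str, int]] = {aa: {} for aa in _FAMILIES}
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i:3 * i + 3]
        aa = CODON_TABLE.get(codon)
        if aa is None:
            continue  # ambiguous bases: codon skipped
        if aa == "*":
            if i < n_codons - 1:
                raise ValueError(f"internal stop codon at codon {i + 1}")
            continue
        counts[aa][codon] = counts[aa].get(codon, 0) + 1

    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    family_f: dict[str, float | None] = {}
    for aa, codons in _FAMILIES.items():
        deg = len(codons)
        if deg == 1:
            continue
        f = _family_homozygosity(counts[aa]) if counts[aa] else None
        family_f[aa] = f
        if f is not None and f > 0:
            by_class[deg].append(f)

    n_families = {2: 9, 3: 1, 4: 5, 6: 3}
    total = 2.0  # Met + Trp
    class_means = {deg: (float(np.mean(v)) if v else None)
                   for deg, v in by_class.items()}
    fallback = [m for m in class_means.values() if m is not None]
    for deg, k in n_families.items():
        mean_f = class_means[deg]
        if mean_f is None:
            if not fallback:
                raise ValueError("no codon family with enough observations")
            mean_f = float(np.mean(fallback))
        total += k / mean_f
    nc = min(61.0, max(20.0, total))
    return CodonUsageStat(nc=nc, family_f=family_f)


def concerted_pattern(dist: np.ndarray, species: list[str],
                      relocated: str | None = None) -> str:
    """Classify a paralog/ortholog distance pattern.

    ``dist`` is a symmetric matrix over gene copies, ``species[i]`` names
    the species of copy i (paralogs share a species label).  Returns:

    - ``"concerted"`` if every within-species paralog distance is strictly
      smaller than every cross-species distance (the homogenization
      signature);
    - ``"escaped"`` if the copy named by ``relocated`` (matrix label index)
      is farther from every other copy than its within-species partner is
      (the relocated-paralog acceleration signature);
    - ``"undetermined"`` on ties or mixed patterns.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or len(species) != n:
        raise ValueError("distance matrix and species labels disagree")
    within = [dist[i, j] for i in range(n) for j in range(i + 1, n)
              if species[i] == species[j]]
    across = [dist[i, j] for i in range(n) for j in range(i + 1, n)
              if species[i] != species[j]]
    if within and across and max(within) < min(across):
        return "concerted"
    if relocated is not None:
        r = int(relocated) if not isinstance(relocated, int) else relocated
        partners = [i for i in range(n) if i != r and species[i] == species[r]]
        if partners:
            p = partners[0]
            others = [i for i in range(n) if i not in (r, p)]
            if others and all(dist[r, i] > dist[p, i] for i in others):
                return "escaped"
    return "undetermined"
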