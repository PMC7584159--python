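"""Core sequence data model, coordinate conventions, and plain-text I/O.

All coordinates are 0-based half-open internally.  BED6 is used for interval
output; 1-based inclusive coordinates appear only in human-readable reports
and are flagged as such there.  ``N`` is a legal base: it never matches in
exact-match scanners and scores as a mismatch in aligners.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTNRYSWKMBDHV")
_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHV",
    "TGCANYRSWMKVHDB",
)


class SequenceError(ValueError):
    """Raised on malformed sequence input (bad alphabet, duplicate ids...)."""


@dataclass
class LabeledSequence:
    """A named DNA string with its offset on a parent coordinate system.

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        DNA over the IUPAC alphabet, stored uppercase.
    offset : int
        0-based start of this slice on its parent sequence (bp).
    """

    id: str
    seq: str
    offset: int = 0

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.offset < 0:
            raise SequenceError(f"record {self.id!r}: negative offset")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise SequenceError(
                f"record {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> "LabeledSequence":
        """Sub-sequence with the offset tracking the parent coordinates."""
        start = max(0, start)
        end = min(len(self.seq), end)
        return LabeledSequence(self.id, self.seq[start:end], self.offset + start)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def revcomp(s: str) -> str:
    """Reverse complement of a DNA string; ``N`` maps to ``N``.

    Raises :class:`SequenceError` on non-IUPAC characters.
    """
    s = s.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceError(f"cannot reverse-complement characters {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[LabeledSequence]:
    """Read a multi-record FASTA into :class:`LabeledSequence` objects.

    Order is preserved; sequences are uppercased.  Empty files, duplicate ids
    and non-nucleotide characters raise :class:`SequenceError` naming the
    offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list[LabeledSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(LabeledSequence(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[LabeledSequence], path: str | os.PathLike,
                width: int = 70) -> None:
    """Write records as FASTA; byte-stable for identical input."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike,
              names: Iterable[str] | None = None) -> None:
    """Write intervals as BED6 (0-based half-open, strand in column 6)."""
    intervals = list(intervals)
    if names is None:
        names = ["." for _ in intervals]
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names, strict=True):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def format_report(title: str, records: list[dict]) -> str:
    """Render a structured key-value text report (one block per record).

    Deterministic: keys are emitted in insertion order, records in list
    order, so identical inputs give identical bytes.
    """
    lines = [f"# {title}"]
    for i, rec in enumerate(records):
        lines.append(f"[record {i}]")
        for key, value in rec.items():
            lines.append(f"{key}\t{value}")
    return "\n".join(lines) + "\n"


def write_report(title: str, records: list[dict], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(format_report(title, records))


def parse_report(text: str) -> list[dict]:
    """Inverse of :func:`format_report` (values come back as strings)."""
    records: list[dict] = []
    current: dict | None = None
    for line in text.splitlines():
        if line.startswith("#") or not line.strip():
            continue
        if line.startswith("[record"):
            current = {}
            records.append(current)
            continue
        if current is None:
            raise ValueError("malformed report: data before first record header")
        key, _, value = line.partition("\t")
        current[key] = value
    return records
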