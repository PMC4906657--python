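"""FASTA and Blasr ``-m 5`` alignment I/O.

The consensus engine consumes two kinds of input: plain FASTA sequences
(the draft backbone being polished and the query reads) and pairwise
alignments in the 19-column whitespace-delimited format that Blasr emits
with ``-m 5``.  Both are plain text; the M5 writer is bit-exact
(single-space separators, no trailing whitespace) so files round-trip.

Coordinate conventions, stated once and followed everywhere:

* all coordinates are 0-based, half-open ``[start, end)``;
* the target strand is always ``'+'`` (records with ``tStrand == '-'``
  are rejected at parse time);
* for ``qStrand == '-'`` records the gapped strings are stored in
  target-forward orientation (i.e. the query segment was
  reverse-complemented before alignment, exactly as Blasr does) and
  ``qStart``/``qEnd`` refer to the reverse-complemented query.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "SequenceRecord",
    "M5Record",
    "read_fasta",
    "write_fasta",
    "parse_m5",
    "write_m5",
    "best_hit_filter",
    "revcomp",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return sequence.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated the FASTA or M5 format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercase-normalized.

    ``name`` is the first whitespace-delimited token of the FASTA header.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name or any(ch.isspace() for ch in self.name):
            raise FormatError(f"invalid sequence name: {self.name!r}")
        if not self.sequence:
            raise FormatError(f"record {self.name!r} has an empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.name!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str) -> str:
    """Uppercase and map any non-ACGT letter (IUPAC ambiguity etc.) to N."""
    seq = seq.upper()
    if set(seq) <= _VALID_BASES:
        return seq
    return "".join(ch if ch in _VALID_BASES else "N" for ch in seq)


def read_fasta(path: os.PathLike | str) -> List[SequenceRecord]:
    """Read a (multi-line) FASTA file into ``SequenceRecord`` objects.

    Sequences are uppercased and non-ACGTN letters become N; record order
    is preserved.  A record with an empty sequence raises :class:`FormatError`
    naming the offending header.
    """
    with open(path) as handle:
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = _normalize(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(SequenceRecord(name=rec.id, sequence=seq))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    path: os.PathLike | str,
    line_width: int = 80,
) -> None:
    """Write records as standard FASTA wrapped at ``line_width`` columns."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    bio_records = [
        _BioSeqRecord(Seq(r.sequence), id=r.name, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=line_width)
        writer.write_file(bio_records)


@dataclass
class M5Record:
    """One pairwise alignment in Blasr ``-m 5`` form.

    The 19 fields appear in Blasr's column order.  The counting fields
    (numMatch etc.) are carried but not validated against the gapped
    strings: real-world files are inconsistent, and the consensus engine
    recomputes whatever it needs from ``matchPattern``.
    """

    qName: str
    qLength: int
    qStart: int
    qEnd: int
    qStrand: str
    tName: str
    tLength: int
    tStart: int
    tEnd: int
    tStrand: str
    score: int
    numMatch: int
    numMismatch: int
    numIns: int
    numDel: int
    mapQV: int
    qAlignedSeq: str
    matchPattern: str
    tAlignedSeq: str

    def validate(self, where: str = "") -> None:
        """Raise :class:`FormatError` unless every structural invariant holds."""
        ctx = f"{where}: " if where else ""
        if not (
            len(self.qAlignedSeq) == len(self.matchPattern) == len(self.tAlignedSeq)
        ):
            raise FormatError(f"{ctx}gapped strings have mismatched lengths")
        if self.qStrand not in "+-" or self.tStrand not in "+-":
            raise FormatError(f"{ctx}unknown strand symbol")
        if not (0 <= self.qStart < self.qEnd <= self.qLength):
            raise FormatError(f"{ctx}bad query coordinates")
        if not (0 <= self.tStart < self.tEnd <= self.tLength):
            raise FormatError(f"{ctx}bad target coordinates")
        if len(self.qAlignedSeq.replace("-", "")) != self.qEnd - self.qStart:
            raise FormatError(f"{ctx}qAlignedSeq length disagrees with qStart/qEnd")
        if len(self.tAlignedSeq.replace("-", "")) != self.tEnd - self.tStart:
            raise FormatError(f"{ctx}tAlignedSeq length disagrees with tStart/tEnd")
        for q, t in zip(self.qAlignedSeq, self.tAlignedSeq):
            if q == "-" and t == "-":
                raise FormatError(f"{ctx}column with a gap in both sequences")

    def recomputed_matches(self) -> int:
        """Match count taken from the pattern, not the numMatch field."""
        return self.matchPattern.count("|")


_M5_INT_FIELDS = {1, 2, 3, 6, 7, 8, 10, 11, 12, 13, 14, 15}


def parse_m5(path: os.PathLike | str) -> List[M5Record]:
    """Parse a Blasr ``-m 5`` file; malformed lines raise with line numbers."""
    records: List[M5Record] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 19:
                raise FormatError(
                    f"{path}:{lineno}: expected 19 fields, found {len(fields)}"
                )
            values: list = []
            for idx, raw in enumerate(fields):
                if idx in _M5_INT_FIELDS:
                    try:
                        values.append(int(raw))
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: field {idx + 1} is not an integer"
                        ) from None
                else:
                    values.append(raw)
            rec = M5Record(*values)
            if rec.tStrand == "-":
                raise FormatError(
                    f"{path}:{lineno}: tStrand '-' is not supported; "
                    "targets must be forward-oriented"
                )
            rec.qAlignedSeq = _normalize_gapped(rec.qAlignedSeq)
            rec.tAlignedSeq = _normalize_gapped(rec.tAlignedSeq)
            rec.validate(where=f"{path}:{lineno}")
            records.append(rec)
    return records


def _normalize_gapped(seq: str) -> str:
    seq = seq.upper()
    return "".join(ch if ch in _VALID_BASES or ch == "-" else "N" for ch in seq)


def write_m5(records: Iterable[M5Record], path: os.PathLike | str) -> None:
    """Write records in the 19-column M5 dialect, bit-exact."""
    with open(path, "w") as handle:
        for r in records:
            handle.write(
                f"{r.qName} {r.qLength} {r.qStart} {r.qEnd} {r.qStrand} "
                f"{r.tName} {r.tLength} {r.tStart} {r.tEnd} {r.tStrand} "
                f"{r.score} {r.numMatch} {r.numMismatch} {r.numIns} {r.numDel} "
                f"{r.mapQV} {r.qAlignedSeq} {r.matchPattern} {r.tAlignedSeq}\n"
            )


def best_hit_filter(alignments: Sequence[M5Record]) -> List[M5Record]:
    """Keep one best placement per query name.

    Ranking key: most matches recomputed from the pattern, then the lower
    (Blasr-style, negative-is-better) score field, then first occurrence.
    The output is ordered by ``tStart`` ascending.
    """
    best: dict = {}
    for idx, rec in enumerate(alignments):
        key = (-rec.recomputed_matches(), rec.score, idx)
        prev = best.get(rec.qName)
        if prev is None or key < prev[0]:
            best[rec.qName] = (key, rec)
    kept = [rec for _, rec in best.values()]
    kept.sort(key=lambda r: r.tStart)
    return kept
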