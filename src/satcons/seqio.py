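"""Streaming readers/writers for the plain-text formats the pipeline touches.

FASTA and FASTQ parsing is line-based and streaming: records are yielded one
at a time (constant working set per record) and malformed input raises
:class:`ParseError` naming the offending line.  BED6 is the single interval
dialect used throughout; the score column carries per-interval metadata such
as alignment noise or identity where relevant.  Tabular reports go through
pandas as TSV with ``.`` for missing values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

__all__ = [
    "SequenceRecord",
    "IntervalRecord",
    "ParseError",
    "AlphabetError",
    "read_sequences",
    "write_sequences",
    "read_intervals",
    "write_intervals",
    "read_table",
    "write_table",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_CHARS = frozenset("ACGTN")
_QUAL_OFFSET = 33
_DEFAULT_QUAL = 40  # constant Q for simulated reads


class ParseError(ValueError):
    """Malformed FASTA/FASTQ/BED input; the message names the line number."""


class AlphabetError(ValueError):
    """Sequence contains characters outside the ACGTN alphabet."""


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base integer qualities."""

    id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(order=True)
class IntervalRecord:
    """A BED6-style half-open interval on a named sequence."""

    sequence_id: str
    start: int
    end: int
    label: str = field(default=".", compare=False)
    score: float = field(default=0.0, compare=False)
    strand: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"interval {self.sequence_id}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an ACGTN sequence (involution; N maps to N)."""
    if not _VALID_CHARS.issuperset(sequence):
        bad = sorted(set(sequence) - _VALID_CHARS)
        raise AlphabetError(f"non-ACGTN characters: {bad}")
    return sequence.translate(_COMPLEMENT)[::-1]


def _check_sequence(seq: str, where: str) -> str:
    seq = seq.upper()
    if not _VALID_CHARS.issuperset(seq):
        bad = sorted(set(seq) - _VALID_CHARS)
        raise ParseError(f"{where}: non-ACGTN characters {bad}")
    return seq


def _infer_format(path: str) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".fa", ".fasta", ".fna"):
        return "fasta"
    if ext in (".fq", ".fastq"):
        return "fastq"
    raise ValueError(f"cannot infer sequence format from {path!r}")


def _read_fasta(handle, path: str) -> Iterator[SequenceRecord]:
    name: Optional[str] = None
    chunks: list[str] = []
    header_line = 0
    lineno = 0
    for lineno, line in enumerate(handle, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                if not chunks:
                    raise ParseError(f"{path}:{header_line}: record {name!r} has no sequence")
                yield SequenceRecord(name, "".join(chunks))
            name = line[1:].split()[0] if len(line) > 1 else ""
            if not name:
                raise ParseError(f"{path}:{lineno}: empty FASTA header")
            chunks, header_line = [], lineno
        else:
            if name is None:
                raise ParseError(f"{path}:{lineno}: sequence data before any '>' header")
            chunks.append(_check_sequence(line, f"{path}:{lineno}"))
    if name is not None:
        if not chunks:
            raise ParseError(f"{path}:{header_line}: record {name!r} has no sequence")
        yield SequenceRecord(name, "".join(chunks))


def _read_fastq(handle, path: str) -> Iterator[SequenceRecord]:
    lineno = 0
    it = iter(handle)
    while True:
        try:
            head = next(it)
        except StopIteration:
            return
        lineno += 1
        head = head.rstrip("\n")
        if not head:
            continue
        if not head.startswith("@"):
            raise ParseError(f"{path}:{lineno}: expected '@' FASTQ header, got {head[:20]!r}")
        name = head[1:].split()[0]
        if not name:
            raise ParseError(f"{path}:{lineno}: empty FASTQ header")
        try:
            seq = next(it).rstrip("\n")
            lineno += 1
            plus = next(it).rstrip("\n")
            lineno += 1
            qual = next(it).rstrip("\n")
            lineno += 1
        except StopIteration:
            raise ParseError(f"{path}:{lineno}: truncated FASTQ record {name!r}") from None
        if not plus.startswith("+"):
            raise ParseError(f"{path}:{lineno - 1}: expected '+' separator")
        if len(qual) != len(seq):
            raise ParseError(
                f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
            )
        yield SequenceRecord(
            name,
            _check_sequence(seq, f"{path}:{lineno - 2}"),
            [ord(c) - _QUAL_OFFSET for c in qual],
        )


def read_sequences(path, format: Optional[str] = None) -> Iterator[SequenceRecord]:
    """Stream :class:`SequenceRecord` objects from a FASTA or FASTQ file.

    ``format`` is ``"fasta"`` or ``"fastq"``; inferred from the extension
    when omitted.  Lowercase bases are folded to uppercase.
    """
    fmt = format or _infer_format(path)
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")
    with open(path) as handle:
        reader = _read_fasta if fmt == "fasta" else _read_fastq
        yield from reader(handle, str(path))


def write_sequences(
    path,
    records: Iterable[SequenceRecord],
    format: Optional[str] = None,
    wrap: int = 60,
) -> int:
    """Write records as FASTA or FASTQ; returns the number written.

    FASTQ qualities use Sanger offset 33; records lacking qualities get a
    constant Q40.
    """
    fmt = format or _infer_format(path)
    n = 0
    with open(path, "w") as out:
        for rec in records:
            if fmt == "fasta":
                out.write(f">{rec.id}\n")
                for i in range(0, len(rec.sequence), wrap):
                    out.write(rec.sequence[i : i + wrap] + "\n")
            else:
                qual = rec.quality or [_DEFAULT_QUAL] * len(rec.sequence)
                qstr = "".join(chr(q + _QUAL_OFFSET) for q in qual)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")
            n += 1
    return n


def read_intervals(path) -> list[IntervalRecord]:
    """Read a BED6 file into a list of :class:`IntervalRecord`."""
    out: list[IntervalRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}")
            chrom, start, end, label, score, strand = fields[:6]
            try:
                rec = IntervalRecord(chrom, int(start), int(end), label, float(score), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            out.append(rec)
    return out


def write_intervals(path, intervals: Iterable[IntervalRecord]) -> int:
    """Write intervals as BED6; returns the number written."""
    n = 0
    with open(path, "w") as out:
        for iv in intervals:
            out.write(
                f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{iv.label}\t{iv.score:g}\t{iv.strand}\n"
            )
            n += 1
    return n


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")
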