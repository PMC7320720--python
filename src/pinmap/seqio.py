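"""Readers and writers for FASTA, FASTQ, SAM and BED3.

All internal coordinates are 0-based half-open; conversion to the 1-based
SAM convention happens only at serialization time.  Qualities are Sanger
Phred+33 throughout (``p = 10**(-q/10)``).
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "SequenceRecord",
    "SamRecord",
    "BedInterval",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "read_bed",
    "write_bed",
    "sam_flags_paired",
    "FLAG_PAIRED",
    "FLAG_PROPER_PAIR",
    "FLAG_UNMAPPED",
    "FLAG_MATE_UNMAPPED",
    "FLAG_REVERSE",
    "FLAG_MATE_REVERSE",
    "FLAG_READ1",
    "FLAG_READ2",
]


class FormatError(ValueError):
    """Raised on malformed FASTA/FASTQ/SAM/BED input."""


# Any IUPAC code outside the four unambiguous bases is normalized to N.
_NON_ACGT = re.compile(r"[^ACGT]")


def _normalize_seq(seq: str) -> str:
    return _NON_ACGT.sub("N", seq.upper())


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional Phred qualities."""

    name: str
    sequence: str
    qualities: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence record with empty name")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.name!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path) -> io.TextIOBase:
    """Open ``path`` as text, transparently handling gzip."""
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=fh))
    return io.TextIOWrapper(fh)


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) FASTA file.

    Sequences are uppercased and ambiguity codes collapsed to N; multi-line
    records are concatenated.
    """
    name: Optional[str] = None
    chunks: list[str] = []
    n_records = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n\r")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield SequenceRecord(name, _normalize_seq("".join(chunks)))
                    n_records += 1
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError("FASTA header with empty name")
                chunks = []
            else:
                if name is None:
                    raise FormatError("FASTA sequence data before first header")
                chunks.append(line)
        if name is not None:
            yield SequenceRecord(name, _normalize_seq("".join(chunks)))
            n_records += 1
    if name is None:
        raise FormatError("empty FASTA file")


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream records from a (possibly gzipped) 4-line FASTQ file.

    Qualities are decoded from Phred+33: ``q = ord(char) - 33``.
    """
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n\r")
            if not header.startswith("@"):
                raise FormatError(f"expected '@' FASTQ header, got {header!r}")
            name = header[1:].split()[0]
            seq = fh.readline().rstrip("\n\r")
            plus = fh.readline()
            if not plus.startswith("+"):
                raise FormatError(f"record {name!r}: missing '+' separator line")
            qual = fh.readline().rstrip("\n\r")
            if len(qual) != len(seq):
                raise FormatError(
                    f"record {name!r}: sequence and quality lengths differ "
                    f"({len(seq)} vs {len(qual)})"
                )
            yield SequenceRecord(
                name, _normalize_seq(seq), [ord(c) - 33 for c in qual]
            )


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.name!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{qual}\n")


# SAM bit flags (SAM spec v1.6).
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80

_CIGAR_OP = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_CONSUMING = set("MIS=X")


def cigar_query_length(cigar: str) -> int:
    """Total query bases consumed by a CIGAR string."""
    if cigar == "*":
        return 0
    return sum(
        int(n) for n, op in _CIGAR_OP.findall(cigar) if op in _QUERY_CONSUMING
    )


@dataclass
class SamRecord:
    """One alignment line; coordinates here are already 1-based (SAM)."""

    qname: str
    flag: int
    rname: str = "*"
    pos: int = 0
    mapq: int = 0
    cigar: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    seq: str = "*"
    qual: str = "*"
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.flag & FLAG_UNMAPPED:
            if self.rname != "*" or self.pos != 0 or self.cigar != "*":
                raise FormatError(
                    f"unmapped record {self.qname!r} must have rname '*', "
                    "pos 0 and cigar '*'"
                )
        elif self.cigar != "*" and self.seq != "*":
            qlen = cigar_query_length(self.cigar)
            if qlen != len(self.seq):
                raise FormatError(
                    f"record {self.qname!r}: CIGAR consumes {qlen} query bases "
                    f"but SEQ has {len(self.seq)}"
                )

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.rname,
            str(self.pos),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext),
            str(self.tlen),
            self.seq,
            self.qual,
        ]
        fields.extend(self.tags)
        return "\t".join(fields)


def sam_flags_paired(
    r1_mapped: bool,
    r2_mapped: bool,
    r1_reverse: bool,
    r2_reverse: bool,
    proper: bool,
) -> tuple[int, int]:
    """SAM flag pair for the two mates of a paired read.

    A proper FR pair with R1 forward gives the familiar (99, 147).
    """
    f1 = FLAG_PAIRED | FLAG_READ1
    f2 = FLAG_PAIRED | FLAG_READ2
    if proper and r1_mapped and r2_mapped:
        f1 |= FLAG_PROPER_PAIR
        f2 |= FLAG_PROPER_PAIR
    if not r1_mapped:
        f1 |= FLAG_UNMAPPED
        f2 |= FLAG_MATE_UNMAPPED
    if not r2_mapped:
        f2 |= FLAG_UNMAPPED
        f1 |= FLAG_MATE_UNMAPPED
    if r1_mapped and r1_reverse:
        f1 |= FLAG_REVERSE
        f2 |= FLAG_MATE_REVERSE
    if r2_mapped and r2_reverse:
        f2 |= FLAG_REVERSE
        f1 |= FLAG_MATE_REVERSE
    return f1, f2


def write_sam(
    records: Iterable[SamRecord],
    header_info: Sequence[tuple[str, int]],
    path,
    program: str = "pinmap",
    command_line: str = "",
) -> None:
    """Write a SAM file with @HD, one @SQ per reference, and @PG.

    ``header_info`` lists (reference name, length) pairs.  A record whose
    rname is not declared in the header is an error.
    """
    known = {name for name, _ in header_info}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in header_info:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        pg = f"@PG\tID:{program}\tPN:{program}"
        if command_line:
            pg += f"\tCL:{command_line}"
        fh.write(pg + "\n")
        for rec in records:
            if rec.rname != "*" and rec.rname not in known:
                raise FormatError(
                    f"record {rec.qname!r} references unknown rname {rec.rname!r}"
                )
            fh.write(rec.to_line() + "\n")


@dataclass(frozen=True, order=True)
class BedInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid BED interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def write_bed(intervals: Iterable[BedInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_bed(path) -> list[BedInterval]:
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >=3 BED columns")
            try:
                iv = BedInterval(parts[0], int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            out.append(iv)
    return out
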