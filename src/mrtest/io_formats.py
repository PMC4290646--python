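"""Data model and file I/O for reads, references and alignments.

The harness works on three kinds of objects:

* :class:`ReadRecord` / :class:`ReadSet` — ordered FASTQ reads, single-end
  or mate-paired.  Order is significant: several metamorphic relations
  permute, duplicate or subset the read list.
* :class:`Reference` — an ordered collection of named contigs (FASTA).
* :class:`AlignmentRecord` / :class:`AlignmentResult` — the per-read mapping
  outcome an aligner reports (SAM), reduced to the fields the relation
  checks compare.  Exactly one primary record is kept per (read name, role);
  secondary and supplementary SAM lines are dropped at ingest.

FASTQ is read and written in the strict 4-line, Phred+33, unwrapped dialect
of modern Illumina output.  SAM is plain text (never BAM) and is parsed and
emitted through pysam; FASTA goes through Biopython.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "ReadRecord",
    "ReadSet",
    "Reference",
    "AlignmentRecord",
    "AlignmentResult",
    "reverse_complement",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "cigar_ops",
    "cigar_reference_span",
    "PHRED_OFFSET",
    "MAX_PHRED",
    "MAX_QUALITY_CHAR",
    "ROLES",
]

PHRED_OFFSET = 33
#: Highest modelled base quality (Illumina 1.8+ scale, Q41 = 'J').
MAX_PHRED = 41
MAX_QUALITY_CHAR = chr(PHRED_OFFSET + MAX_PHRED)

ROLES = ("single", "read1", "read2")

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """A file or record violates the format contract."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a sequence over {A, C, G, T, N} (N maps to N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: name, bases, Phred+33 qualities and mate role."""

    name: str
    sequence: str
    quality: str
    role: str = "single"

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise FormatError(f"read name {self.name!r} is empty or has whitespace")
        if len(self.sequence) != len(self.quality):
            raise FormatError(
                f"read {self.name!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if not set(self.sequence) <= _VALID_BASES:
            bad = sorted(set(self.sequence) - _VALID_BASES)
            raise FormatError(f"read {self.name!r}: illegal base(s) {bad}")
        for c in self.quality:
            if not PHRED_OFFSET <= ord(c) <= PHRED_OFFSET + MAX_PHRED:
                raise FormatError(
                    f"read {self.name!r}: quality character {c!r} outside "
                    f"Phred+33 range 0..{MAX_PHRED}"
                )
        if self.role not in ROLES:
            raise FormatError(f"read {self.name!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.quality]


@dataclass(frozen=True)
class ReadSet:
    """An ordered read collection, optionally mate-paired.

    For paired data ``reads1[i]`` and ``reads2[i]`` are mates and share a
    name; the pairing is positional, so every transformation that reorders
    or subsets reads must apply the same operation to both lists.
    """

    reads1: tuple[ReadRecord, ...]
    reads2: tuple[ReadRecord, ...] = ()
    paired: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "reads1", tuple(self.reads1))
        object.__setattr__(self, "reads2", tuple(self.reads2))
        if self.paired:
            if len(self.reads1) != len(self.reads2):
                raise FormatError(
                    f"paired set with {len(self.reads1)} read1 but "
                    f"{len(self.reads2)} read2 records"
                )
            for r1, r2 in zip(self.reads1, self.reads2):
                if r1.name != r2.name:
                    raise FormatError(
                        f"mates out of register: {r1.name!r} vs {r2.name!r}"
                    )
        elif self.reads2:
            raise FormatError("unpaired ReadSet must have empty reads2")

    def __len__(self) -> int:
        """Number of fragments (read pairs when paired, reads otherwise)."""
        return len(self.reads1)

    def iter_records(self) -> Iterator[ReadRecord]:
        """All records in processing order: mates interleaved for pairs."""
        if self.paired:
            for r1, r2 in zip(self.reads1, self.reads2):
                yield r1
                yield r2
        else:
            yield from self.reads1

    @staticmethod
    def single(reads: Iterable[ReadRecord]) -> "ReadSet":
        return ReadSet(reads1=tuple(reads), reads2=(), paired=False)


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reference:
    """Ordered map of contig name to sequence over {A, C, G, T, N}."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", dict(self.sequences))
        if not self.sequences:
            raise FormatError("reference has no contigs")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"contig {name!r} is empty")
            if not set(seq) <= _VALID_BASES:
                raise FormatError(f"contig {name!r} has illegal characters")

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, contig: str) -> str:
        return self.sequences[contig]

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentRecord:
    """Primary mapping outcome for one read.

    ``pos`` is the 1-based leftmost mapping coordinate (SAM convention).
    Unmapped records carry no placement fields at all.
    """

    read_name: str
    role: str
    mapped: bool
    contig: str | None = None
    pos: int | None = None
    strand: str | None = None
    cigar: str | None = None
    mapq: int = 0
    properly_paired: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"record {self.read_name!r}: bad role {self.role!r}")
        if self.mapped:
            if self.contig is None or self.pos is None or self.strand is None:
                raise FormatError(
                    f"mapped record {self.read_name!r} lacks contig/pos/strand"
                )
            if self.pos < 1:
                raise FormatError(f"record {self.read_name!r}: pos {self.pos} < 1")
            if self.strand not in ("+", "-"):
                raise FormatError(
                    f"record {self.read_name!r}: bad strand {self.strand!r}"
                )
        else:
            if any(v is not None for v in (self.contig, self.pos, self.strand, self.cigar)):
                raise FormatError(
                    f"unmapped record {self.read_name!r} has placement fields"
                )
            if self.properly_paired:
                raise FormatError(
                    f"unmapped record {self.read_name!r} flagged properly paired"
                )
        if not 0 <= self.mapq <= 255:
            raise FormatError(f"record {self.read_name!r}: MAPQ {self.mapq}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.read_name, self.role)


@dataclass
class AlignmentResult:
    """One primary :class:`AlignmentRecord` per (read name, role) key."""

    records: dict[tuple[str, str], AlignmentRecord] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[AlignmentRecord]) -> "AlignmentResult":
        out: dict[tuple[str, str], AlignmentRecord] = {}
        for rec in records:
            if rec.key in out:
                raise FormatError(f"duplicate primary record for {rec.key}")
            out[rec.key] = rec
        return cls(records=out)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AlignmentRecord]:
        return iter(self.records.values())

    def get(self, name: str, role: str) -> AlignmentRecord | None:
        return self.records.get((name, role))


def cigar_ops(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples."""
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string."""
    return sum(n for n, op in cigar_ops(cigar) if op in "MDN=X")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path, role: str = "single") -> list[ReadRecord]:
    """Parse a strict 4-line FASTQ file into an ordered record list.

    Malformed records raise :class:`FormatError` naming the offending
    (1-based) line number.
    """
    records: list[ReadRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"{path}: line count {len(lines)} is not a multiple of 4 "
            f"(truncated record near line {len(lines)})"
        )
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@"):
            raise FormatError(f"{path}: line {i + 1}: expected '@' header")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: line {i + 3}: expected '+' separator")
        name = header[1:].split()[0] if len(header) > 1 else ""
        try:
            records.append(ReadRecord(name=name, sequence=seq, quality=qual, role=role))
        except FormatError as exc:
            raise FormatError(f"{path}: record at line {i + 1}: {exc}") from exc
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write records in the 4-line dialect; round-trips byte-exactly."""
    with open(path, "w") as fh:
        for rec in reads:
            fh.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")


def read_fastq_pair(
    path1: str | Path, path2: str | Path | None = None
) -> ReadSet:
    """Load a single-end file or a mate pair of FASTQ files as a ReadSet."""
    if path2 is None:
        return ReadSet.single(read_fastq(path1, role="single"))
    return ReadSet(
        reads1=tuple(read_fastq(path1, role="read1")),
        reads2=tuple(read_fastq(path2, role="read2")),
        paired=True,
    )


def write_read_set(reads: ReadSet, path1: str | Path, path2: str | Path | None = None) -> None:
    write_fastq(reads.reads1, path1)
    if reads.paired:
        if path2 is None:
            raise ValueError("paired ReadSet needs a second output path")
        write_fastq(reads.reads2, path2)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> Reference:
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate contig {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"{path}: no FASTA records")
    return Reference(sequences=sequences)


def write_fasta(reference: Reference, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def read_sam(path: str | Path) -> AlignmentResult:
    """Ingest a SAM file, keeping one primary record per (name, role).

    FLAG bits are decoded per the SAM spec: 0x4 unmapped, 0x10 reverse
    strand, 0x2 properly paired, 0x40/0x80 mate role.  Secondary (0x100)
    and supplementary (0x800) lines are skipped.
    """
    result = AlignmentResult()
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    with sam:
        for seg in sam.fetch(until_eof=True):
            if seg.is_secondary or seg.is_supplementary:
                continue
            if seg.flag & _FLAG_PAIRED:
                role = "read1" if seg.flag & _FLAG_READ1 else "read2"
            else:
                role = "single"
            if seg.is_unmapped:
                rec = AlignmentRecord(
                    read_name=seg.query_name, role=role, mapped=False,
                    mapq=seg.mapping_quality,
                )
            else:
                if seg.reference_name is None:
                    raise FormatError(
                        f"{path}: mapped record {seg.query_name!r} with no contig"
                    )
                rec = AlignmentRecord(
                    read_name=seg.query_name,
                    role=role,
                    mapped=True,
                    contig=seg.reference_name,
                    pos=seg.reference_start + 1,
                    strand="-" if seg.is_reverse else "+",
                    cigar=seg.cigarstring,
                    mapq=seg.mapping_quality,
                    properly_paired=bool(seg.flag & _FLAG_PROPER),
                )
            if rec.key in result.records:
                raise FormatError(f"{path}: duplicate primary record for {rec.key}")
            result.records[rec.key] = rec
    return result


def write_sam(result: AlignmentResult, reference: Reference, path: str | Path) -> None:
    """Emit a header-complete SAM file; round-trips via :func:`read_sam`."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": len(seq)}
            for name, seq in reference.sequences.items()
        ],
    }
    contig_ids = {name: i for i, name in enumerate(reference.sequences)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for rec in result:
            seg = pysam.AlignedSegment(sam.header)
            seg.query_name = rec.read_name
            flag = 0
            if rec.role != "single":
                flag |= _FLAG_PAIRED
                flag |= _FLAG_READ1 if rec.role == "read1" else _FLAG_READ2
            if rec.mapped:
                if rec.contig not in contig_ids:
                    raise FormatError(
                        f"record {rec.read_name!r}: contig {rec.contig!r} "
                        f"not in reference"
                    )
                if rec.strand == "-":
                    flag |= _FLAG_REVERSE
                if rec.properly_paired:
                    flag |= _FLAG_PROPER
                seg.reference_id = contig_ids[rec.contig]
                seg.reference_start = rec.pos - 1
                seg.cigarstring = rec.cigar
            else:
                flag |= _FLAG_UNMAPPED
            seg.flag = flag
            seg.mapping_quality = rec.mapq
            sam.write(seg)
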