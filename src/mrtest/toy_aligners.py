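"""Built-in seed-and-extend aligner with controllable tie-breaking.

Real short-read aligners are black boxes to a metamorphic-testing harness.
To make the harness exercisable without external binaries, this module
provides a deliberately small, fully deterministic seed-and-extend aligner
whose *only* configurable failure surface is how it picks among co-optimal
loci for a multi-mapping read:

``lexicographic``
    The first hit in canonical order (contig order in the reference, then
    position, then ``+`` before ``-``).  A pure function of read content
    and reference — the "correct" behaviour every relation expects.

``global_rng``
    One pseudo-random stream, seeded once per run, consumed in
    read-processing order.  Repeating a run on the same file reproduces the
    output exactly, yet any change to the order or multiset of reads shifts
    which draw each multi-mapper receives.  This is the fixed-global-seed
    mechanism behind BWA's order-sensitive tie-breaking.

``read_seeded_rng``
    The stream is re-initialised per read from a digest of configurable
    read fields (name, sequence, quality).  Choices are then independent of
    file position — but become sensitive to any field in the digest, so
    including the quality string makes quality-only perturbations move
    multi-mappers.  This is the per-read-seed mechanism of Bowtie/Bowtie2.

Alignment itself is ungapped: candidate loci come from the read's first
k-mer (and the first k-mer of its reverse complement), extended over the
full read length; CIGARs are all-M; MAPQ is 37 for unique best hits and 0
for ambiguous ones.
"""

from __future__ import annotations

import shlex
import subprocess
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .io_formats import (
    AlignmentRecord,
    AlignmentResult,
    ReadRecord,
    ReadSet,
    Reference,
    read_sam,
    reverse_complement,
    write_fasta,
    write_read_set,
)

__all__ = [
    "HarnessError",
    "ConfigError",
    "AlignerError",
    "TIE_BREAK_MODES",
    "ToyAlignerConfig",
    "CandidateHit",
    "AlignerAdapter",
    "index_reference",
    "align_read",
    "align_pair",
    "break_tie",
    "ToyAligner",
    "ExternalAligner",
    "external_adapter",
]


class HarnessError(RuntimeError):
    """Internal harness malfunction (not an MR violation)."""


class ConfigError(HarnessError):
    """Invalid harness or adapter configuration."""


class AlignerError(HarnessError):
    """The aligner under test crashed or produced no output."""


TIE_BREAK_MODES = ("lexicographic", "global_rng", "read_seeded_rng")

#: MAPQ for a unique best hit / for an ambiguous (multi-mapped) placement.
UNIQUE_MAPQ = 37
AMBIGUOUS_MAPQ = 0


@dataclass(frozen=True)
class ToyAlignerConfig:
    """Tunable aligner parameters.

    ``k`` is the seed length in bp; ``max_mismatches`` the most substitutions
    tolerated over the full read; ``insert_min``/``insert_max`` bound the
    outer fragment span of a properly paired mate pair.  ``read_seed_fields``
    selects which read fields feed the per-read digest in
    ``read_seeded_rng`` mode.
    """

    k: int = 11
    max_mismatches: int = 3
    tie_break: str = "lexicographic"
    global_seed: int = 0
    read_seed_fields: tuple[str, ...] = ("name", "sequence", "quality")
    insert_min: int = 100
    insert_max: int = 600

    def __post_init__(self) -> None:
        if self.k < 4:
            raise ConfigError(f"seed length k={self.k} < 4")
        if self.max_mismatches < 0:
            raise ConfigError("max_mismatches must be >= 0")
        if self.tie_break not in TIE_BREAK_MODES:
            raise ConfigError(f"unknown tie_break mode {self.tie_break!r}")
        bad = set(self.read_seed_fields) - {"name", "sequence", "quality"}
        if bad:
            raise ConfigError(f"unknown read_seed_fields {sorted(bad)}")
        if self.insert_min > self.insert_max:
            raise ConfigError("insert_min > insert_max")


@dataclass(frozen=True)
class CandidateHit:
    contig: str
    pos: int  # 1-based leftmost
    strand: str
    n_mismatches: int


@runtime_checkable
class AlignerAdapter(Protocol):
    """Contract any aligner (toy or external) satisfies."""

    name: str

    def align(self, reads: ReadSet, reference: Reference) -> AlignmentResult:
        ...


# ---------------------------------------------------------------------------
# Indexing and per-read alignment
# ---------------------------------------------------------------------------


def index_reference(
    reference: Reference, k: int
) -> dict[str, list[tuple[str, int, str]]]:
    """Exact k-mer index over both strands.

    Maps each k-mer to the (contig, 1-based pos, strand) loci where it
    occurs; a ``-`` entry at position p means the k-mer's reverse complement
    occupies the forward strand at p.  Palindromic k-mers are therefore
    indexed on both strands at the same locus.
    """
    shortest = min(len(s) for s in reference.sequences.values())
    if k > shortest:
        raise ConfigError(
            f"k={k} exceeds shortest contig length {shortest}"
        )
    index: dict[str, list[tuple[str, int, str]]] = {}
    for contig, seq in reference.sequences.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            index.setdefault(kmer, []).append((contig, i + 1, "+"))
            index.setdefault(reverse_complement(kmer), []).append((contig, i + 1, "-"))
    return index


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance, short-circuiting once ``limit`` is exceeded."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def _candidates(
    read: ReadRecord,
    index: dict[str, list[tuple[str, int, str]]],
    reference: Reference,
    cfg: ToyAlignerConfig,
) -> list[CandidateHit]:
    seq = read.sequence
    L = len(seq)
    k = cfg.k
    rc = reverse_complement(seq)
    # Seed with the first k-mer of the read and of its reverse complement.
    # A '+' index entry for seq[:k] at p places the read forward at p; a
    # '-' entry means seq[:k] matches the minus strand there, i.e. the
    # read's 5' end sits at the *right* end of the locus: start = p + k - L.
    loci: dict[tuple[str, int, str], None] = {}
    for (c, p, s) in index.get(seq[:k], ()):
        start = p if s == "+" else p + k - L
        loci.setdefault((c, start, s), None)
    for (c, p, s) in index.get(rc[:k], ()):
        # rc[:k] forward at p -> read on '-' strand at p; rc[:k] on the
        # minus strand at p -> seq[-k:] forward there -> read '+' strand.
        if s == "+":
            loci.setdefault((c, p, "-"), None)
        else:
            loci.setdefault((c, p + k - L, "+"), None)
    hits: list[CandidateHit] = []
    for (c, start, s) in loci:
        ref_seq = reference.sequences[c]
        if start < 1 or start + L - 1 > len(ref_seq):
            continue
        query = seq if s == "+" else rc
        mm = _count_mismatches(query, ref_seq[start - 1 : start - 1 + L],
                               cfg.max_mismatches)
        if mm <= cfg.max_mismatches:
            hits.append(CandidateHit(contig=c, pos=start, strand=s, n_mismatches=mm))
    return hits


def break_tie(
    hits: list[CandidateHit],
    read: ReadRecord,
    cfg: ToyAlignerConfig,
    stream_state: np.random.Generator | None,
) -> CandidateHit:
    """Pick one of >= 2 co-optimal hits according to the configured mode.

    ``hits`` must already be in canonical order; ``stream_state`` is the
    run-wide stream for ``global_rng`` mode (consumed one draw per tie,
    in read-processing order) and is ignored by the other modes.
    """
    if not hits:
        raise HarnessError("break_tie called with no hits")
    if cfg.tie_break == "lexicographic":
        return hits[0]
    if cfg.tie_break == "global_rng":
        if stream_state is None:
            raise HarnessError("global_rng mode needs the per-run stream")
        return hits[int(stream_state.integers(len(hits)))]
    # read_seeded_rng: stable non-cryptographic digest of the selected
    # read fields plus the run seed, re-seeding a fresh stream per read.
    parts = []
    for f in ("name", "sequence", "quality"):
        if f in cfg.read_seed_fields:
            parts.append(getattr(read, f))
    digest = zlib.crc32("\x00".join(parts).encode()) ^ (cfg.global_seed & 0xFFFFFFFF)
    rng = np.random.default_rng(digest)
    return hits[int(rng.integers(len(hits)))]


def align_read(
    read: ReadRecord,
    index: dict[str, list[tuple[str, int, str]]],
    reference: Reference,
    cfg: ToyAlignerConfig,
    stream_state: np.random.Generator | None = None,
    contig_rank: dict[str, int] | None = None,
) -> tuple[AlignmentRecord, list[CandidateHit]]:
    """Align one read; returns the chosen record plus all surviving hits.

    Reads shorter than ``k`` are reported unmapped (not an error).  A
    unique best hit gets MAPQ 37; co-optimal best hits are resolved by
    :func:`break_tie` and get MAPQ 0.
    """
    if contig_rank is None:
        contig_rank = {c: i for i, c in enumerate(reference.sequences)}
    unmapped = AlignmentRecord(read_name=read.name, role=read.role, mapped=False,
                               mapq=0)
    if len(read) < cfg.k:
        return unmapped, []
    hits = _candidates(read, index, reference, cfg)
    if not hits:
        return unmapped, []
    hits.sort(key=lambda h: (contig_rank[h.contig], h.pos, h.strand))
    best_mm = min(h.n_mismatches for h in hits)
    best = [h for h in hits if h.n_mismatches == best_mm]
    if len(best) == 1:
        chosen, mapq = best[0], UNIQUE_MAPQ
    else:
        chosen, mapq = break_tie(best, read, cfg, stream_state), AMBIGUOUS_MAPQ
    record = AlignmentRecord(
        read_name=read.name,
        role=read.role,
        mapped=True,
        contig=chosen.contig,
        pos=chosen.pos,
        strand=chosen.strand,
        cigar=f"{len(read)}M",
        mapq=mapq,
    )
    return record, hits


def align_pair(
    read1: ReadRecord,
    read2: ReadRecord,
    index: dict[str, list[tuple[str, int, str]]],
    reference: Reference,
    cfg: ToyAlignerConfig,
    stream_state: np.random.Generator | None = None,
) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Align mates independently, then set the properly-paired flag.

    A pair is properly paired iff both mates map to the same contig on
    opposite strands with an outer span inside [insert_min, insert_max].
    """
    rec1, _ = align_read(read1, index, reference, cfg, stream_state)
    rec2, _ = align_read(read2, index, reference, cfg, stream_state)
    if rec1.mapped and rec2.mapped and rec1.contig == rec2.contig \
            and rec1.strand != rec2.strand:
        left = min(rec1.pos, rec2.pos)
        right = max(rec1.pos + len(read1) - 1, rec2.pos + len(read2) - 1)
        outer = right - left + 1
        if cfg.insert_min <= outer <= cfg.insert_max:
            rec1 = replace(rec1, properly_paired=True)
            rec2 = replace(rec2, properly_paired=True)
    return rec1, rec2


# ---------------------------------------------------------------------------
# Adapters
# ---------------------------------------------------------------------------


class ToyAligner:
    """In-process :class:`AlignerAdapter` around the toy aligner.

    The ``global_rng`` stream is re-initialised from ``global_seed`` at the
    start of every :meth:`align` call, so each run of the aligner is
    reproducible on identical input — exactly the property that makes the
    mode's order sensitivity a silent fault rather than visible noise.
    """

    def __init__(self, config: ToyAlignerConfig | None = None) -> None:
        self.config = config or ToyAlignerConfig()
        self._index_cache: dict[int, dict] = {}

    @property
    def name(self) -> str:
        return f"toy-{self.config.tie_break.replace('_', '-')}"

    def _index(self, reference: Reference) -> dict:
        key = id(reference)
        if key not in self._index_cache:
            self._index_cache.clear()  # hold at most one reference
            self._index_cache[key] = index_reference(reference, self.config.k)
        return self._index_cache[key]

    def align(self, reads: ReadSet, reference: Reference) -> AlignmentResult:
        index = self._index(reference)
        stream = (
            np.random.default_rng(self.config.global_seed)
            if self.config.tie_break == "global_rng"
            else None
        )
        result = AlignmentResult()
        if reads.paired:
            for r1, r2 in zip(reads.reads1, reads.reads2):
                rec1, rec2 = align_pair(r1, r2, index, reference, self.config, stream)
                result.records[rec1.key] = rec1
                result.records[rec2.key] = rec2
        else:
            for r in reads.reads1:
                rec, _ = align_read(r, index, reference, self.config, stream)
                result.records[rec.key] = rec
        return result


_PLACEHOLDERS = ("{reference}", "{reads1}", "{sam}")


class ExternalAligner:
    """Adapter that shells out to any aligner via a command template.

    The template must contain ``{reference}``, ``{reads1}`` and ``{sam}``
    placeholders (``{reads2}`` as well for paired input); the adapter writes
    FASTA/FASTQ inputs to ``workdir``, runs the command, and ingests the
    SAM the command produced.  External tools emitting BAM should convert
    to SAM (e.g. ``samtools view -h``) inside the template.
    """

    def __init__(self, command_template: str, workdir: str | Path,
                 name: str = "external") -> None:
        for ph in _PLACEHOLDERS:
            if ph not in command_template:
                raise ConfigError(f"command template lacks {ph} placeholder")
        self.command_template = command_template
        self.workdir = Path(workdir)
        self.name = name
        self._run_log: list[dict] = []

    @property
    def run_log(self) -> list[dict]:
        return list(self._run_log)

    def align(self, reads: ReadSet, reference: Reference) -> AlignmentResult:
        self.workdir.mkdir(parents=True, exist_ok=True)
        ref_path = self.workdir / "reference.fa"
        r1_path = self.workdir / "reads_1.fastq"
        r2_path = self.workdir / "reads_2.fastq"
        sam_path = self.workdir / "out.sam"
        write_fasta(reference, ref_path)
        write_read_set(reads, r1_path, r2_path if reads.paired else None)
        if reads.paired and "{reads2}" not in self.command_template:
            raise ConfigError("paired input but template lacks {reads2}")
        command = self.command_template.format(
            reference=shlex.quote(str(ref_path)),
            reads1=shlex.quote(str(r1_path)),
            reads2=shlex.quote(str(r2_path)),
            sam=shlex.quote(str(sam_path)),
        )
        proc = subprocess.run(
            command, shell=True, capture_output=True, text=True
        )
        self._run_log.append({
            "command": command,
            "returncode": proc.returncode,
            "stderr": proc.stderr,
        })
        if proc.returncode != 0:
            raise AlignerError(
                f"aligner command failed (exit {proc.returncode}): {proc.stderr}"
            )
        if not sam_path.exists():
            raise AlignerError(f"aligner produced no output at {sam_path}")
        return read_sam(sam_path)


def external_adapter(command_template: str, workdir: str | Path,
                     name: str = "external") -> ExternalAligner:
    """Build an :class:`ExternalAligner` from a command template."""
    return ExternalAligner(command_template, workdir, name=name)
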