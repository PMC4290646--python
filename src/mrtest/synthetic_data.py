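"""Simulation of references with engineered repeats and Illumina-style reads.

The metamorphic relations only discriminate between tie-breaking behaviours
when multi-mapping reads exist, so the simulated reference deliberately
contains segments duplicated verbatim at a second locus: any read sampled
wholly inside one copy has at least two co-optimal alignments.  The read
simulator draws fragments uniformly, emits FR mate pairs with a truncated
normal insert size, applies i.i.d. substitution errors, and records every
read's true origin in a truth table so tests can assert alignment recovery
without an oracle aligner.

Defaults describe the study conditions exercised throughout the harness:
a 100 kb contig with one 1 kb duplicated segment, 5,000 pairs of 100 bp
reads, 300 +/- 30 bp inserts and a 0.5% per-base substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    MAX_PHRED,
    PHRED_OFFSET,
    ReadRecord,
    ReadSet,
    Reference,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "RepeatInterval",
    "SimulationError",
    "make_reference",
    "simulate_reads",
    "plant_variants",
    "write_bed",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters (lengths in bp; ``n_reads`` counts fragments,
    i.e. read pairs when ``paired``)."""

    ref_length: int = 100_000
    n_repeats: int = 1
    repeat_length: int = 1_000
    n_reads: int = 5_000
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.005
    paired: bool = True
    seed: int = 0
    contig_name: str = "sim1"

    def __post_init__(self) -> None:
        if self.n_repeats > 0 and self.repeat_length < self.read_length:
            raise SimulationError(
                "repeat_length must be >= read_length so a read can fall "
                "wholly inside a repeat copy"
            )
        if not 0 <= self.error_rate < 1:
            raise SimulationError("error_rate must be in [0, 1)")
        if self.read_length < 1 or self.n_reads < 1 or self.ref_length < 1:
            raise SimulationError("lengths and counts must be positive")


@dataclass(frozen=True)
class RepeatInterval:
    """A repeat copy as a BED-style 0-based half-open interval."""

    contig: str
    start: int
    end: int

    def contains(self, start0: int, end0: int) -> bool:
        return self.start <= start0 and end0 <= self.end


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def make_reference(cfg: SimConfig) -> tuple[Reference, list[RepeatInterval]]:
    """Random reference with ``n_repeats`` segments duplicated verbatim.

    Returns the reference and the annotation of *all* repeat copies (two
    intervals per engineered repeat).  Deterministic in ``cfg.seed``.
    """
    if cfg.ref_length <= 2 * cfg.n_repeats * cfg.repeat_length:
        raise SimulationError(
            f"ref_length {cfg.ref_length} cannot pack "
            f"{cfg.n_repeats} repeat(s) of {cfg.repeat_length} bp twice over"
        )
    rng = np.random.default_rng(cfg.seed)
    seq = _random_sequence(rng, cfg.ref_length)
    intervals: list[RepeatInterval] = []
    taken: list[tuple[int, int]] = []

    def place_one() -> int:
        for _ in range(10_000):
            start = int(rng.integers(0, cfg.ref_length - cfg.repeat_length + 1))
            end = start + cfg.repeat_length
            if all(end <= s or start >= e for s, e in taken):
                taken.append((start, end))
                return start
        raise SimulationError("could not pack repeat segments; lower n_repeats")

    for _ in range(cfg.n_repeats):
        src = place_one()
        dst = place_one()
        seq[dst : dst + cfg.repeat_length] = seq[src : src + cfg.repeat_length]
        intervals.append(RepeatInterval(cfg.contig_name, src, src + cfg.repeat_length))
        intervals.append(RepeatInterval(cfg.contig_name, dst, dst + cfg.repeat_length))
    intervals.sort(key=lambda iv: iv.start)
    reference = Reference(sequences={cfg.contig_name: seq.tobytes().decode()})
    return reference, intervals


def _quality_string(rng: np.random.Generator, length: int) -> str:
    """Constant high baseline (Q40) with sparse random decrements.

    Qualities only matter to the harness through MR8 and the per-read
    seeding of the read_seeded_rng tie-break, not through scoring.
    """
    phred = np.full(length, MAX_PHRED - 1, dtype=np.int64)
    drop = rng.random(length) < 0.1
    phred[drop] -= rng.integers(1, 11, size=int(drop.sum()))
    return (phred + PHRED_OFFSET).astype(np.uint8).tobytes().decode()


def _apply_errors(
    rng: np.random.Generator, seq: np.ndarray, error_rate: float
) -> np.ndarray:
    if error_rate <= 0:
        return seq
    seq = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < error_rate)
    for i in hit:
        # substitute with one of the three other bases, uniformly
        choices = _BASES[_BASES != seq[i]]
        seq[i] = choices[rng.integers(0, 3)]
    return seq


def simulate_reads(
    reference: Reference,
    cfg: SimConfig,
    repeats: Sequence[RepeatInterval] = (),
) -> tuple[ReadSet, pd.DataFrame]:
    """Sample reads uniformly from the reference.

    Paired mode emits FR pairs: the fragment is drawn on a random strand,
    read1 is the fragment's 5' end and read2 the reverse complement of its
    3' end, with fragment length ~ Normal(insert_mean, insert_sd) truncated
    to [read_length, contig length].  The truth table records each read's
    true contig, 1-based leftmost position, strand and whether it lies
    wholly inside an annotated repeat copy.
    """
    contig = cfg.contig_name
    if contig not in reference.sequences:
        contig = next(iter(reference.sequences))
    seq = np.frombuffer(reference.sequences[contig].encode(), dtype="S1")
    L = len(seq)
    if cfg.read_length > L:
        raise SimulationError("read_length exceeds contig length")
    rng = np.random.default_rng(cfg.seed + 1)
    rlen = cfg.read_length

    def in_repeat(start0: int) -> bool:
        end0 = start0 + rlen
        return any(iv.contig == contig and iv.contains(start0, end0)
                   for iv in repeats)

    reads1: list[ReadRecord] = []
    reads2: list[ReadRecord] = []
    truth_rows: list[dict] = []

    def emit(name: str, role: str, start0: int, strand: str) -> ReadRecord:
        frag = seq[start0 : start0 + rlen]
        if strand == "-":
            bases = _apply_errors(rng, frag, cfg.error_rate).tobytes().decode()
            bases = reverse_complement(bases)
        else:
            bases = _apply_errors(rng, frag, cfg.error_rate).tobytes().decode()
        truth_rows.append({
            "name": name, "role": role, "contig": contig,
            "pos": start0 + 1, "strand": strand, "in_repeat": in_repeat(start0),
        })
        return ReadRecord(name=name, sequence=bases,
                          quality=_quality_string(rng, rlen), role=role)

    for i in range(cfg.n_reads):
        name = f"sim_{i:06d}"
        if cfg.paired:
            insert = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            insert = max(rlen, min(insert, L))
            frag_start = int(rng.integers(0, L - insert + 1))
            frag_strand = "+" if rng.random() < 0.5 else "-"
            left0 = frag_start
            right0 = frag_start + insert - rlen
            if frag_strand == "+":
                reads1.append(emit(name, "read1", left0, "+"))
                reads2.append(emit(name, "read2", right0, "-"))
            else:
                reads1.append(emit(name, "read1", right0, "-"))
                reads2.append(emit(name, "read2", left0, "+"))
        else:
            start0 = int(rng.integers(0, L - rlen + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            reads1.append(emit(name, "single", start0, strand))

    read_set = ReadSet(reads1=tuple(reads1), reads2=tuple(reads2),
                       paired=cfg.paired)
    truth = pd.DataFrame(truth_rows,
                         columns=["name", "role", "contig", "pos", "strand",
                                  "in_repeat"])
    return read_set, truth


def plant_variants(
    reference: Reference, variants: Sequence[tuple[str, int, str]]
) -> Reference:
    """Return a sample genome: the reference with SNVs substituted in.

    ``variants`` are (contig, 1-based pos, alt base); the alt must differ
    from the reference base.  Reads simulated from the returned genome but
    aligned against the original reference then carry the planted alleles,
    giving the variant caller known expected calls.
    """
    sequences = {c: bytearray(s.encode()) for c, s in reference.sequences.items()}
    for contig, pos, alt in variants:
        if contig not in sequences:
            raise SimulationError(f"unknown contig {contig!r}")
        if not 1 <= pos <= len(sequences[contig]):
            raise SimulationError(f"variant position {pos} outside {contig!r}")
        if alt not in "ACGT":
            raise SimulationError(f"bad alt allele {alt!r}")
        if sequences[contig][pos - 1 : pos] == alt.encode():
            raise SimulationError(
                f"alt equals reference base at {contig}:{pos}"
            )
        sequences[contig][pos - 1] = ord(alt)
    return Reference(sequences={c: bytes(b).decode() for c, b in sequences.items()})


def write_bed(intervals: Sequence[RepeatInterval], path: str | Path) -> None:
    """Write repeat annotation as BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\trepeat\n")
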