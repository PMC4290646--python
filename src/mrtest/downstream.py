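"""Propagation of alignment discordance into variant calls.

A tie-breaking fault in an aligner moves only MAPQ-0 multi-mappers, which
is easy to dismiss — until those reads feed a variant caller.  This module
provides a deliberately naive pileup caller (per-position plurality vote
with depth and allele-fraction thresholds) and a concordance counter, so
the harness can show the full chain: order-sensitive tie-breaking changes
where repeat reads pile up, which changes the variant list; filtering on
mapping quality (discarding MAPQ 0) restores concordance, because all the
discordance is carried by ambiguously placed reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    AlignmentResult,
    ReadSet,
    Reference,
    cigar_ops,
    reverse_complement,
)
from .metamorphic_relations import UnsupportedCigarError

__all__ = [
    "CallerConfig",
    "VariantCall",
    "pileup_call",
    "variant_concordance",
    "variant_discordance_experiment",
    "write_vcf",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class CallerConfig:
    """Pileup-caller thresholds.

    ``min_mapq`` is the quality-control knob of interest: at 0 every read
    contributes; at >= 1 ambiguously placed (MAPQ-0) reads are excluded.
    """

    min_depth: int = 5
    min_alt_fraction: float = 0.3
    min_mapq: int = 0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.min_alt_fraction <= 1:
            raise ValueError("min_alt_fraction must be in (0, 1]")


@dataclass(frozen=True)
class VariantCall:
    contig: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt alleles are identical")
        if not 0 < self.alt_fraction <= 1:
            raise ValueError("alt_fraction must be in (0, 1]")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt_base)


def pileup_call(
    result: AlignmentResult,
    reads: ReadSet,
    reference: Reference,
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Naive plurality variant caller over all-M/S alignments.

    Piles up the aligned base of every mapped record with
    ``mapq >= min_mapq``; emits a call wherever depth reaches ``min_depth``
    and the plurality non-reference base reaches ``min_alt_fraction`` of
    the depth.  N bases are ignored.
    """
    cfg = config or CallerConfig()
    read_by_key = {(r.name, r.role): r for r in reads.iter_records()}
    # per-contig base-count matrices, shape (4, contig length)
    counts = {
        contig: np.zeros((4, len(seq)), dtype=np.int32)
        for contig, seq in reference.sequences.items()
    }
    for rec in result:
        if not rec.mapped or rec.mapq < cfg.min_mapq:
            continue
        read = read_by_key.get(rec.key)
        if read is None:
            raise ValueError(f"no read for alignment record {rec.key}")
        aligned = (read.sequence if rec.strand == "+"
                   else reverse_complement(read.sequence))
        mat = counts[rec.contig]
        q = 0
        p = rec.pos - 1
        for n, op in cigar_ops(rec.cigar):
            if op == "M":
                codes = np.frombuffer(aligned[q : q + n].encode(), dtype=np.uint8)
                positions = np.arange(p, p + n)
                for base, code in _BASE_CODE.items():
                    sel = codes == ord(base)
                    if sel.any():
                        np.add.at(mat[code], positions[sel], 1)
                q += n
                p += n
            elif op == "S":
                q += n
            else:
                raise UnsupportedCigarError(
                    f"record {rec.read_name!r}: unsupported CIGAR op {op!r}"
                )

    calls: list[VariantCall] = []
    for contig, mat in counts.items():
        depth = mat.sum(axis=0)
        covered = np.flatnonzero(depth >= cfg.min_depth)
        if covered.size == 0:
            continue
        ref_codes = np.frombuffer(
            reference.sequences[contig].encode(), dtype=np.uint8
        )
        for i in covered:
            ref_base = chr(ref_codes[i])
            if ref_base not in _BASE_CODE:
                continue
            col = mat[:, i].copy()
            col[_BASE_CODE[ref_base]] = -1
            alt_code = int(col.argmax())
            alt_count = int(col[alt_code])
            if alt_count <= 0:
                continue
            frac = alt_count / int(depth[i])
            if frac >= cfg.min_alt_fraction:
                calls.append(VariantCall(
                    contig=contig, pos=int(i) + 1, ref_base=ref_base,
                    alt_base=_CODE_BASE[alt_code], depth=int(depth[i]),
                    alt_fraction=frac,
                ))
    calls.sort(key=lambda c: (c.contig, c.pos, c.alt_base))
    return calls


def variant_concordance(
    a: Sequence[VariantCall], b: Sequence[VariantCall]
) -> tuple[int, int, int]:
    """(shared, only-in-a, only-in-b) counts keyed on (contig, pos, alt)."""
    keys_a = {c.key for c in a}
    keys_b = {c.key for c in b}
    return (len(keys_a & keys_b), len(keys_a - keys_b), len(keys_b - keys_a))


def variant_discordance_experiment(
    aligner,
    sim_config=None,
    mr1_seed: int = 17,
    variant_spacing: int = 50,
    caller_configs: Sequence[CallerConfig] = (
        CallerConfig(min_mapq=0),
        CallerConfig(min_mapq=1),
    ),
) -> dict[int, tuple[int, int, int]]:
    """End-to-end demonstration of fault propagation into variant calls.

    Plants SNVs every ``variant_spacing`` bp inside the first engineered
    repeat copy of a simulated reference, simulates reads from that sample
    genome, aligns source and MR1-permuted read sets against the original
    reference with ``aligner``, calls variants from both alignments at each
    caller configuration, and returns
    ``{min_mapq: (shared, only_source, only_followup)}``.

    For an order-sensitive tie-breaker the lists differ at ``min_mapq=0``
    and coincide once MAPQ-0 reads are filtered; for a content-pure
    tie-breaker they coincide at every threshold.
    """
    from .metamorphic_relations import mr1_permute
    from .synthetic_data import (
        SimConfig,
        make_reference,
        plant_variants,
        simulate_reads,
    )

    cfg = sim_config or SimConfig()
    reference, repeats = make_reference(cfg)
    repeat = repeats[0]
    variants = []
    for off in range(variant_spacing, cfg.repeat_length - variant_spacing + 1,
                     variant_spacing):
        pos = repeat.start + off  # 1-based position inside the repeat copy
        ref_base = reference[repeat.contig][pos - 1]
        alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        variants.append((repeat.contig, pos, alt))
    sample_genome = plant_variants(reference, variants)
    reads, _ = simulate_reads(sample_genome, cfg, repeats)

    source_result = aligner.align(reads, reference)
    followup_reads, _ = mr1_permute(reads, mr1_seed)
    followup_result = aligner.align(followup_reads, reference)

    out: dict[int, tuple[int, int, int]] = {}
    for caller_cfg in caller_configs:
        calls_src = pileup_call(source_result, reads, reference, caller_cfg)
        calls_fu = pileup_call(followup_result, followup_reads, reference,
                               caller_cfg)
        out[caller_cfg.min_mapq] = variant_concordance(calls_src, calls_fu)
    return out


def write_vcf(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Minimal VCF: fixed columns plus DP and AF in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,'
                 'Description="Alt allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos, c.alt_base)):
            fh.write(
                f"{c.contig}\t{c.pos}\t.\t{c.ref_base}\t{c.alt_base}\t.\t.\t"
                f"DP={c.depth};AF={c.alt_fraction:.4f}\n"
            )
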