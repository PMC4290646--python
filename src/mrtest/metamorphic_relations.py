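"""The nine metamorphic relations: input transformations and output checks.

A metamorphic relation (MR) sidesteps the oracle problem: instead of asking
whether one alignment run is correct, it transforms the input in a way
whose effect on a *correct* aligner's output is predictable, reruns the
aligner, and checks the predicted relationship between the two outputs.

Each MR here is a pair: a transformation of the source :class:`ReadSet`
(MR5-MR9 additionally consume the source alignment, applied "after initial
mapping") and an expected relation between source and follow-up
:class:`AlignmentResult` objects:

===== ============================== =========================================
MR    transformation                 expected relation
===== ============================== =========================================
MR1   random permutation of reads    identical mapping per read
MR2   reverse complement + reversed  identical mapping per read
      qualities, file order reversed
MR3   reads duplicated (copies       originals unchanged; each copy maps
      renamed)                       where its original does
MR4   half the reads removed         retained reads unchanged; coverage
                                     ratio reported (expected ~0.5)
MR5   mapped reads extended 20 bp    identical mapping per read
      from the reference, Q41
MR6   unmapped reads re-mapped       nothing maps
MR7   mapped (properly paired)       everything maps, at the same location
      reads re-mapped
MR8   qualities of mapped reads      identical mapping per read
      raised
MR9   mismatches in mapped reads     identical mapping over the selected
      corrected from the reference   reads
===== ============================== =========================================

A single discordant read fails an MR: the published failure matrices mark
a run failed on *any* difference between the two alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .comparison import (
    DEFAULT_FIELDS,
    DiffEntry,
    MRReport,
    Verdict,
    compare_records,
    mean_coverage,
)
from .io_formats import (
    MAX_PHRED,
    MAX_QUALITY_CHAR,
    PHRED_OFFSET,
    AlignmentRecord,
    AlignmentResult,
    ReadRecord,
    ReadSet,
    Reference,
    cigar_ops,
    reverse_complement,
)
from .toy_aligners import HarnessError

__all__ = [
    "MR_IDS",
    "DUPLICATE_SUFFIX",
    "TransformMetadata",
    "MRCase",
    "MR_REGISTRY",
    "TransformError",
    "UnsupportedCigarError",
    "mr1_permute",
    "mr2_revcomp",
    "mr3_duplicate",
    "mr4_halve",
    "mr5_extend",
    "mr6_select_unmapped",
    "mr7_select_mapped",
    "mr8_boost_quality",
    "mr9_correct_mismatches",
    "check_relation",
]

MR_IDS = tuple(f"MR{i}" for i in range(1, 10))

#: Reserved suffix appended to duplicate read names by MR3.
DUPLICATE_SUFFIX = ".dup"

#: Default extension length (bp) for MR5 and quality increment for MR8.
DEFAULT_EXTENSION = 20
DEFAULT_QUALITY_DELTA = 5


class TransformError(ValueError):
    """The transformation's preconditions are violated."""


class UnsupportedCigarError(TransformError):
    """A CIGAR contains operations the transformation cannot walk."""


@dataclass(frozen=True)
class TransformMetadata:
    """What a transformation did, for the relation check.

    ``name_map`` sends every follow-up read name to its source read name
    (identity except for MR3's renamed duplicates) and is total over the
    follow-up set.
    """

    mr_id: str
    name_map: dict[str, str]
    seed: int | None = None
    params: dict = field(default_factory=dict)


def _identity_map(reads: ReadSet) -> dict[str, str]:
    return {r.name: r.name for r in reads.reads1}


# ---------------------------------------------------------------------------
# Transformations MR1-MR4 (no source alignment needed)
# ---------------------------------------------------------------------------


def mr1_permute(reads: ReadSet, seed: int) -> tuple[ReadSet, TransformMetadata]:
    """Reshuffle the reads; the same permutation is applied to both mates."""
    perm = np.random.default_rng(seed).permutation(len(reads))
    out = ReadSet(
        reads1=tuple(reads.reads1[i] for i in perm),
        reads2=tuple(reads.reads2[i] for i in perm) if reads.paired else (),
        paired=reads.paired,
    )
    meta = TransformMetadata("MR1", _identity_map(out), seed=seed,
                             params={"permutation": [int(i) for i in perm]})
    return out, meta


def _revcomp_record(rec: ReadRecord) -> ReadRecord:
    return replace(rec, sequence=reverse_complement(rec.sequence),
                   quality=rec.quality[::-1])


def mr2_revcomp(reads: ReadSet) -> tuple[ReadSet, TransformMetadata]:
    """Reverse complement every read (qualities reversed to stay with their
    bases) and reverse the order of reads within each file.  Mate roles are
    not swapped."""
    out = ReadSet(
        reads1=tuple(_revcomp_record(r) for r in reversed(reads.reads1)),
        reads2=tuple(_revcomp_record(r) for r in reversed(reads.reads2)),
        paired=reads.paired,
    )
    return out, TransformMetadata("MR2", _identity_map(out))


def mr3_duplicate(
    reads: ReadSet, suffix: str = DUPLICATE_SUFFIX
) -> tuple[ReadSet, TransformMetadata]:
    """Append a renamed copy of every read; copies map back via name_map."""
    for r in reads.reads1:
        if r.name.endswith(suffix):
            raise TransformError(
                f"input read {r.name!r} already carries the reserved "
                f"duplicate suffix {suffix!r}"
            )
    dup1 = tuple(replace(r, name=r.name + suffix) for r in reads.reads1)
    dup2 = tuple(replace(r, name=r.name + suffix) for r in reads.reads2)
    out = ReadSet(reads1=reads.reads1 + dup1, reads2=reads.reads2 + dup2,
                  paired=reads.paired)
    name_map = {r.name: r.name for r in reads.reads1}
    name_map.update({r.name + suffix: r.name for r in reads.reads1})
    return out, TransformMetadata("MR3", name_map, params={"suffix": suffix})


def mr4_halve(reads: ReadSet) -> tuple[ReadSet, TransformMetadata]:
    """Remove half of the reads: the even-index half (0, 2, 4, ...) of the
    original order is retained, identically in both mate files."""
    if len(reads) < 2:
        raise TransformError("need at least 2 reads to remove half")
    keep = range(0, len(reads), 2)
    out = ReadSet(
        reads1=tuple(reads.reads1[i] for i in keep),
        reads2=tuple(reads.reads2[i] for i in keep) if reads.paired else (),
        paired=reads.paired,
    )
    return out, TransformMetadata("MR4", _identity_map(out))


# ---------------------------------------------------------------------------
# Transformations MR5-MR9 (applied after initial mapping)
# ---------------------------------------------------------------------------


def _require_record(source: AlignmentResult, read: ReadRecord) -> AlignmentRecord:
    rec = source.get(read.name, read.role)
    if rec is None:
        raise HarnessError(
            f"source alignment has no record for ({read.name!r}, {read.role!r})"
        )
    return rec


def _extend_one(read: ReadRecord, rec: AlignmentRecord, reference: Reference,
                ext: int) -> ReadRecord:
    if not rec.mapped:
        return read
    contig_seq = reference.sequences[rec.contig]
    L = len(read)
    if rec.strand == "+":
        # 3' end of the read is the reference-right end of the alignment.
        start0 = rec.pos - 1 + L
        tail = contig_seq[start0 : start0 + ext]
    else:
        # 3' end in read orientation faces reference-left; take the bases
        # upstream of the alignment and reverse complement them.
        stop0 = rec.pos - 1
        tail = reverse_complement(contig_seq[max(0, stop0 - ext) : stop0])
    return replace(read, sequence=read.sequence + tail,
                   quality=read.quality + MAX_QUALITY_CHAR * len(tail))


def mr5_extend(
    reads: ReadSet, source: AlignmentResult, reference: Reference,
    ext: int = DEFAULT_EXTENSION,
) -> tuple[ReadSet, TransformMetadata]:
    """Extend each mapped read by ``ext`` bases copied from the reference
    adjacent to its alignment, appended at the read's 3' end with the
    maximum modelled quality.  Extensions running past a contig end are
    truncated at the boundary; unmapped reads pass through unchanged."""
    out1 = tuple(
        _extend_one(r, _require_record(source, r), reference, ext)
        for r in reads.reads1
    )
    out2 = tuple(
        _extend_one(r, _require_record(source, r), reference, ext)
        for r in reads.reads2
    )
    out = ReadSet(reads1=out1, reads2=out2, paired=reads.paired)
    return out, TransformMetadata("MR5", _identity_map(out),
                                  params={"extension": ext})


def _select(reads: ReadSet, source: AlignmentResult,
            keep: Callable[[AlignmentRecord], bool],
            pair_rule: str, mr_id: str) -> tuple[ReadSet, TransformMetadata]:
    if reads.paired:
        idx = [
            i for i in range(len(reads))
            if keep(_require_record(source, reads.reads1[i]))
            and keep(_require_record(source, reads.reads2[i]))
        ]
        out = ReadSet(
            reads1=tuple(reads.reads1[i] for i in idx),
            reads2=tuple(reads.reads2[i] for i in idx),
            paired=True,
        )
    else:
        out = ReadSet.single(
            r for r in reads.reads1 if keep(_require_record(source, r))
        )
    return out, TransformMetadata(mr_id, _identity_map(out),
                                  params={"pair_rule": pair_rule})


def mr6_select_unmapped(
    reads: ReadSet, source: AlignmentResult
) -> tuple[ReadSet, TransformMetadata]:
    """Keep only unmapped reads (pairs where both mates are unmapped)."""
    return _select(reads, source, lambda rec: not rec.mapped,
                   "both_unmapped", "MR6")


def mr7_select_mapped(
    reads: ReadSet, source: AlignmentResult
) -> tuple[ReadSet, TransformMetadata]:
    """Keep only mapped reads; for paired data, only properly paired pairs."""
    if reads.paired:
        return _select(reads, source, lambda rec: rec.properly_paired,
                       "properly_paired", "MR7")
    return _select(reads, source, lambda rec: rec.mapped, "mapped", "MR7")


def mr8_boost_quality(
    reads: ReadSet, source: AlignmentResult, delta: int = DEFAULT_QUALITY_DELTA
) -> tuple[ReadSet, TransformMetadata]:
    """Raise every quality of every mapped read by ``delta`` Phred units,
    capped at Q41; sequences, order and unmapped reads untouched."""
    if delta < 1:
        raise TransformError("quality delta must be >= 1")

    def boost(read: ReadRecord) -> ReadRecord:
        if not _require_record(source, read).mapped:
            return read
        qual = "".join(
            chr(min(ord(c) - PHRED_OFFSET + delta, MAX_PHRED) + PHRED_OFFSET)
            for c in read.quality
        )
        return replace(read, quality=qual)

    out = ReadSet(reads1=tuple(boost(r) for r in reads.reads1),
                  reads2=tuple(boost(r) for r in reads.reads2),
                  paired=reads.paired)
    return out, TransformMetadata("MR8", _identity_map(out),
                                  params={"delta": delta})


def _correct_one(read: ReadRecord, rec: AlignmentRecord,
                 reference: Reference) -> ReadRecord:
    if not rec.mapped:
        return read
    contig_seq = reference.sequences[rec.contig]
    # Work on the aligned-orientation query, then restore read orientation.
    aligned = (read.sequence if rec.strand == "+"
               else reverse_complement(read.sequence))
    out = list(aligned)
    q = 0  # query cursor
    p = rec.pos - 1  # reference cursor (0-based)
    for n, op in cigar_ops(rec.cigar):
        if op == "M":
            out[q : q + n] = contig_seq[p : p + n]
            q += n
            p += n
        elif op == "S":
            q += n
        else:
            raise UnsupportedCigarError(
                f"read {read.name!r}: unsupported CIGAR op {op!r} in {rec.cigar!r}"
            )
    corrected = "".join(out)
    if rec.strand == "-":
        corrected = reverse_complement(corrected)
    return replace(read, sequence=corrected)


def mr9_correct_mismatches(
    reads: ReadSet, source: AlignmentResult, reference: Reference
) -> tuple[ReadSet, TransformMetadata]:
    """Select the mapped reads (properly paired pairs for paired data) and
    replace every base inside an aligned (M) segment by the reference base
    at its aligned position, strand-aware.  Qualities are untouched."""
    selected, _ = mr7_select_mapped(reads, source)
    out = ReadSet(
        reads1=tuple(_correct_one(r, _require_record(source, r), reference)
                     for r in selected.reads1),
        reads2=tuple(_correct_one(r, _require_record(source, r), reference)
                     for r in selected.reads2),
        paired=selected.paired,
    )
    return out, TransformMetadata("MR9", _identity_map(out))


# ---------------------------------------------------------------------------
# Relation checks
# ---------------------------------------------------------------------------

#: MRs whose relation is per-read identity over the follow-up domain.
_IDENTITY_MRS = {"MR1", "MR2", "MR3", "MR4", "MR5", "MR8", "MR9"}


def check_relation(
    mr_id: str,
    source: AlignmentResult,
    followup: AlignmentResult,
    meta: TransformMetadata,
    fields: tuple[str, ...] = DEFAULT_FIELDS,
    reference: Reference | None = None,
) -> MRReport:
    """Compute the verdict for one MR from the two alignment results.

    * MR1/MR2/MR3/MR4/MR5/MR8/MR9 — every follow-up record must equal its
      source record (via ``meta.name_map``) on the compared field set; for
      MR3 this covers originals and duplicates alike, for MR4/MR9 the
      comparison domain is the selected reads only.
    * MR6 — every follow-up record must be unmapped.
    * MR7 — every follow-up record must be mapped *and* at its source
      location (a moved multi-mapper is a failure: the published matrices
      score any difference between the alignments).
    * MR4 additionally reports the follow-up/source mean-coverage ratio
      when a reference is supplied (expected ~0.5).

    A follow-up key missing from ``name_map`` or from the source result is
    a harness error, not an MR failure.
    """
    if mr_id not in MR_IDS:
        raise HarnessError(f"unknown MR id {mr_id!r}")
    diffs: list[DiffEntry] = []
    for key, fu_rec in followup.records.items():
        name, role = key
        if name not in meta.name_map:
            raise HarnessError(
                f"{mr_id}: follow-up read {name!r} absent from name_map"
            )
        src_rec = source.get(meta.name_map[name], role)
        if mr_id == "MR6":
            if fu_rec.mapped:
                diffs.append(DiffEntry(key=key, source=src_rec,
                                       followup=fu_rec, fields=("mapped",)))
            continue
        if src_rec is None:
            raise HarnessError(
                f"{mr_id}: source alignment lacks record for "
                f"({meta.name_map[name]!r}, {role!r})"
            )
        if mr_id == "MR7" and not fu_rec.mapped:
            diffs.append(DiffEntry(key=key, source=src_rec,
                                   followup=fu_rec, fields=("mapped",)))
            continue
        differing = compare_records(src_rec, fu_rec, fields)
        if differing:
            diffs.append(DiffEntry(key=key, source=src_rec, followup=fu_rec,
                                   fields=tuple(differing)))
    coverage_ratio = None
    if mr_id == "MR4" and reference is not None:
        src_cov = mean_coverage(source, reference)
        if src_cov > 0:
            coverage_ratio = mean_coverage(followup, reference) / src_cov
    verdict = Verdict.FAIL if diffs else Verdict.PASS
    return MRReport(
        mr_id=mr_id,
        verdict=verdict,
        n_compared=len(followup),
        n_discordant=len(diffs),
        diffs=diffs,
        coverage_ratio=coverage_ratio,
    )


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MRCase:
    """An MR's identity, transformation and relation check.

    ``apply`` normalises the per-MR transform signatures: MR1 consumes the
    harness seed, MR5-MR9 the source alignment (and, where needed, the
    reference).  ``params`` carries per-MR overrides (``ext`` for MR5,
    ``delta`` for MR8, ``suffix`` for MR3).
    """

    mr_id: str
    needs_source_alignment: bool
    description: str

    def apply(
        self,
        reads: ReadSet,
        source: AlignmentResult | None = None,
        reference: Reference | None = None,
        seed: int = 0,
        params: dict | None = None,
    ) -> tuple[ReadSet, TransformMetadata]:
        params = params or {}
        if self.needs_source_alignment and source is None:
            raise HarnessError(f"{self.mr_id} requires the source alignment")
        if self.mr_id == "MR1":
            return mr1_permute(reads, seed)
        if self.mr_id == "MR2":
            return mr2_revcomp(reads)
        if self.mr_id == "MR3":
            return mr3_duplicate(reads, **params)
        if self.mr_id == "MR4":
            return mr4_halve(reads)
        if self.mr_id == "MR5":
            if reference is None:
                raise HarnessError("MR5 requires the reference")
            return mr5_extend(reads, source, reference, **params)
        if self.mr_id == "MR6":
            return mr6_select_unmapped(reads, source)
        if self.mr_id == "MR7":
            return mr7_select_mapped(reads, source)
        if self.mr_id == "MR8":
            return mr8_boost_quality(reads, source, **params)
        if self.mr_id == "MR9":
            if reference is None:
                raise HarnessError("MR9 requires the reference")
            return mr9_correct_mismatches(reads, source, reference)
        raise HarnessError(f"unknown MR id {self.mr_id!r}")

    def check(
        self,
        source: AlignmentResult,
        followup: AlignmentResult,
        meta: TransformMetadata,
        fields: tuple[str, ...] = DEFAULT_FIELDS,
        reference: Reference | None = None,
    ) -> MRReport:
        return check_relation(self.mr_id, source, followup, meta,
                              fields=fields, reference=reference)


MR_REGISTRY: dict[str, MRCase] = {
    "MR1": MRCase("MR1", False, "random permutation of reads"),
    "MR2": MRCase("MR2", False, "reverse complement of reads"),
    "MR3": MRCase("MR3", False, "addition (duplication) of reads"),
    "MR4": MRCase("MR4", False, "removal of half the reads"),
    "MR5": MRCase("MR5", True, "extension of mapped reads from the reference"),
    "MR6": MRCase("MR6", True, "re-mapping of unmapped reads"),
    "MR7": MRCase("MR7", True, "re-mapping of mapped reads"),
    "MR8": MRCase("MR8", True, "quality increase of mapped reads"),
    "MR9": MRCase("MR9", True, "correction of mismatches in mapped reads"),
}
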