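"""Field-wise equivalence of alignment records and coverage statistics.

A metamorphic relation never asks whether an individual alignment is
*correct* — it asks whether two alignments of related inputs agree.  This
module supplies that agreement test: a configurable field-wise record
comparison, the per-MR report object, and the mean-coverage statistic used
by the read-removal relation.

The default compared field set is (mapped, contig, pos, strand, cigar):
the mapping *location*.  MAPQ and the properly-paired flag are excluded by
default because they may legitimately change under several relations (a
mate's multi-mapping partner moving changes pairing without moving the
read itself).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

from .io_formats import (
    AlignmentRecord,
    AlignmentResult,
    Reference,
    cigar_reference_span,
)

__all__ = [
    "DEFAULT_FIELDS",
    "Verdict",
    "DiffEntry",
    "MRReport",
    "compare_records",
    "mean_coverage",
]

#: Default field set: the mapping location, as the relation checks compare it.
DEFAULT_FIELDS: tuple[str, ...] = ("mapped", "contig", "pos", "strand", "cigar")

_ALL_FIELDS = DEFAULT_FIELDS + ("mapq", "properly_paired")


class Verdict(str, Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    ERROR = "ERROR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def compare_records(
    a: AlignmentRecord,
    b: AlignmentRecord,
    fields: Sequence[str] = DEFAULT_FIELDS,
) -> list[str]:
    """Names of the selected fields on which two records disagree.

    Two unmapped records compare equal regardless of their residual null
    fields (SAM leaves them unspecified); a mapped/unmapped mismatch is
    reported as the single difference ``["mapped"]``.
    """
    for f in fields:
        if f not in _ALL_FIELDS:
            raise ValueError(f"unknown comparison field {f!r}")
    if not a.mapped and not b.mapped:
        return []
    if a.mapped != b.mapped and "mapped" in fields:
        return ["mapped"]
    return [f for f in fields if getattr(a, f) != getattr(b, f)]


@dataclass(frozen=True)
class DiffEntry:
    """One discordant read: both records and the fields that differ."""

    key: tuple[str, str]
    source: AlignmentRecord | None
    followup: AlignmentRecord
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("DiffEntry with no differing fields")


@dataclass
class MRReport:
    """Per-MR verdict plus per-read discordance details.

    ``coverage_ratio`` is populated only for the read-removal relation
    (follow-up mean coverage divided by source mean coverage).
    """

    mr_id: str
    verdict: Verdict
    n_compared: int
    n_discordant: int
    diffs: list[DiffEntry] = field(default_factory=list)
    coverage_ratio: float | None = None
    error: str | None = None

    def __post_init__(self) -> None:
        if self.verdict is not Verdict.ERROR:
            expect = Verdict.FAIL if self.n_discordant >= 1 else Verdict.PASS
            if self.verdict is not expect:
                raise ValueError(
                    f"{self.mr_id}: verdict {self.verdict} inconsistent with "
                    f"{self.n_discordant} discordant read(s)"
                )

    def to_row(self) -> dict:
        """Flat TSV-ready summary row."""
        return {
            "mr_id": self.mr_id,
            "verdict": str(self.verdict),
            "n_compared": self.n_compared,
            "n_discordant": self.n_discordant,
            "coverage_ratio": (
                "" if self.coverage_ratio is None else f"{self.coverage_ratio:.4f}"
            ),
        }

    def to_json(self) -> str:
        """Full report including per-read diffs, deterministically ordered."""

        def rec(r: AlignmentRecord | None) -> dict | None:
            if r is None:
                return None
            return {
                "read_name": r.read_name, "role": r.role, "mapped": r.mapped,
                "contig": r.contig, "pos": r.pos, "strand": r.strand,
                "cigar": r.cigar, "mapq": r.mapq,
                "properly_paired": r.properly_paired,
            }

        doc = {
            "mr_id": self.mr_id,
            "verdict": str(self.verdict),
            "n_compared": self.n_compared,
            "n_discordant": self.n_discordant,
            "coverage_ratio": self.coverage_ratio,
            "error": self.error,
            "diffs": [
                {
                    "key": list(d.key),
                    "fields": list(d.fields),
                    "source": rec(d.source),
                    "followup": rec(d.followup),
                }
                for d in sorted(self.diffs, key=lambda d: d.key)
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True)


def mean_coverage(result: AlignmentResult, reference: Reference) -> float:
    """Mean depth: aligned reference bases divided by total reference length.

    Only the reference span of each mapped record's CIGAR contributes.
    Records extending past their contig end raise ``ValueError``.
    """
    total = 0
    for rec in result:
        if not rec.mapped:
            continue
        if rec.contig not in reference.sequences:
            raise ValueError(f"record {rec.read_name!r}: unknown contig {rec.contig!r}")
        span = cigar_reference_span(rec.cigar)
        if rec.pos + span - 1 > reference.length(rec.contig):
            raise ValueError(
                f"record {rec.read_name!r} extends past end of {rec.contig!r}"
            )
        total += span
    return total / reference.total_length
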