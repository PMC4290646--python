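"""Suite orchestration: source run, transform, follow-up run, relation check.

The loop for one aligner and one dataset:

1. align the pristine source input once (the source alignment is cached and
   reused by every MR that needs it);
2. for each requested MR, apply its transformation to the pristine input,
   align the follow-up input, and check the expected relation;
3. collect per-MR reports into a :class:`SuiteResult` and render suites as
   the pass/fail matrix (rows = MRs, columns = runs, cells P/F/E).

An aligner crash during a follow-up run yields verdict ERROR for that MR
only — a harness/adapter event, never an MR violation — and the remaining
MRs still run.  All seeds are part of the configuration and echoed in the
run metadata: the harness exists to expose seed-scope bugs and must never
hide its own randomness.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .comparison import DEFAULT_FIELDS, MRReport, Verdict
from .io_formats import (
    ReadSet,
    Reference,
    write_read_set,
    write_sam,
)
from .metamorphic_relations import MR_IDS, MR_REGISTRY
from .toy_aligners import AlignerAdapter, AlignerError, ConfigError

__all__ = [
    "SuiteConfig",
    "SuiteResult",
    "run_suite",
    "render_matrix",
    "suite_to_tsv",
    "suite_to_json",
]


@dataclass(frozen=True)
class SuiteConfig:
    """What to run: which MRs, with which seeds, comparison fields and
    per-MR parameter overrides (e.g. ``{"MR5": {"ext": 20}}``)."""

    mrs: tuple[str, ...] = MR_IDS
    seed: int = 0
    fields: tuple[str, ...] = DEFAULT_FIELDS
    mr_params: dict = field(default_factory=dict)
    label: str | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.mrs:
            raise ConfigError("MR list must be non-empty")
        unknown = [m for m in self.mrs if m not in MR_IDS]
        if unknown:
            raise ConfigError(f"unknown MR id(s) {unknown}")


@dataclass
class SuiteResult:
    """One column of the pass/fail matrix plus run metadata."""

    label: str
    reports: dict[str, MRReport]
    metadata: dict


def _digest_reads(reads: ReadSet) -> str:
    h = hashlib.sha256()
    for rec in reads.iter_records():
        h.update(f"{rec.name}\n{rec.sequence}\n{rec.quality}\n".encode())
    return h.hexdigest()


def run_suite(
    reads: ReadSet,
    reference: Reference,
    aligner: AlignerAdapter,
    config: SuiteConfig | None = None,
) -> SuiteResult:
    """Run the requested MRs for one aligner on one dataset."""
    cfg = config or SuiteConfig()
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_read_set(
            reads,
            out_dir / "source_1.fastq",
            out_dir / "source_2.fastq" if reads.paired else None,
        )

    label = cfg.label or aligner.name
    started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    try:
        source_result = aligner.align(reads, reference)
    except AlignerError as exc:
        # Without a source alignment no relation can be checked at all.
        reports = {
            mr_id: MRReport(mr_id=mr_id, verdict=Verdict.ERROR, n_compared=0,
                            n_discordant=0, error=str(exc))
            for mr_id in cfg.mrs
        }
        return SuiteResult(label=label, reports=reports, metadata={
            "aligner": aligner.name, "seed": cfg.seed, "started": started,
            "source_error": str(exc),
        })
    if out_dir is not None:
        write_sam(source_result, reference, out_dir / "source.sam")

    reports: dict[str, MRReport] = {}
    for mr_id in cfg.mrs:
        case = MR_REGISTRY[mr_id]
        followup_reads, meta = case.apply(
            reads,
            source=source_result if case.needs_source_alignment else None,
            reference=reference,
            seed=cfg.seed,
            params=cfg.mr_params.get(mr_id),
        )
        if out_dir is not None:
            write_read_set(
                followup_reads,
                out_dir / f"{mr_id}_1.fastq",
                out_dir / f"{mr_id}_2.fastq" if followup_reads.paired else None,
            )
        try:
            followup_result = aligner.align(followup_reads, reference)
        except AlignerError as exc:
            reports[mr_id] = MRReport(mr_id=mr_id, verdict=Verdict.ERROR,
                                      n_compared=0, n_discordant=0,
                                      error=str(exc))
            continue
        if out_dir is not None:
            write_sam(followup_result, reference, out_dir / f"{mr_id}.sam")
        reports[mr_id] = case.check(source_result, followup_result, meta,
                                    fields=cfg.fields, reference=reference)
        if out_dir is not None:
            (out_dir / f"{mr_id}_report.json").write_text(
                reports[mr_id].to_json()
            )

    result = SuiteResult(
        label=label,
        reports=reports,
        metadata={
            "aligner": aligner.name,
            "seed": cfg.seed,
            "mrs": list(cfg.mrs),
            "fields": list(cfg.fields),
            "started": started,
            "input_digest": _digest_reads(reads),
            "n_fragments": len(reads),
            "paired": reads.paired,
        },
    )
    if out_dir is not None:
        (out_dir / "suite.tsv").write_text(suite_to_tsv(result))
        (out_dir / "metadata.json").write_text(
            json.dumps(result.metadata, indent=2, sort_keys=True)
        )
    return result


_CELL = {Verdict.PASS: "P", Verdict.FAIL: "F", Verdict.ERROR: "E"}


def render_matrix(results: list[SuiteResult]) -> pd.DataFrame:
    """Pass/fail matrix: rows = MRs, columns = suite runs, cells P/F/E."""
    if not results:
        raise ConfigError("render_matrix needs at least one suite result")
    rows = [m for m in MR_IDS if any(m in r.reports for r in results)]
    data = {
        r.label: [
            _CELL[r.reports[m].verdict] if m in r.reports else ""
            for m in rows
        ]
        for r in results
    }
    return pd.DataFrame(data, index=pd.Index(rows, name="MR"))


def suite_to_tsv(result: SuiteResult) -> str:
    """One row per MR: id, verdict, counts and (for MR4) coverage ratio."""
    frame = pd.DataFrame([result.reports[m].to_row() for m in result.reports])
    return frame.to_csv(sep="\t", index=False)


def suite_to_json(result: SuiteResult) -> str:
    """Full suite report with per-read diffs, deterministically ordered."""
    doc = {
        "label": result.label,
        "metadata": {k: v for k, v in result.metadata.items()
                     if k != "started"},
        "reports": {m: json.loads(result.reports[m].to_json())
                    for m in result.reports},
    }
    return json.dumps(doc, indent=2, sort_keys=True)
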