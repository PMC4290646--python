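"""Shared fixtures: tiny hand-built datasets and strategies for reads."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from mrtest import (
    AlignmentRecord,
    AlignmentResult,
    ReadRecord,
    Reference,
    SimConfig,
    ToyAligner,
    ToyAlignerConfig,
    make_reference,
    simulate_reads,
)

# ---------------------------------------------------------------------------
# hypothesis strategies
# ---------------------------------------------------------------------------

bases = st.text(alphabet="ACGTN", min_size=1, max_size=40)
qual_char = st.characters(min_codepoint=33, max_codepoint=33 + 41)


@st.composite
def read_records(draw, role: str = "single") -> ReadRecord:
    seq = draw(bases)
    qual = draw(st.text(alphabet=qual_char, min_size=len(seq),
                        max_size=len(seq)))
    name = draw(st.from_regex(r"[A-Za-z0-9_.:-]{1,12}", fullmatch=True))
    return ReadRecord(name=name, sequence=seq, quality=qual, role=role)


@st.composite
def alignment_records(draw) -> AlignmentRecord:
    name = draw(st.from_regex(r"[A-Za-z0-9_]{1,10}", fullmatch=True))
    role = draw(st.sampled_from(["single", "read1", "read2"]))
    mapped = draw(st.booleans())
    if not mapped:
        return AlignmentRecord(read_name=name, role=role, mapped=False,
                               mapq=draw(st.integers(0, 255)))
    length = draw(st.integers(1, 50))
    return AlignmentRecord(
        read_name=name, role=role, mapped=True, contig="ref1",
        pos=draw(st.integers(1, 951)),
        strand=draw(st.sampled_from(["+", "-"])),
        cigar=f"{length}M",
        mapq=draw(st.integers(0, 255)),
        properly_paired=draw(st.booleans()) if role != "single" else False,
    )


@st.composite
def alignment_results(draw) -> AlignmentResult:
    recs = draw(st.lists(alignment_records(), max_size=12,
                         unique_by=lambda r: r.key))
    return AlignmentResult.from_records(recs)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def small_reference() -> Reference:
    """A 60 bp hand-checkable single-contig reference."""
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    return Reference(sequences={"chr_t": seq})


@pytest.fixture(scope="session")
def sim_dataset():
    """A small repeat-rich simulated dataset shared across unit tests."""
    cfg = SimConfig(ref_length=20_000, repeat_length=500, n_reads=500, seed=1)
    reference, repeats = make_reference(cfg)
    reads, truth = simulate_reads(reference, cfg, repeats)
    return cfg, reference, repeats, reads, truth


@pytest.fixture(scope="session")
def lex_aligner() -> ToyAligner:
    return ToyAligner(ToyAlignerConfig(tie_break="lexicographic"))
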