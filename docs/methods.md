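# Methods

## The testing model

`mrtest` treats an aligner as a black-box function `A : (ReadSet,
Reference) → AlignmentResult`, where an `AlignmentResult` keeps exactly one
primary record per (read name, mate role) with the fields (mapped, contig,
1-based position, strand, CIGAR, MAPQ, properly-paired flag). Each
metamorphic relation (MR) is a pair: an input transformation `T` and a
predicate over `(A(S), A(T(S)))`. The harness runs the source input once,
caches that alignment, applies every requested transformation to the
*pristine* source input, aligns each follow-up set, and evaluates the
predicate. Caching the source run changes nothing for a deterministic
aligner, and every aligner the harness ships is deterministic given its
configuration.

Relations come in three shapes:

* **identity relations** (MR1, MR2, MR3, MR4, MR5, MR8, MR9): every
  follow-up record, routed through the transformation's name map, must
  equal its source record on the compared field set;
* **MR6**: every follow-up record must be unmapped;
* **MR7**: every follow-up record must be mapped *and* at its source
  location. The location clause matters: an order-sensitive tie-breaker
  keeps multi-mappers mapped while silently moving them, and a pass/fail
  matrix scored on "difference between the resulting alignments" must
  count that as failure.

One discordant read fails the relation. `PASS`/`FAIL` are MR verdicts;
`ERROR` (an aligner crash or missing output) is deliberately a third state
so that harness problems are never mistaken for MR violations.

### Compared fields

The default field set is `(mapped, contig, pos, strand, cigar)` — the
mapping location. MAPQ and the properly-paired flag are excluded because
they can legitimately change without any read moving: if a multi-mapping
mate is re-drawn, its uniquely-mapped partner keeps its location but loses
the proper-pair flag. The field set is configurable per suite. Two
unmapped records always compare equal; SAM leaves their residual fields
unspecified.

### Per-MR conventions

The published descriptions of several transformations leave freedom that
the implementation pins down once:

* **MR1** uses a seeded Fisher–Yates permutation (via
  `numpy.random.default_rng`); the same index permutation is applied to
  both mate files.
* **MR2** is implemented literally: reverse complement each read, reverse
  its quality string, reverse the order of reads within each file; mate
  roles are *not* swapped. Under this reading a correct ungapped aligner
  maps every read to the opposite strand, so MR2 fails for every aligner
  here — it encodes a desirable rather than necessary property, and the
  harness reports that honestly rather than redefining the relation.
* **MR3** renames duplicate copies with the reserved suffix `.dup` so SAM
  keys stay unique; the name map sends each copy to its original. A
  consequence worth knowing: a per-read-seeded tie-breaker that hashes the
  read *name* will fail MR3 on its multi-mappers, because the copies hash
  differently from the originals.
* **MR4** retains the even indices (0, 2, 4, …) of the original order —
  a deterministic "remove half" that makes the check reproducible. The
  0.5 coverage ratio is a reported statistic, not part of the verdict:
  per-read identity is exact, the halving claim is only statistical.
* **MR5** extends at the read's 3' end in read orientation (reference-right
  for `+` alignments, reverse complement of the upstream reference for
  `-`), appending quality `J` (Phred 41, the model's maximum). Extensions
  are truncated at contig boundaries. Because extension changes read
  length (and the leftmost coordinate of `-`-strand reads), MR5 fails on
  the default field set for any aligner — again a validation finding about
  the relation, preserved as such.
* **MR8** raises qualities by +5 by default, capped at Phred 41, on mapped
  reads only.
* **MR9** walks `POS` + CIGAR (`M` and `S` operations; anything else is an
  explicit unsupported-CIGAR error naming the read) and replaces every
  `M`-segment base with the reference base, strand-aware; it never relies
  on MD tags, which are optional in SAM.

## The toy aligner

Seed-and-extend, ungapped: candidate loci are the exact-index hits of the
read's first k-mer and of the first k-mer of its reverse complement
(k = 11 by default), each extended over the full read length and kept if
the substitution count is ≤ 3 (`max_mismatches`). The best hit is the
minimum-mismatch one; a unique best gets MAPQ 37, co-optimal bests go to
the tie-breaker and get MAPQ 0 — mirroring the convention that MAPQ 0
marks ambiguous placement, which is exactly what downstream filtering
keys on. CIGARs are all-M; indels would enlarge the aligner without
enlarging the relation-checking surface, and they would complicate both
the MR9 CIGAR walk and the brute-force oracle.

Mates are aligned independently; a pair is properly paired iff both map
to the same contig on opposite strands with outer span in
[`insert_min`, `insert_max`] = [100, 600] by default, chosen to bracket
the simulator's 300 ± 30 bp inserts with a wide margin.

### Tie-breaking modes

Candidate hits are first put in a canonical order (contig order in the
reference, then position, then `+` before `-`), so that every mode's
choice is reproducible given its seed:

* `lexicographic` — first hit of the canonical order. Invariant under any
  permutation, duplication or subsetting of the input file.
* `global_rng` — one `numpy` stream initialised from `global_seed` at the
  start of each run and consumed one draw per tie in read-processing
  order. Re-running the same file reproduces every choice, but any edit
  to the order or multiset of reads shifts the draw each multi-mapper
  receives. This reproduces the fixed-global-seed mechanism: failures are
  confined to MAPQ-0 reads by construction, since uniquely-mapping reads
  never consume a draw.
* `read_seeded_rng` — a fresh stream per read, seeded from
  `crc32(selected fields) XOR global_seed` where the selected fields are
  any subset of {name, sequence, quality}. A stable non-cryptographic
  digest suffices: the harness needs reproducibility and field
  sensitivity, not collision resistance. With quality in the digest, a
  quality-only perturbation (MR8) re-seeds multi-mappers and moves about
  half of them; with quality excluded, MR8 cannot move anything.

These modes reproduce the *mechanism* (seed scope and seed inputs) of the
real aligners' tie-breaking, not their actual generators, so pass/fail
signatures — not bit-level outputs — are the comparable quantity.

## The simulator

`make_reference` draws a uniform-random contig and copies `n_repeats`
segments verbatim to non-overlapping second loci (rejection placement;
the configuration is rejected up front if the reference cannot hold all
copies). Reads sampled wholly inside a repeat copy are guaranteed
multi-mappers; the repeat annotation is exported as 0-based half-open BED
and each read's truth record carries an `in_repeat` flag.

`simulate_reads` draws fragments uniformly, emits FR pairs with insert ~
Normal(300, 30) truncated to [read length, contig length], applies i.i.d.
substitution errors at 0.5% per base, and assigns qualities from a flat
Q39 baseline with sparse random decrements (10% of bases, 1–10 Phred).
Defaults — 100 kb reference, one 1 kb duplicated segment, 5,000 pairs of
100 bp reads — give ~10× coverage, ~2% of reads repeat-born (≈ 200
multi-mapping reads per run, enough that every order-sensitivity failure
is essentially certain), and run in seconds. What the simulator does
*not* model: indels, position-dependent error profiles, GC bias, chimeric
fragments, duplicate reads. Passing relations here therefore demonstrate
the harness and the tie-breaking mechanisms, not aligner sensitivity on
real data — the harness is precisely for pointing at real aligners via
the adapter template.

`plant_variants` substitutes chosen SNVs into a copy of the reference to
act as the sample genome; simulating from the mutated genome while
aligning against the original gives the variant caller known expected
alleles.

## Downstream caller

`pileup_call` piles up the aligned base of every mapped record with
`mapq ≥ min_mapq` and calls, per position, the plurality non-reference
base when depth ≥ 5 and its fraction ≥ 0.3. A depth/fraction plurality
vote is the minimal caller that exhibits the phenomenon of interest:
where repeat-born reads land decides which pile receives the planted
alleles, so an order-sensitive tie-breaker makes the source and
MR1-permuted alignments yield different call lists at `min_mapq = 0`,
while `min_mapq ≥ 1` excludes every ambiguously placed read and the lists
coincide exactly. The propagation experiment plants one SNV every 50 bp
inside the first repeat copy — dense enough that discordance at
`min_mapq = 0` is near-certain for any seed, sparse enough that reads
rarely accumulate more planted mismatches than the aligner tolerates.

## Numerical and reproducibility choices

* Every stochastic component (reference, reads, MR1 permutation,
  tie-break streams) takes an explicit integer seed, surfaced in the suite
  configuration and echoed in the run metadata; re-running a suite with
  the same seeds is byte-identical in every verdict and diff.
* `scripts/acceptance.py` derives independent sub-seeds from its single
  `--seed` via `numpy.random.SeedSequence` and reruns the full pipeline at
  the default study scale (~20 s on one core).
* The brute-force oracle used in testing scans every position on both
  strands of a ≤ 2 kb reference; oracle reads carry their planted errors
  strictly between the first and last k bases so the seeding heuristic is
  exercised without being defeated — seed sensitivity is a deliberate
  non-goal of the toy aligner.
* Degenerate inputs: reads shorter than k are unmapped, not errors; MR6 on
  a dataset with no fully-unmapped pairs produces an empty follow-up set
  and a vacuous PASS; an `N` base never matches and so counts as a
  mismatch everywhere.

## Known limitations

* SAM text only; BAM/CRAM inputs must be converted (e.g. `samtools view
  -h`) inside an adapter template. Secondary/supplementary lines are
  dropped at ingest, so multi-hit reporting is represented only by which
  single location the aligner chose.
* The toy aligner is ungapped and single-seeded; it is a mechanism
  instrument, not a usable aligner.
* MR2's mate-role handling (no swap) and MR5's 3'-end choice are single
  documented readings of ambiguous prose; both relations fail for every
  aligner under these readings, and the harness treats that as information
  about the relations rather than the aligners.
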