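# mrtest — metamorphic testing for short-read sequence aligners

Short-read aligners have no practical test oracle: for a real FASTQ file
nobody can say which BAM is "the correct one", so conventional testing
cannot tell a sound aligner from a subtly broken one. `mrtest` applies
**metamorphic testing** to this problem. Instead of judging a single run,
it transforms the input reads in a way whose effect on a correct aligner's
output is predictable, reruns the aligner, and checks the predicted
relationship between the two outputs. Any violated relation is a concrete,
reproducible counterexample to a user expectation — no gold standard
required.

The package is for bioinformaticians and pipeline engineers who want to
regression-test an aligner (or a wrapper around one) the way its users
implicitly expect it to behave.

## The nine metamorphic relations

For a source read set *S* with alignment *A(S)*, each relation MRk supplies
a transformation *T_k* and an expected relation between *A(S)* and
*A(T_k(S))* (compared on mapping location: mapped flag, contig, position,
strand, CIGAR):

| MR  | transformation                              | expectation |
|-----|---------------------------------------------|-------------|
| MR1 | random permutation of reads (same for mates)| identical mapping per read |
| MR2 | reverse complement, qualities reversed, file order reversed | identical mapping |
| MR3 | every read duplicated (copies renamed)      | originals and copies map like the originals |
| MR4 | half the reads removed                      | retained reads unchanged; coverage ratio ≈ 0.5 |
| MR5 | mapped reads extended 20 bp from the reference at high quality | identical mapping |
| MR6 | unmapped reads re-mapped                    | nothing maps |
| MR7 | mapped (properly paired) reads re-mapped    | everything maps, at the same location |
| MR8 | qualities of mapped reads raised            | identical mapping |
| MR9 | mismatches in mapped reads corrected from the reference | identical mapping over the selected reads |

A single discordant read fails a relation.

## Built-in faulty aligners

Real aligners break these relations through the *scope of the random seed*
used to pick among co-optimal loci for multi-mapping reads. The package
ships a deterministic seed-and-extend toy aligner with three tie-breaking
modes that isolate exactly that mechanism:

* `lexicographic` — canonical first hit; a pure function of read content
  (the correct behaviour);
* `global_rng` — one stream seeded per run, consumed in read order:
  reruns are identical, but reordering the file silently moves MAPQ-0
  reads (the BWA-style mechanism — fails MR1/MR3/MR4/MR7);
* `read_seeded_rng` — stream re-seeded per read from a digest of name,
  sequence and (optionally) quality: order-invariant, but quality-sensitive
  when quality is in the digest (the Bowtie-style mechanism — passes MR1,
  fails MR8).

A repeat-rich read simulator guarantees multi-mappers exist, and a naive
pileup variant caller demonstrates that the discordance propagates into
variant calls until MAPQ-0 reads are filtered out.

## Worked example

```
mrtest simulate --ref-length 20000 --repeat-length 500 --n-reads 400 --seed 3 --out data
mrtest run --ref data/reference.fa --reads1 data/reads_1.fastq --reads2 data/reads_2.fastq \
           --aligner toy-lex        --seed 5 --out run_lex
mrtest run --ref data/reference.fa --reads1 data/reads_1.fastq --reads2 data/reads_2.fastq \
           --aligner toy-global-rng --seed 5 --out run_global
mrtest report run_lex/suite.json run_global/suite.json
```

prints (P = pass, F = fail):

```
    toy-lexicographic toy-global-rng
MR
MR1                 P              F
MR2                 F              F
MR3                 P              F
MR4                 P              F
MR5                 F              F
MR6                 P              P
MR7                 P              F
MR8                 P              P
MR9                 P              F
```

The order-sensitive tie-breaker fails every relation that changes read
order or multiset (MR1 reported `12/800` discordant reads, all MAPQ 0),
while the content-pure tie-breaker passes them. MR2 and MR5 fail for
*both* aligners: reverse-complemented reads legitimately map to the
opposite strand and extended reads change length and position, so these
two encode desirable rather than necessary expectations — a validation
finding, not an implementation bug. Per-read diffs for every cell are in
`run_*/MR*_report.json`, with all intermediate FASTQ/SAM retained for
audit.

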