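# Methods

## Model and procedure

seedex is a two-stage seed-and-extend aligner.  The central engineering
idea is that the search-space construction — deciding *where* to attempt
alignment — is expressed as a short pipeline of deterministic list
operations over 64-bit packed candidate values: diagonal adjustment, sort
and deduplication, coverage counting, paired-end filtering, exclusion of
previously examined loci, prioritization, and window coalescing.  Each
operation is a pure function of its inputs, so the sequential
implementation is order-deterministic and independently testable against
set/sort/interval oracles.

### Sequence representation

DNA is packed 21 three-bit symbols per 64-bit word, filled from low- to
high-order bits; bit 63 is unused and trailing bits of the last word are
forced to zero so word equality equals sequence equality.  Base codes set
the high bit and carry the conventional 2-bit base code below
(`A=100, C=101, G=110, T=111`); `N` is all-zero so it matches nothing —
including another `N` — under symbol comparison.  A per-symbol code array
is cached alongside the packed words for fast slicing.

### Seeds and keys

* **Spaced seed (nongapped stage).** The 7-periodic pattern `0010111`
  repeated across an 84 nt span gives 48 care positions.  The don't-care
  residues {0, 1, 3} mod 7 form a perfect difference set, which is why
  probing at 7 adjacent offsets detects every ≤2-mismatch gapless mapping
  (the suite re-derives this equivalence and verifies sensitivity by
  exhaustive enumeration; three mismatches can escape).  The lookup key is
  MurmurHash3 (x86 32-bit, fixed hash seed recorded in the index header)
  of the care-position codes, truncated to 30 bits.  Hashing rather than
  literal bit-packing keeps the care set configurable while preserving the
  two properties that matter: the key depends on care symbols only, and
  keys live in a 30-bit space.
* **Contiguous seed (gapped stage).** 20-mers, packed into a 64-bit word
  and hashed the same way to 30 bits.  Any seed containing `N` emits no
  key: a wildcard key would create false buckets that the downstream
  verification would only have to discard.

MurmurHash3 is implemented in-package (scalar and numpy-vectorised over
fixed-width rows); the tests check it against an independent
reference implementation.

### Index

One H/J table pair per stage.  Every valid seed position of every
reference sequence contributes one J entry (forward strand only —
reverse-strand candidates come from seeding the read's reverse
complement, which halves the index).  J is sorted by (key, subId, pos);
H is logically one slot per possible 30-bit key but stored sparsely — the
contract is behavioural, not a memory layout.

**Big-bucket sampling.** Let a position be "big" when its key's list is
longer than the threshold (default 128).  Within each maximal run of
consecutive big positions, only positions congruent to the run start
(mod interval, default 10) keep their entry.  Anchoring at the run start
makes the ≤ interval retained-gap guarantee provable, and the retained
count in a length-L run is exactly ⌈L/10⌉.  The cost is that a read from
a sampled region must be seeded at up to 10 adjacent offsets to be
guaranteed a hit — which the gapped stage's iterative schedule provides.

### Candidate engine

Candidates pack (strand, subId, diagonal position, coverage, flags) into
one 64-bit integer whose natural ordering is lexicographic
(strand, subId, dpos).  The diagonal `dpos = pos − seed_offset` collapses
all seeds of one gapless alignment onto a single value; coverage counts
how many distinct seeds voted for a locus and drives prioritization.
Paired-end filtering flags loci that have a distance/orientation-
compatible locus in the other mate (fragment length measured
rightmost-end minus leftmost-start, the SAM TLEN convention); flagged
loci outrank unflagged ones at equal coverage.  Window coalescing merges
diagonals on one (strand, subId) that differ by at most a "wobble" slack,
set by default to the longest gap a reportable alignment can afford,
(match·read_len + gap_open − Vt)/(−gap_extend) — 31 nt at the defaults
for 100 nt reads — since a gap shifts the diagonal by at most its length.

### Nongapped verification and soft clipping

Verification compares the whole read against the reference window at the
candidate diagonal.  Per-position contributions (+2 match, −6 mismatch,
a forcing penalty beyond the reference boundary) are fed to a maximum-sum
contiguous-segment scan, which *is* the optimal terminal-clip choice for
gapless alignments (the suite checks this against brute force over all
clip pairs).  The mismatch ceiling (default 2) applies to the retained
interior only: clipped terminal errors — the sequencing-error case soft
clipping exists for — do not count against it.

### Gapped extension

Smith–Waterman–Gotoh local alignment with affine gaps (open −5,
extend −3 per base, i.e. a length-L gap costs 5+3L) and full traceback to
CIGAR, with unaligned read ends emitted as soft clips.  Ties prefer the
diagonal (fewer gaps) and the leftmost reference end; the best-cell rule
is max score, then smallest window column, then smallest read row — fully
deterministic.  The implementation is a tight pure-Python cell loop over
desk-scale windows (~100×260 at the defaults); the suite proves score
equality against an independently written full-matrix Gotoh oracle and
re-scores every emitted CIGAR/MD to the reported AS.

The seed schedule tiles the read without overlap in iteration 1 (last
seed anchored at read_len − seed_len), then repeatedly inserts midpoints
between all previously examined offsets until every offset is scheduled —
for 20-mers in 100 nt: offsets {0,20,40,60,80}, then 4, 8, 16, 32 and 16
more across six iterations, covering all 81 offsets exactly once.  The
exact straddling rule near read boundaries is under-specified in general;
the integer-midpoint rule used here is one consistent reading and is
pinned by tests.  A read leaves the loop once `max_satisfactory` mappings
with AS ≥ Vt exist; `max_candidates` per iteration (default 32) is the
throughput/sensitivity dial, and raising it never loses a mapping found
at lower effort (tested).

### MAPQ

The two models implement the documented ranges and tie behaviour; no
published closed form exists for either inspiration, so the formulas are
this package's own and are recorded in the SAM @PG line:

* **Model A (0–60):** ties ⇒ min(3, round(−10·log₁₀(1 − 1/k))); otherwise
  4 + 56·(best − second)/(perfect − Vt), with an absent second-best
  treated as a competitor at Vt.  The +4 floor keeps any uniquely-best
  mapping above any tied one and makes MAPQ monotone in the score gap.
* **Model B (0–44):** a bucket table over the same normalized quantities;
  unique high-scoring ⇒ 44, tied best ⇒ 0 or 1.

The model-input structure carries an optional `vt` field (defaulting to
read length, which matches Vt = 100 at 100 nt) because the normalization
needs the reporting threshold.

### Pipeline and SAM

Reads are processed in batches; batching is purely a memory-bounding
contract and the output is byte-identical for any batch size (tested).
A read enters the gapped stage iff its satisfactory nongapped mapping
count is below the configured minimum (default 1).  Primary-mapping
choice for pairs prefers concordant combinations (same subId, configured
orientation, TLEN in range) over raw score sums.  Records carry AS/NM/MD;
MD and NM are built from the traceback and re-scoring CIGAR+MD under the
scoring parameters reproduces AS exactly (shared round-trip oracle with
the evaluation module).  Output is plain SAM, parsed back with pysam in
the tests.

## Synthetic data and what passing tests show

The simulator draws uniform-ACGT references (optionally with planted
tandem repeats for the sampling tests), uniform fragment positions,
Gaussian fragment lengths (default 350 ± 50), FR orientation, per-base
substitutions (default 1%) and 1–3 nt indels (default 0.1%/base), and
records each read's true origin and CIGAR.  It is deliberately simpler
than a full error-model simulator: errors are uniform, qualities carry no
information, and coverage biases, adapter contamination and large
structural variation are absent.  Passing the benchmark (≥99% of reads
correct within 3 nt on a repeat-free 50 kb reference) therefore
demonstrates the correctness of the seeding/extension machinery under the
stated error model, not performance on real genomes with heavy repeat
content or biased error profiles.

Suite problem sizes — 50 kb references, hundreds of read pairs, 10⁴
small DP instances against the brute-force oracle plus a layer up to
~120×260 — were chosen so the full suite runs in well under a quarter
hour on one CPU while still exercising every contract at meaningful
scale.

## Numerical and design choices

* Symbol codes are forced by the worked encoding example; `N=0b000` is an
  inference (any code with the high bit clear would do; all-zero also
  makes padded words self-consistent).
* The stated "30 care positions" for the spaced seed cannot be reconciled
  with pattern 0010111 over span 84 (48 one-bits); the care set is all
  pattern-1 positions and 30 bits refers to the key width here.
* Candidate bit widths (7-bit subId, 31-bit dpos, 8-bit saturating
  coverage, 16 flag bits) are this implementation's layout; only the
  ordering contract matters.
* The gapless soft-clip example score of a 100 nt read with one terminal
  mismatch: clipped 99M1S = 198 beats unclipped 100M = 192; a 2 nt
  deletion with perfect 49/49 flanks scores 98·2 − (5 + 2·3) = 185.
* Degenerate inputs: empty reads and windows return no alignment; reads
  shorter than the spaced-seed probe span skip straight to the gapped
  stage; a reference sequence shorter than the seed span contributes no
  index entries (warning); index/reference mismatch is detected by a
  SHA-256 digest and refuses to align.
* Determinism: every tie-break is by packed-value or coordinate order;
  the simulator uses a single seeded generator; two identical runs are
  byte-identical.

## Known limitations

Pure-Python DP limits throughput to desk scale (roughly 10²–10³ reads/s
on one core depending on error content); there is no BAM/CRAM output,
no spliced or bisulfite mode, no quality-aware mismatch weighting, and
MAPQ is not recalibrated against ground truth.  Paired-end rescue
(aligning a mate by local search near its partner) is not implemented;
discordant pairs are reported as such.
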