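# Methods

## Mapping model

`fanseq` maps single-end reads to a reference by exact-match seeding and
local refinement, iterated over decreasing seed lengths.

**Coordinates.** All internal coordinates are 0-based, half-open; conversion
to 1-based happens only when SAM records are emitted.

**Segmentation.** Each reference sequence is tiled with segments of
`segment_size` (default 50 Mb) stepping by `segment_size − overlap`.  The
overlap defaults to the maximum read length in the batch plus `2·I`
(`I` = indel allowance), so that the refinement window of any candidate —
including the `±I` band padding — is wholly contained in at least one
segment.  A candidate whose padded window crosses an interior segment
boundary is rejected in that segment and found intact in the neighbouring
one; de-duplication on global `(source, pos, strand)` then removes the
double counting.  This is what makes the output provably invariant to the
segment size, the segment processing order and the worker count, and it is
why segments can be dispatched to worker processes with no shared state.

**Seed index.** For each segment and seed length *n*, every *n*-mer over
{A,C,G,T} is 2-bit packed and stored as a (value, global position) array
sorted by value; a query is two binary searches (`numpy.searchsorted`), and
queries for all seeds of all pending reads are batched into single
vectorised calls.  *n*-mers containing any non-ACGT symbol are not indexed
and never used as query seeds, so hard-masked (N) regions are skipped;
soft-masked lower-case bases are upper-cased first.  The packing is an
implementation detail: the dict-style `to_dict()` view and the packed
lookup agree, which the tests assert by full scan on small segments.

**Seed placement.** A read of length *L* yields non-overlapping tiling seeds
at offsets 0, *n*, 2*n*, …, plus one end-anchored seed at *L−n* when *L* is
not a multiple of *n*.  Non-overlapping tiles are what the pigeonhole
guarantee needs (*f* errors cannot dirty *f*+1 disjoint seeds); the end
anchor recovers coverage of the tail remainder.

**Hotspots.** Every exact match at position *p* of a seed with read offset
*i* votes for candidate start *p − i*; negative starts are discarded.  Votes
are accumulated per (strand, start); with indel detection on, starts within
`I` of each other merge into one hotspot represented by the minimum start.
Hotspots are refined in support-descending order (ties: smaller start first,
then `+` before `−`) up to `max_hotspots_refined` (default 1024) per read
per segment, a cap that only matters for pathological repeats.

**Refinement.**
- *Indels off* (`I = 0`): Hamming distance between the read and the
  reference window; accepted iff ≤ `E`.  Reference N never matches anything,
  including a read N (the two are encoded as distinct symbols).
- *Indels on* (`I ≥ 1`): banded unit-cost edit alignment (mismatch = 1,
  each inserted/deleted base = 1) over the window padded by `I` on both
  sides, band half-width `I`.  The DP state is (read prefix, window prefix,
  indel bases used ≤ `I`) with the minimal mismatch count as value, so the
  acceptance rule — mismatches + indel bases ≤ `E` *and* indel bases ≤ `I` —
  is evaluated exactly rather than approximated by a single combined score.
  Leading/trailing window bases are free (semi-global), which is how the
  reported start may shift by up to `I` from the hotspot diagonal.
  Among equal-cost solutions the DP prefers fewer indel bases, then the
  leftmost end cell; traceback resolves remaining ties in the fixed order
  insertion → diagonal → deletion, giving a deterministic CIGAR (e.g. a
  1-nt insertion inside a CC run reports as `3M1I4M`).

**Best location.** Candidates from all segments are de-duplicated and the
minimal-error set retained.  One location is reported: the lexicographically
smallest `(source, pos, strand)` with `+` ordered before `−`; `unique` is
true iff no other location ties the minimal error count.  Reporting one
location plus a uniqueness flag (rather than all ties) keeps the output a
function of the read and reference alone and supports downstream
unique-only filtering.

**Step-down loop.** Stages run at seed lengths `initial_seed`,
`initial_seed − step`, … down to the floor `S` (defaults 14, step 2,
S = 12), each stage mapping only the reads left unmapped by earlier stages;
a mapped read is never revisited, so adding stages can only add mappings.
Reads shorter than the current seed length simply produce no seeds and are
deferred to shorter-seed stages.  Per-stage tallies (reads mapped, reads
remaining) are recorded and logged.

## Read preprocessing

Applied before mapping, in this order, each rule idempotent: (1) truncate at
the first base with Phred quality < 20 (FASTQ offset 33 by default, +64 by
flag); (2) discard reads shorter than 18 nt; (3) discard reads whose longest
homopolymer run or longest period-2 (dinucleotide-unit) tandem repeat is
strictly longer than half the read length, with half computed exactly (a
10-of-20 run is kept, 11-of-20 discarded).  The period-2 scan subsumes
homopolymers, which is harmless since the rule is a disjunction.
Preprocessing only trims or removes reads — bases are never edited.  A
`--no-qc` flag disables all three rules.

## Seed-length theory

`max_guaranteed_errors(L, n) = ⌊L/n⌋ − 1` is the largest substitution count
for which a clean seed is guaranteed.  (Note one apparent inconsistency in
the motivating literature: 75-nt reads with 14-nt seeds are sometimes quoted
as guaranteeing 5 errors, but the formula — which the implementation and the
exhaustive tests obey — gives ⌊75/14⌋ − 1 = 4.)

`miss_rate_given_f(L, n, f)` is the probability that *f* distinct,
uniformly placed substitutions hit every seed.  The error-placement model
(uniform without replacement) is a modelling choice; the seed set is exactly
the mapper's (`seed_offsets`), so the theory predicts the implementation.
The default evaluator is exact inclusion–exclusion over seed subsets
(feasible whenever the read has ≤ 20 seeds; union sizes from interval
merging), with a vectorised Monte Carlo estimator for larger seed sets;
tests cross-check both against brute-force enumeration of all C(L, f)
placements.

`predicted_mappable_fraction(L, p, E) = P(Binomial(L, p) ≤ E)` links the
per-base error rate to an upper envelope for sensitivity; at L = 75, E = 7
it gives 99.99% for p = 0.02 and 98.98% for p = 0.04, which the simulated
runs approach to within their seeding miss (~0.1 percentage points at 4%).

## Simulator

`simulate_reads` draws start positions uniformly over valid windows, picks
the reverse strand with probability `strand_mix` (default 0.5), substitutes
each base independently with `sub_rate` (always to a different base), and
optionally injects 1-nt insertions/deletions at `indel_rate` per base.
Constant Q40 qualities are emitted so the Q20 truncation rule is neutral on
simulated data.  Reads failing the low-complexity rule are removed together
with their truth records.  The defaults (75-nt reads; 2%/4% substitution
conditions; no indels) mirror the simulated benchmark conditions this
package targets.  What the simulator deliberately does *not* model:
platform-specific quality profiles, position-dependent error rates,
coverage bias, polymorphism between sample and reference, or spliced reads
— so passing tests demonstrate algorithmic correctness under the stated
error model, not end-to-end performance on any particular instrument's data.

## Evaluation and quantification

`classify` compares results to truth with a position tolerance (default 0;
a tolerance of `I` is recommended when indels are injected, since the
reported start may legitimately shift).  Reads dropped by preprocessing
before mapping are absent from both reads and truth and so excluded from
the denominator.  `quantify_genes` counts reads per gene after merging
splice variants via a transcript→gene table, uses the longest variant as
the effective gene length (a `mean` mode is provided, since variant-merged
length handling is a free choice), computes
rpkM = count / ((length/1000)·(total/10⁶)), and drops genes with fewer than
10 reads.  Multi-mapped reads count at their single reported location by
default; a `unique_only` switch drops them.

## Problem sizes and numerical choices

The packaged experiments run at desk scale: sensitivity conditions use a
5-Mb i.i.d. random genome and 20,000 reads per error rate (the binomial
error-count distribution, which drives sensitivity, is independent of
genome size once reads are effectively unique, and 20,000 reads give a
standard error below 0.08 percentage points at 99% sensitivity);
determinism checks use a 2-Mb genome with 0.5/1/5-Mb segment sizes and 1, 2
and 4 workers; oracle equivalence uses 1,000 read/window pairs up to 50 nt.
The exhaustive pigeonhole check covers all ~2.3 million error placements
for read lengths ≤ 30 at seed lengths 4 and 6.

Known limitations: single-end only; no spliced alignment; no
quality-aware scoring; the banded DP is quadratic in the indel allowance
and intended for small `I` (the standard setting is `I = 1`); hotspot-cap
truncation can in principle (repeat-heavy references, cap exceeded) break
segment-size invariance, though never observed under the test conditions.
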