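# Methods

This note documents the models and procedures implemented in crisprdesk,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Candidate model

A CRISPR-Cas9 target site is a 23-nt footprint: a 20-nt spacer, one
arbitrary base, and the GG of the SpCas9 NGG PAM. Extraction scans both
strands of a normalized sequence (uppercase, U→T, anything else → N) at
*every* offset; the common regex behaviour of resuming after a match would
silently drop overlapping sites, which are real targets, so lookahead
matching is used. Reverse-strand sites appear on the forward strand as
`CC·N21` and are reported as their reverse complement with the start of
their forward-strand footprint (0-based, half-open — BED convention).
Windows containing N are excluded at extraction, not at parsing: I/O is
lossless and the biology policy lives in one place. Consequence: a 2-bit
code can represent every emitted spacer.

Gene candidates are kept per locus (results are per-site); genome-wide
spacers are deduplicated to (sequence → occurrence count) for indexing,
because the index is per-sequence and the count is what scoring needs.

## Off-target search: inverted signature slice lists

Spacers are packed 2 bits/base (A=0, C=1, G=2, T=3, leftmost base most
significant) into 40-bit codes. The code is split into `num_slices` equal
slices; for each slice position an inverted table maps slice signature →
sorted spacer list. Query: gather the buckets matching the query's
signatures, then verify each candidate's full Hamming distance (XOR, fold
odd/even bits, popcount).

Correctness rests on the pigeonhole principle: a neighbour at distance
`m < num_slices` cannot have a mismatch in every slice, so it is found in
at least one bucket. The default is therefore 5 slices × 4 bases for the
default `max_mm = 4` — the minimal configuration with the exact-recall
guarantee; a query bound with `max_mm ≥ num_slices` is rejected as a
configuration error rather than silently losing recall. Results are sorted
by (distance, encoded value) so every downstream artifact is reproducible.

The index serializes to a little-endian binary file (magic `ISSLIDX1`,
header, value/count arrays, per-slice signature tables) with a text dump
mode for debugging; loading is verified to reproduce in-memory query
results exactly.

## Off-target scoring

No single canonical aggregation exists at this package's scale, so the
classical multiplicative single-hit penalty was chosen: a hit with
mismatched positions `P` scores `100 · Π_{p∈P} (1 − w_p)` and a guide's
specificity is `10000 / (100 + Σ hits)`. Two weight vectors ship:

- `uniform`: `w_p = 0.5` everywhere — every expected value in the tests is
  a closed form (one mismatch halves a hit, etc.);
- `literature`: the position-dependent experimentally derived weights of
  Hsu et al. 2013 (positions 1–20, PAM-distal to PAM-proximal), the de
  facto standard penalty vector.

Exactly one distance-0 occurrence of the query is excluded as the intended
on-target site. Additional exact copies are counted as off-targets: a
guide whose sequence occurs twice in the genome cuts twice and must be
penalized (one duplicate → specificity 50). Only the 20-nt spacer enters
the distance; the PAM is not compared (standard SpCas9 practice; the
index stores spacers only). Bulges/indels and PAM-variant scoring are out
of scope.

## On-target consensus

Three independent, auditable sequence rules vote; acceptance needs
`consensus_threshold` (default 2) of 3. The defaults are this package's
own rule set — simple, pure functions of the target sequence, pluggable
behind a common interface so alternative published scorers can be
substituted:

- **g20** — spacer position 20 (PAM-proximal) is G. Default: active
  guides are enriched for a G adjacent to the PAM.
- **composition** — GC fraction in [0.30, 0.70] (inclusive at both ends)
  and no `TTTT` run: extreme GC impairs binding; poly-T terminates Pol III
  transcription of the guide.
- **structure** — no pair of non-overlapping substrings of length ≥ 6
  that are exact reverse complements (a self-hairpin would fold the
  spacer). Checking all 6-mer pairs is exhaustive because any longer stem
  contains a disjoint 6-nt sub-stem.

All three methods always run — no short-circuiting once the vote is
decided — so every per-method boolean is recorded for audit.

## Orchestration contract

The engine reproduces a function-as-a-service execution model locally:

- **Queues** — `genome_fetch`, `index_build`, `ontarget`, `offtarget`,
  FIFO tables in a single SQLite file (durable across CLI invocations;
  `:memory:` for throwaway runs).
- **Statelessness** — handlers read everything from the message payload
  and the shared stores; nothing is retained between invocations.
  Off-target messages carry a candidate reference, never index data; the
  index is a shared read-only store.
- **Idempotency** — the key is (queue, canonical payload). A re-delivered
  message whose key is already processed completes without re-running its
  handler, so double delivery provably leaves results unchanged.
- **Batching** — per-queue batch sizes (defaults: fetch 1, index build 1,
  on-target 100, off-target 10; all configurable). Fetch and index tasks
  are heavyweight singletons; assessments are cheap and batched.
- **Limits** — per-invocation wall-clock budget (default 900 s) enforced
  by checkpoint-and-requeue: when the budget expires mid-batch the
  remaining messages return to the queue untouched. The clock is
  injectable, so the behaviour is tested with a fake clock rather than
  real sleeps. The memory ceiling (default 10 GiB) and concurrency cap
  (default 1000) are recorded and validated but not actively metered —
  desk-scale fixtures never approach them, and rss accounting would be
  dead weight.
- **Retries** — a handler exception releases the message for redelivery
  while its delivery count is within the retry cap (default 3); beyond it
  the message is dead-lettered and the job fails with the recorded cause.
- **Scale-from-zero** — draining returns immediately (zero worker
  invocations) when the queues are empty; instrumentation counters verify
  no idle worker activity.
- **Determinism** — results are keyed by (job, record, start, strand) and
  each assessment writes a pure function of its candidate and the shared
  index, so the final table is byte-identical across batch sizes, worker
  counts and interleavings. This is asserted end-to-end over six
  schedules plus forced double delivery.

Genomes above `chunk_bytes` are fetched as byte-range portions and merged
before parsing. "50 megabytes" is taken as binary (50·2²⁰) and the same
constant is both the split threshold and the portion size — one
configurable knob; the threshold is strict ("larger than"), so a file of
exactly one chunk is fetched whole. Chunking operates on raw bytes;
extraction and indexing only ever run on the merged whole, so no site can
straddle a portion boundary. Job statuses advance monotonically
(`submitted → preparing_genome → indexing → assessing → complete`, with
forward skips on warm runs and `failed` reachable from any non-terminal
state). Partial results are visible before completion and flagged
per-record via `both_complete`.

## Synthetic fixtures

The generators produce every input the pipeline needs, deterministically
from a seed:

- **Random genomes** — i.i.d. bases with `P(G)+P(C) = gc_fraction`
  (default 0.5, 10–20 kb in the shipped tests: large enough that a 20 kb
  genome yields ~2500 distinct spacers, small enough that brute-force
  oracles run in seconds). No repeat structure by default; a tandem-repeat
  helper exists for stress tests because repetitive, GC-skewed genomes
  concentrate near-identical spacers into shared index buckets.
- **Planted sites** — a spacer mutated at *exactly* `d` positions (each
  mutated base forced to differ, distance re-verified by direct
  comparison before use) written as `spacer + TGG`, giving the extractor a
  forward candidate at a known locus. `plant_offtarget_family` places one
  site per requested distance on a fixed stride.
- **Exact-count genes** — `n` blocks of `spacer + TGG` where spacers and
  junctions are free of GG/CC dinucleotides, so each block contributes
  exactly one forward site and the sequence has no reverse-strand site.
  The guarantee is checked by the extractor itself, across
  `n ∈ {1, …, 10000}`.

What passing on these fixtures shows: exact neighbour recall, exact
extraction, schedule-invariant orchestration, and correct arithmetic.
What it does not show: behaviour on real chromosomes (repeats, assembly
gaps, biased composition change bucket-occupancy distributions and
therefore speed, not correctness), nor biological validity of the default
on-target rules, which are stand-ins chosen for auditability.

## Problem sizes and tolerances

Tests and the acceptance script use 10–20 kb genomes, 1 kb random
sequences (1000 of them for the extraction oracle), 200 off-target
queries × mismatch bounds 0–4, and gene fixtures up to 10,000 guides —
sizes chosen so every independent oracle (naive scanning, brute-force
Hamming enumeration) completes in seconds while remaining statistically
non-trivial. All oracle comparisons are exact set/sequence equality; score
checks use closed forms under uniform weights; the only sampling tolerance
is the genome GC check (±2% on 100 kb, comfortably above binomial noise).

## Known limitations

- Single-PAM (NGG) extraction; alternative PAMs are an extension point.
- No ambiguous-base expansion: N kills a site rather than enumerating it.
- In-memory index; genomes ≫ 1 Gb would want a disk-mapped layout.
- The HTTP facade is a development convenience (stdlib server, no auth,
  single host), not a deployment surface.
- Checksums of fetched portions are not verified; the merge contract
  checks lengths and coverage only.
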