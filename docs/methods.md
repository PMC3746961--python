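# Methods

## The Model Assembly as a recovery reference

Given reads with known placements on reference transcripts, the Model
Assembly (MA) is the set of maximal unions of overlapping-or-touching read
intervals per transcript (0-based half-open throughout; touching intervals
merge because a region contiguously covered by reads is one region).  The
shortest possible MA fragment is one read (76 nt at the default read
length).  A read counts toward the read count of the fragment that fully
contains it; since fragments are the connected components of read coverage,
every read is fully contained in exactly one fragment, which makes the
conservation identity Σ(pnc × length) = total read nucleotides exact in
integer arithmetic.  Whether partially overhanging reads should count
differently never arises under this containment rule; we flag this as the
one place where a real-data pipeline (reads mapped with an aligner,
multi-hits broken by subject id) could differ from the truth-manifest path.

pnc = (reads × read length) / fragment length.  Expression bins B1–B8 use
right-closed boundaries 1, 2, 3, 4, 5, 10, 30: denser at low coverage
because the fragment distribution is denser there.  Fragments on
isoform-bearing genes or transposon transcripts keep their bin but are
flagged `excluded` and skipped by binned statistics: shared subsequence
makes read assignment (and therefore pnc) unreliable for them.

## Mapping

The bundled aligner indexes every exact subject word of 28 nt (the
Megablast default word size, and the floor below which spurious hits
cannot seed), seeds on shared words, and reports maximal positive-scoring
ungapped segments per diagonal under match +1 / mismatch −2.  Scoring-based
extension is what makes the aligner useful at both extremes: it crosses
occasional sequencing errors inside homologous segments but cannot extend
through unrelated sequence (expected score −1.25/4 per column), so a
chimera junction terminates the hit.  Gapped homology appears as separate
hits on neighbouring diagonals, which the downstream interval chaining
consumes exactly as the original scripts consumed Megablast output.
`min_identity` is a post-filter on reported hits (default 0 for
evaluation, 95 for clustering); every reported hit contains at least one
exact 28-mer by construction.  Ties between equal-scoring segments keep the
leftmost start and, for the same start, the longest extent.  No E-values or
bit scores: the surrogate score identity × aligned length orders hits
deterministically, which is all the evaluation needs.

## Hit resolution

Per anchor (query for misassembly, subject for recovery) hits are visited
in descending anchor-axis length, ties broken by descending surrogate
score, then partner id, then start.  A hit is retained iff it adds strictly
more than 10 nt of new anchor coverage; nested hits add nothing and are
always rejected.  The 10 nt threshold is the published unique-coverage
cutoff ("discard when ≤ 10 nt"), kept exactly.  Any two retained hits each
contribute > 10 nt the other does not cover (the pairwise invariant the
tests verify).  The greedy parser is deliberately *not* a coverage
optimizer — a long hit accepted first can block a two-hit combination that
would cover slightly more (`test_greedy_not_coverage_optimal_documented`
freezes such a case).  The selection rule, not maximal coverage, is the
contract; an exhaustive-enumeration oracle in the acceptance suite confirms
the greedy result is the unique subset consistent with that rule.  Whether
the original scripts applied the rules per query–subject pair or globally
per anchor is ambiguous; global-per-anchor is the default, `per_pair=True`
is available.

## Classification and statistics

* Misassembly: best single-source fraction = max over subjects of the
  union of that subject's retained query intervals, divided by query
  length.  Boundaries go to the upper class (0.9 → ≥90 %, 0.6 → 60–90 %);
  the source material is inconsistent between ">90 %" and "≥90 %", and we
  chose the closed-lower reading once for both thresholds.
* Detection: recovered length ≥ 1 nt after resolution (no published floor
  exists, so the weakest sensible one is used).
* N50/N_MA50: smallest length whose descending cumulative sum reaches half
  the denominator, compared as 2·cum ≥ denom to stay in integers.  When an
  assembly is smaller than half the MA, N_MA50 is undefined; we return 0
  with a warning rather than guessing.
* Length-stratified recovery uses the ten published length categories
  (≤76, 76–300, 300–500, 500–1000, 1000–1500, 1500–2000, 2000–3000,
  3000–4000, 4000–5000, 5000–6500 nt; longer fragments fall into a
  catch-all) with box-plot summaries: Q1/Q3 by linear-interpolation
  percentiles, whiskers at the extremes of the non-outlier range, outliers
  outside Q1 − 1.5·IQR / Q3 + 1.5·IQR.
* Isoform recovery categorizes each exon's length recovery into 0 %,
  >0–20, >20–40, >40–60, >60–80, >80–100 %; an isoform is a member of every
  category one of its exons occupies, and per-category median pnc is taken
  over member isoforms.
* Shared/unique regions: within a pooled transcript set, shared = union of
  intervals covered by hits from other pool members (self-hits excluded);
  unique = complement.  Edges of shared regions are soft by up to
  word − 1 nt, the seeding resolution.
* ROC: TPR = 100 × Σ recovered / MA total; FPR = 100 × fragments with zero
  retained hits / fragments.

## Redundancy clustering

Longest-first greedy clustering at ≥ 95 % identity on either strand with
word 8, accurate mode (every current representative is scored and the best
taken).  Identity is matched columns of the resolved hits divided by the
shorter sequence length, capped at 1 — a simplification of CD-HIT-EST's
k-mer filter that reproduces the same decision boundary at these scales
(96 %-identical pairs cluster, 94 % do not), though sequences exactly at
the 95 % boundary may be decided differently than CD-HIT would.
Representatives are always at least as long as their members; clustering
the non-redundant output again yields only singletons.

## Augmentation

The base assembly (query) is mapped against the donor (subject); resolved
donor coverage is subtracted from each donor sequence and leftover
intervals ≥ 76 nt (the global minimum fragment length; the source never
states a separate filter, so the global threshold is inherited) are cut out
as `donorid:start-end` records and appended.  Size conservation is exact:
augmented total = base total + unique total.  Re-augmenting with the same
donor adds nothing at the default minimum region, because residual
uncovered slivers at junctions are bounded by 2 × (word − 1) = 54 nt < 76.
Recovery gain is measured by re-running the recovery statistics before and
after.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the method was
developed on: multi-exon genes (2–6 exons ≥ 100 nt, introns 50–200 nt, all
plus strand), transcripts of 400–2 000 nt, a configurable fraction of
two-isoform genes (one skipped exon, so isoform pairs share and differ in
at least one exon) and of paralog pairs (a planted 100 nt shared block,
comfortably above the 28 nt word), 76 nt paired reads with insert
N(300, 30) and per-base substitution errors (default 0.5 %).  Expression
weights are lognormal (σ = 1.2) with multinomial read allocation; the
original simulation's molecule-count parameterization has no closed form,
so the lognormal is a stand-in chosen to reproduce the dense-low/sparse-high
pnc spectrum, not a claim about that simulator.  Corruption plants
truncations (keep a contiguous 50–75 % by default), chimeras (two sources,
each segment 40–60 % of the fragment so no single source can reach 90 %),
near-duplicates (exactly ⌊2 %·L⌋ substitutions, i.e. ≥ 95 % identity,
reverse-complemented half the time) and dropouts, all recorded in a truth
manifest sufficient to compute every downstream statistic without
alignment.

Not emulated: indels in reads, position-dependent Illumina error profiles,
meaningful quality strings, PCR/fragmentation bias, antisense or
multi-isoform (> 2) loci.  Passing tests therefore demonstrate the
evaluation machinery is correct on data whose truth is known, not that any
particular real assembler behaves as reported.

## Problem sizes and determinism

Default bench conditions: 30 genes, 4 000 reads (≈ 7× mean coverage,
matching the low-fold regime of the original simulation), corruption at
20 % truncation / 10 % chimera / 10 % duplicate / 5 % dropout.  The test
suite uses 5–12 genes and 1 000–2 000 reads per instance, 20–50 seeds for
distributional checks.  All stages derive their RNG from
`(seed, stage-tag)` via numpy's seed sequences, so adding a stage never
shifts another stage's stream and every artifact (FASTA, FASTQ, TSV, JSON)
is byte-reproducible under a fixed seed.

## Known limitations

* The aligner is ungapped; a single indel splits a hit in two.  Chaining
  absorbs this for coverage purposes but per-hit identity is not a gapped
  alignment identity.
* Greedy chain selection can be sub-optimal in coverage (documented above).
* Clustering identity near the 95 % threshold may differ from CD-HIT-EST.
* pnc from truth placements is exact; pnc from re-mapped reads inherits
  whatever multi-mapping policy the caller uses (ties broken by subject id).
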