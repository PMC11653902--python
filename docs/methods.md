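# Methods

## Problem setting and data model

A DNA storage design is an ordered set of equal-length strands over
Σ = {A, C, G, T}. Retrieval returns an unordered multiset S of n reads,
each a noisy copy of one design strand, corrupted by per-base
insertions, deletions and substitutions. A clustering is a partition of
S into nonempty subsets; the perfect clustering groups each read with
the other copies of its origin strand. The clusterer receives no
cluster-size distribution, no density threshold and no reference
design, and n is large enough that all-pairs edit distance
(O(n²·l²)) is out of the question.

Reads are plain strings; ingest either case-folds or rejects
out-of-alphabet symbols (N, gaps) with a logged warning — the hash
arithmetic is defined only over Σ, and silently rewriting bases would
bias similarity. The empty read is representable (heavy deletion can
produce it) and travels through the pipeline as a permanent singleton
candidate.

## Similarity machinery

**Numsets.** Each read s is summarized by the set N_s of its
overlapping q-grams encoded in base 4 (symbol values A=0, C=1, G=2,
T=3, positional weight 4^i). The encoding is bijective between Σ^q and
[0, 4^q). Reads shorter than q get an empty numset: they cannot carry a
MinHash signature, are never candidate pairs in stages 2–3, and remain
singletons unless a future variant of the merge rule claims them — a
deliberate containment of degenerate channel outputs rather than a
crash.

**MinHash / LSH.** For a permutation π of [0, 4^q),
MinHash_π(N) = min{π[v] : v ∈ N}. P[MinHash_π(N₁) = MinHash_π(N₂)]
equals the Jaccard coefficient of the two sets, so the per-read vector
of m MinHash values supports cheap similarity probes: a random k-tuple
of components collides with probability J^k. Permutations are
materialized as arrays for q ≤ 8 (≤ 65,536 entries); for larger q each
permutation is replaced by a keyed SplitMix64 finalizer — a bijection
on the 64-bit integers — and the minimum is taken over mixed images,
which preserves the min-wise property with O(1) memory per permutation.
One permutation family is created per run and shared by stages 2 and 3;
per-chunk families would make cross-chunk signature comparison in
stage 3 meaningless.

**Dice + edit distance.** The merge decision for a candidate pair is

    DSC ≥ θ_high   or   (DSC ≥ θ_low  and  d_edit ≤ thres)

with DSC(X,Y) = 2|X∩Y|/(|X|+|Y|). The edit distance is evaluated
lazily — only when DSC falls in [θ_low, θ_high) — and only as a
thresholded decision, which lets the banded algorithm in `edlib` exit
early. A pair with two empty numsets has no defined DSC and never
merges. For same-origin length-60 reads at ~6% total error, DSC
concentrates around ~0.45 while random pairs sit near ~0.015, so the
two thresholds bracket the ambiguous band tightly.

## The three stages

**Stage 1 — chunking.** Anchor hash h_{y,t}(x): the substring of x of
length ≤ w + t starting at the first occurrence of the anchor y ∈ Σ^w,
or ε when y is absent. Identical error-free windows are common within a
true cluster and vanishingly rare across random strands, so identical
ε-free signatures are merged wholesale (transitive closure within a
round — the fixed point of the pairwise rule, and order-independent).
Each round draws a fresh anchor pair and a fresh random representative
per cluster (scores do not exist yet in this stage; random rotation
maximizes anchor diversity). Early rounds require a *pair* of
signatures to match; when the per-round merge count drops to
mergers_ratio·n or below for p consecutive rounds the scheme switches
to a single signature, and a second such stagnation ends the stage. The
per-round counter is reset every round: a cumulative counter would
make the stagnation rule either fire immediately or never. A hard cap
(`step1_max_rounds`, default 120) guarantees termination on adversarial
inputs. Chunk purity is the only quality that matters here; recall is
delegated to stage 3, which is why the stage may legitimately leave
most reads as singleton chunks on short-strand inputs where a
length-(w+t) anchor window rarely survives intact.

**Stage 2 — clustering per chunk.** Each chunk is re-clustered from
singletons, independently: per iteration, k of the m MinHash components
are drawn (without replacement), reads are bucketed by exact k-tuple,
and every cross-cluster pair inside a bucket is submitted to the merge
test at the strict stage-2 thresholds. Buckets larger than
`bucket_cap` (default 2,000) are subsampled with a seeded scheme (three
random partners per member) to bound the worst-case pair count.
Successful merges increment both reads' scores — the count of merge
participations that later identifies reliable representatives. The
output refines the chunk partition by construction.

**Stage 3 — full clustering.** The same filter-and-test scheme runs
over the entire input, but each cluster is represented by its
highest-score member (ties broken by seeded random choice), and the
thresholds are lowered (default 0.9× the stage-2 θ values, and a larger
edit cap): representatives are trusted, and the remaining singletons
are the most error-laden reads. Per round the singleton count before
and after (r0, r1) yields the relative reduction
ρ = (r0 − r1)/max(r0, 1). When ρ ≤ `step3_replace_eps` for
`step3_replace_patience` consecutive rounds, every multi-read cluster
rotates to its next-highest-score member not recently used (falling
back to a reset once all members have served) — stagnation usually
means the current representatives have exhausted their luck, not that
the clustering is finished. Once at least one rotation has happened,
ρ ≤ `step3_finish_eps` for `step3_finish_patience` consecutive rounds
terminates the stage; `step3_max_rounds` is a safety cap only, sized so
that normal runs converge well before it. Representative merges
increment both representatives' scores, keeping the score ranking
meaningful across rotations. Stage 3 only ever merges clusters — the
final partition coarsens the stage-2 output.

Cluster ids in the returned partition are dense integers ordered by
each cluster's first member in input order, so output files are
reproducible byte for byte.

## Parameters and defaults

| parameter | default | role |
|---|---|---|
| w, t | 5, 10 | anchor length and tail; signatures ≤ 15 nt |
| mergers_ratio, p | 0.01, 3 | stage-1 stagnation rule |
| q | 6 | gram size; 4^6 = 4096-value domain |
| m | 50 | stored MinHash components per read |
| k | 3 | components per LSH tuple |
| max_iterations | 30 | stage-2 rounds per chunk |
| θ_high, θ_low (stage 2) | 0.40, 0.22 | Dice thresholds |
| thres (stage 2) | ⌈0.15·l̃⌉ | edit cap; l̃ = median read length |
| stage-3 θ | 0.9 × stage-2 | lowered for representative comparison |
| thres (stage 3) | ⌈0.20·l̃⌉ | |
| replace/finish eps | 0.005 | singleton-stagnation threshold |
| replace/finish patience | 8 / 4 | consecutive stagnant rounds |
| step3_max_rounds | 600 | termination safety cap |
| bucket_cap | 2000 | pair-enumeration bound per bucket |

The defaults were frozen by validation on the synthetic suite at the
benchmark regimes (lengths 60–150, errors 0–6%, cluster sizes 0–32).
Two choices deserve comment:

* **k = 3.** The per-round candidate probability of a same-origin pair
  is J^k. At the hardest regime (length 60, ~6% total error) J ≈ 0.3;
  k = 4 leaves too little recall per round for short strands (measured
  accuracy(0.95) collapses from ≈0.89 to ≈0.51 on a 500-strand pilot),
  while k = 3 keeps the false-candidate rate negligible (random-pair
  J ≈ 0.007 gives ~3·10⁻⁷ per tuple) and the Dice/edit gate removes
  what little survives.
* **step3_max_rounds = 600.** Stage 3's own stagnation rule terminates
  typical 80k-read runs after ~250–300 rounds; the cap exists so that
  pathological inputs cannot loop forever, and is deliberately far
  above the convergence point so it never acts as a hidden tuning knob.

All parameters are exposed on `GradHCParams`, in the YAML config the
CLI accepts, and are logged with every run.

## Simulator

`generate_design` draws i.i.d. uniform strands. `corrupt` implements
the channel with a fixed, documented event order: scanning left to
right, insertions are attempted before each position and may repeat
geometrically (k insertions with probability p_ins^k·(1−p_ins)), a
single uniform draw at the position deletes (p_del), substitutes with
one of the *other three* symbols (p_sub), or keeps the base, and one
final insertion slot follows the last position. Marginal per-base
deletion/substitution rates are exactly p_del and p_sub, and the
expected output length is l·(1−p_del) + (l+1)·p_ins/(1−p_ins). Every
statistical test in the suite is derived from this convention, not from
any external tool's behavior. Cluster sizes come from a pluggable model
(uniform integer range — the default, matching the benchmark's "sizes
0–32" description with the least-informative choice —, fixed, or an
empirical list); sizes of 0 are legal and leave the strand unread.
Emitted reads are shuffled before ids are assigned, so ids carry no
origin information; the ground truth (read id → design index) is
returned alongside and recorded in the dataset manifest together with
the seed and all model settings.

`pseudo_randomize` XORs each design strand with a seeded pseudo-random
mask under the 2-bit encoding A=00, C=01, G=10, T=11. It is an
involution (same seed ⇒ same masks), so decoding costs only the seed.
Its purpose is defensive encoding: designs with long repeats shared
across strands make different-origin reads look similar and defeat any
substring-correlation clusterer; masked strands are mutually far in
edit distance.

`channel_rate_report` estimates realized channel rates by globally
aligning each read to its origin and tallying cigar operations, with
Wilson confidence intervals. Alignment can compress adjacent events
(e.g. an insertion next to a deletion), so observed counts are a lower
bound on generated events — the tests assert exactly that relation.

**What the simulator does not emulate:** PCR amplification bias and
cluster-size overdispersion, homopolymer-conditioned error profiles,
strand-position-dependent error rates, chimeric reads, and quality
scores. Passing the synthetic suite therefore demonstrates correctness
of the algorithmic machinery under the stated channel, not performance
on any particular sequencing technology; wet datasets also require the
best-edit-distance reference labeling (`label_by_best_edit`, ties to
the lowest strand index) instead of generator truth.

## Metrics

The optimal injective map is computed exactly: the sparse overlap
matrix (only positive entries are materialized) is turned into a
rectangular assignment problem with one dummy column per true cluster
(weight smaller than any unit of overlap, so dummies never displace a
real match — they only encode "unmatched maps to ∅"), solved with
`scipy.sparse.csgraph.min_weight_full_bipartite_matching`. Greedy
matching is *not* used anywhere: it demonstrably differs on small
adversarial fixtures, and the metric definitions take a global argmax.

Threat Score follows the printed definition: TP is the total overlap
achieved by the overlap-maximizing map π′, FN and FP count
true-cluster members outside and predicted-cluster members outside
their matched partner (whole clusters when unmatched), which makes
TS = TP/(2n − TP). Accuracy(γ), defined for 0.5 < γ ≤ 1, exploits that
a false-positive-free predicted cluster is a subset of exactly one true
cluster, so the maximum over injective maps decomposes per true
cluster; a tolerance of 1e-9 in the coverage comparison guards against
binary-float artifacts in γ·|C| (0.95·20 must count as covered by 19).
Both implementations are checked against exhaustive enumeration of all
injective maps on 200 random small instances in the test suite.

## Numerical and engineering choices

* Union-find with path compression and size-ordered member-list
  merging keeps all partition maintenance near-linear.
* Signature tables are int64 matrices; per-round bucket discovery is a
  lexsort over the selected k columns, so stage-3 rounds cost
  O(R·k·log R) for R live clusters plus the (few) merge tests.
* All randomness flows from one integer seed through
  `numpy.random.Generator.spawn`, one child per stage: runs are exactly
  reproducible, and stage behavior is insensitive to how much
  randomness earlier stages consumed.
* File writers are atomic (write to a temp file, rename into place); a
  run directory always contains the effective parameters, the seed and
  a manifest sufficient to reproduce it bit for bit.
* Empty inputs yield empty clusterings; metric functions refuse empty
  universes and mismatched read sets rather than guessing.

## Known limitations

* Stage 1 contributes little on very short strands (anchor windows of
  w + t = 15 nt rarely survive 6% error in both of two random
  representatives), shifting nearly all work to stage 3; accuracy is
  unaffected but the chunking speed-up is lost exactly where inputs
  are already cheap per comparison.
* Reads shorter than q never acquire signatures and end as singletons.
* The per-read score is a lifetime counter; on extremely long runs a
  once-good representative that accumulated score early can shadow a
  better one until a rotation event.
* `label_by_best_edit` implements the per-read best-edit rule only; no
  iterative refinement of ambiguous assignments is attempted, and ties
  are resolved by strand index for determinism.
* The benchmark suite runs the hard short-strand regime at 5,000
  design strands (~80,000 reads), a deliberate desk-scale problem size
  for the package's own validation; larger inputs scale near-linearly
  (the suite asserts a log-log runtime slope < 1.5 over 10³–10⁵ reads).
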