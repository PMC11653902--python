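"""The three-stage gradual hash-based clustering pipeline.

Given n noisy reads, the pipeline groups copies of the same original
strand without knowing cluster sizes or densities in advance:

1. **Chunking** — iterated anchor-hash signature collisions produce a
   coarse partition into chunks.  Early rounds require two independent
   anchor signatures to agree (high precision); once the per-round merge
   rate stagnates the scheme drops to a single signature, and when it
   stagnates again the stage stops.

2. **Clustering per chunk** — within each chunk independently, reads are
   re-clustered from singletons: for a number of iterations, a random
   k-tuple of MinHash components is drawn, reads bucketed by identical
   tuples, and every candidate pair is submitted to the two-threshold
   Dice / edit-distance merge test.  Each successful merge increments
   both reads' scores.

3. **Full clustering** — cluster *representatives* (highest-score
   members) are compared across the whole input with the same
   signature-collision + merge-test scheme at lowered thresholds,
   merging clusters that were split across chunks and absorbing leftover
   singletons.  Representatives are rotated when the singleton count
   stagnates; the stage finishes when stagnation persists after at least
   one rotation.

All randomness flows from a single integer seed; two runs with the same
parameters and seed produce identical read -> cluster mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Iterable, Mapping, Sequence

import numpy as np

from .hashing import (
    EPSILON,
    PermutationFamily,
    SignatureTable,
    anchor_hash,
    sample_anchor_pair,
)
from .sequence_model import ReadSet, bulk_numset_arrays
from .similarity import MergeThresholds, merge_test

logger = logging.getLogger(__name__)


class Clustering(Mapping):
    """A partition of read ids into nonempty clusters.

    Behaves as an immutable mapping read-id -> cluster-id; the inverse
    view is available through :meth:`clusters`.
    """

    def __init__(self, assignments: Mapping[str, int]):
        self._assign = dict(assignments)
        clusters: dict[int, set[str]] = {}
        for rid, cid in self._assign.items():
            clusters.setdefault(int(cid), set()).add(rid)
        self._clusters = {cid: frozenset(m) for cid, m in clusters.items()}

    @classmethod
    def from_clusters(cls, groups: Iterable[Iterable[str]]) -> "Clustering":
        assign: dict[str, int] = {}
        for cid, members in enumerate(groups):
            members = list(members)
            if not members:
                raise ValueError("clusters must be nonempty")
            for rid in members:
                if rid in assign:
                    raise ValueError(f"read {rid!r} appears in two clusters")
                assign[rid] = cid
        return cls(assign)

    # Mapping interface ------------------------------------------------
    def __getitem__(self, read_id: str) -> int:
        return self._assign[read_id]

    def __iter__(self):
        return iter(self._assign)

    def __len__(self) -> int:
        return len(self._assign)

    # views --------------------------------------------------------------
    def clusters(self) -> dict[int, frozenset[str]]:
        """cluster-id -> member set."""
        return dict(self._clusters)

    @property
    def n_reads(self) -> int:
        return len(self._assign)

    @property
    def n_clusters(self) -> int:
        return len(self._clusters)

    def sizes(self) -> list[int]:
        return [len(m) for m in self._clusters.values()]

    def singleton_count(self) -> int:
        return sum(1 for m in self._clusters.values() if len(m) == 1)

    def relabeled(self, order: Sequence[str] | None = None) -> "Clustering":
        """Dense integer cluster ids, ordered by each cluster's smallest member.

        ``order`` fixes what "smallest" means: the position in the given
        read-id sequence (typically the input order).  Without it, ids
        compare lexicographically.
        """
        if order is not None:
            pos = {rid: i for i, rid in enumerate(order)}
            key = lambda members: min(pos[r] for r in members)  # noqa: E731
        else:
            key = min
        ranked = sorted(self._clusters.values(), key=key)
        assign = {rid: cid for cid, members in enumerate(ranked) for rid in members}
        return Clustering(assign)

    def __eq__(self, other) -> bool:
        """Equality as partitions (cluster labels are immaterial)."""
        if not isinstance(other, Clustering):
            return NotImplemented
        return set(self._clusters.values()) == set(other._clusters.values())

    def __hash__(self):  # pragma: no cover
        return hash(frozenset(self._clusters.values()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Clustering(n_reads={self.n_reads}, n_clusters={self.n_clusters})"


class DisjointSets:
    """Union-find over read indices with per-root member lists."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.members: list[list[int] | None] = [[i] for i in range(n)]
        self.n_roots = n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        la, lb = self.members[ra], self.members[rb]
        if len(la) < len(lb):  # type: ignore[arg-type]
            ra, rb, la, lb = rb, ra, lb, la
        self.parent[rb] = ra
        la.extend(lb)  # type: ignore[union-attr]
        self.members[rb] = None
        self.n_roots -= 1
        return ra

    def roots(self) -> list[int]:
        return [i for i, m in enumerate(self.members) if m is not None]

    def size(self, root: int) -> int:
        return len(self.members[root])  # type: ignore[arg-type]

    def to_clustering(self, ids: Sequence[str]) -> Clustering:
        assign = {}
        for root in self.roots():
            for i in self.members[root]:  # type: ignore[union-attr]
                assign[ids[i]] = root
        return Clustering(assign).relabeled(order=list(ids))


@dataclass(frozen=True)
class GradHCParams:
    """All pipeline parameters; every field has a working default.

    Stage 1: ``w`` (anchor length), ``t`` (tail length), ``mergers_ratio``
    and ``p`` (the per-round merge-rate stagnation rule), ``step1_max_rounds``
    (hard termination cap).

    Stage 2: ``q`` (gram size), ``m`` (MinHash components stored per
    read), ``k`` (components per LSH tuple), ``max_iterations`` and the
    stage thresholds.  ``thres_2``/``thres_3`` default to ceil(0.15 *
    median read length) and ceil(0.20 * median read length) when unset.

    Stage 3: thresholds default to 0.9x the stage-2 theta values (the
    representatives are trusted, so the net is widened), plus the
    singleton-stagnation constants controlling representative rotation
    and termination.
    """

    w: int = 5
    t: int = 10
    mergers_ratio: float = 0.01
    p: int = 3
    step1_max_rounds: int = 120
    q: int = 6
    m: int = 50
    k: int = 3
    max_iterations: int = 30
    theta_high_2: float = 0.40
    theta_low_2: float = 0.22
    thres_2: int | None = None
    theta_high_3: float | None = None
    theta_low_3: float | None = None
    thres_3: int | None = None
    step3_replace_eps: float = 0.005
    step3_replace_patience: int = 8
    step3_finish_eps: float = 0.005
    step3_finish_patience: int = 4
    step3_max_rounds: int = 600
    bucket_cap: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mergers_ratio", "theta_high_2", "theta_low_2",
                     "step3_replace_eps", "step3_finish_eps"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.theta_low_2 > self.theta_high_2:
            raise ValueError("theta_low_2 must be <= theta_high_2")
        th3, tl3 = self.theta_high_3, self.theta_low_3
        if th3 is not None and th3 > self.theta_high_2:
            raise ValueError("stage-3 thresholds must not exceed stage-2 thresholds")
        if tl3 is not None and th3 is not None and tl3 > th3:
            raise ValueError("theta_low_3 must be <= theta_high_3")
        for name in ("w", "t", "p", "step1_max_rounds", "q", "m", "k",
                     "max_iterations", "step3_replace_patience",
                     "step3_finish_patience", "step3_max_rounds", "bucket_cap"):
            if getattr(self, name) < (0 if name == "t" else 1):
                raise ValueError(f"{name} out of range")
        if self.k > self.m:
            raise ValueError("k must be <= m")

    def resolve(self, read_lengths: Sequence[int]) -> "ResolvedParams":
        """Fill length-dependent and stage-3 defaults for a concrete input."""
        med = float(np.median(read_lengths)) if len(read_lengths) else 0.0
        thres_2 = self.thres_2 if self.thres_2 is not None else ceil(0.15 * med)
        thres_3 = self.thres_3 if self.thres_3 is not None else ceil(0.20 * med)
        th3 = self.theta_high_3 if self.theta_high_3 is not None else 0.9 * self.theta_high_2
        tl3 = self.theta_low_3 if self.theta_low_3 is not None else 0.9 * self.theta_low_2
        return ResolvedParams(
            base=self,
            step2=MergeThresholds(self.theta_high_2, self.theta_low_2, thres_2),
            step3=MergeThresholds(th3, tl3, thres_3),
        )


@dataclass(frozen=True)
class ResolvedParams:
    base: GradHCParams
    step2: MergeThresholds
    step3: MergeThresholds


@dataclass
class ScoreTable:
    """Per-read merge-participation counters (never decreasing)."""

    counts: np.ndarray  # (n_reads,) int64

    @classmethod
    def zeros(cls, n: int) -> "ScoreTable":
        return cls(np.zeros(n, dtype=np.int64))

    def increment(self, *read_indices: int) -> None:
        for i in read_indices:
            self.counts[i] += 1


@dataclass
class PipelineTrace:
    """Stage boundaries and per-round diagnostics of one run."""

    chunks: Clustering | None = None
    step2: Clustering | None = None
    final: Clustering | None = None
    step1_rounds: int = 0
    step1_merges_per_round: list[int] = field(default_factory=list)
    step3_rounds: int = 0
    singleton_trajectory: list[tuple[int, int]] = field(default_factory=list)
    representative_replacements: int = 0


# --------------------------------------------------------------------------
# Stage 1 — division into chunks
# --------------------------------------------------------------------------

def chunks_generation(
    reads: ReadSet,
    params: GradHCParams,
    rng: np.random.Generator,
    trace: PipelineTrace | None = None,
) -> Clustering:
    """Coarse partition by iterated anchor-signature collision merging.

    Each round samples a fresh anchor pair, computes per-cluster
    signatures from a randomly drawn representative, and merges (the
    transitive closure of) all clusters sharing an identical,
    EPSILON-free signature.  Rounds whose merge count stays at or below
    ``mergers_ratio * n`` for ``p`` consecutive rounds first switch from
    the double to the single signature and, on a second stagnation, stop.
    A hard round cap guarantees termination.
    """
    n = len(reads)
    seqs = reads.sequences
    uf = DisjointSets(n)
    if n == 0:
        return Clustering({})
    double_sig = True
    patience = 0
    rounds = 0
    while rounds < params.step1_max_rounds:
        rounds += 1
        h1, h2 = sample_anchor_pair(params.w, params.t, rng)
        roots = uf.roots()
        picks = rng.random(len(roots))
        groups: dict[object, list[int]] = {}
        for u, root in zip(picks, roots):
            members = uf.members[root]
            rep = members[int(u * len(members))]  # type: ignore[index]
            a = anchor_hash(seqs[rep], h1)
            if a is EPSILON:
                continue
            if double_sig:
                b = anchor_hash(seqs[rep], h2)
                if b is EPSILON:
                    continue
                key = (a, b)
            else:
                key = a
            groups.setdefault(key, []).append(root)
        merges = 0
        for group in groups.values():
            if len(group) > 1:
                base = group[0]
                for other in group[1:]:
                    base = uf.union(base, other)
                    merges += 1
        if trace is not None:
            trace.step1_merges_per_round.append(merges)
        if merges / n <= params.mergers_ratio:
            patience += 1
        else:
            patience = 0
        if patience >= params.p:
            if double_sig:
                double_sig = False
                patience = 0
            else:
                break
    if trace is not None:
        trace.step1_rounds = rounds
    logger.info("stage 1: %d rounds, %d chunks (n=%d)", rounds, uf.n_roots, n)
    return uf.to_clustering(reads.ids)


# --------------------------------------------------------------------------
# Stage 2 — clustering per chunk
# --------------------------------------------------------------------------

def _bucket_pairs(
    bucket: Sequence[int], cap: int, rng: np.random.Generator
):
    """Candidate pairs within one signature bucket.

    Buckets up to ``cap`` members are enumerated exhaustively; larger
    ones are subsampled (3 seeded random partners per member) to bound
    the worst-case pair blowup on adversarial inputs.
    """
    b = len(bucket)
    if b <= cap:
        for i in range(b - 1):
            u = bucket[i]
            for j in range(i + 1, b):
                yield u, bucket[j]
    else:
        for u in bucket:
            for j in rng.integers(0, b, size=3):
                v = bucket[int(j)]
                if v != u:
                    yield u, v


def clustering_per_chunk(
    chunks: Clustering,
    reads: ReadSet,
    params: GradHCParams,
    rng: np.random.Generator,
) -> tuple[Clustering, ScoreTable, SignatureTable]:
    """Re-cluster every chunk independently from singletons.

    Builds the q-gram numsets and the m-long MinHash table once for the
    whole input (one shared permutation family keeps stage-3 signature
    comparisons across chunks meaningful), then repeatedly buckets each
    chunk's reads by a random k-tuple of MinHash components and applies
    the stage-2 merge test inside buckets.  Returns the refined
    clustering together with the score and signature tables reused by
    stage 3.  The output provably refines the chunk partition.
    """
    n = len(reads)
    resolved = params.resolve([len(s) for s in reads.sequences])
    numsets = bulk_numset_arrays(reads.sequences, params.q)
    family = PermutationFamily(params.q, params.m, rng)
    sig_table = family.signature_matrix(numsets)
    sig_table.numsets = numsets  # type: ignore[attr-defined]
    scores = ScoreTable.zeros(n)
    uf = DisjointSets(n)
    if n == 0:
        return Clustering({}), scores, sig_table

    seqs = reads.sequences
    pos = {rid: i for i, rid in enumerate(reads.ids)}
    sig = sig_table.matrix
    has = sig_table.has_signature
    th = resolved.step2

    for members in chunks.clusters().values():
        idxs = [pos[r] for r in members]
        live = [i for i in idxs if has[i]]
        if len(live) < 2:
            continue
        n_parts = len(idxs)  # clusters currently inside this chunk
        for _ in range(params.max_iterations):
            if n_parts == 1:
                break
            cols = rng.choice(params.m, size=params.k, replace=False)
            buckets: dict[tuple, list[int]] = {}
            sub = sig[np.asarray(live)][:, cols]
            for row, i in enumerate(live):
                buckets.setdefault(tuple(sub[row]), []).append(i)
            for bucket in buckets.values():
                if len(bucket) < 2:
                    continue
                for u, v in _bucket_pairs(bucket, params.bucket_cap, rng):
                    if uf.find(u) == uf.find(v):
                        continue
                    if merge_test(numsets[u], numsets[v], seqs[u], seqs[v], th):
                        uf.union(u, v)
                        scores.increment(u, v)
                        n_parts -= 1
    out = uf.to_clustering(reads.ids)
    logger.info(
        "stage 2: %d chunks -> %d clusters (%d singletons)",
        chunks.n_clusters, out.n_clusters, out.singleton_count(),
    )
    return out, scores, sig_table


# --------------------------------------------------------------------------
# Stage 3 — full clustering
# --------------------------------------------------------------------------

def choose_representative(
    members: Sequence[int],
    scores: ScoreTable,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> int:
    """The member with maximal score; ties broken by seeded random choice.

    ``exclude`` supports representative rotation: recently used members
    are skipped unless every member has been used already.
    """
    pool = [i for i in members if not exclude or i not in exclude]
    if not pool:
        pool = list(members)
    best = max(scores.counts[i] for i in pool)
    tied = [i for i in pool if scores.counts[i] == best]
    if len(tied) == 1:
        return tied[0]
    return tied[int(rng.random() * len(tied))]


def full_clustering(
    clustering: Clustering,
    reads: ReadSet,
    sig_table: SignatureTable,
    scores: ScoreTable,
    params: GradHCParams,
    rng: np.random.Generator,
    trace: PipelineTrace | None = None,
) -> Clustering:
    """Merge clusters across chunks via representative signature collisions.

    Each round compares one representative per cluster: representatives
    with identical k-tuples are candidate pairs for the stage-3 merge
    test (thresholds lowered relative to stage 2).  The singleton count
    before/after each round (r0, r1) drives convergence: when the
    relative reduction rho = (r0 - r1) / max(r0, 1) stays at or below
    ``step3_replace_eps`` for ``step3_replace_patience`` consecutive
    rounds, representatives are rotated; once rotation has happened at
    least once, the same stagnation sustained for
    ``step3_finish_patience`` rounds finishes the stage.  This stage only
    merges clusters — it never splits them.
    """
    n = len(reads)
    if n == 0:
        return Clustering({})
    resolved = params.resolve([len(s) for s in reads.sequences])
    th = resolved.step3
    seqs = reads.sequences
    pos = {rid: i for i, rid in enumerate(reads.ids)}
    numsets = getattr(sig_table, "numsets", None)
    if numsets is None:
        numsets = bulk_numset_arrays(seqs, params.q)
    sig = sig_table.matrix
    has = sig_table.has_signature

    uf = DisjointSets(n)
    for members in clustering.clusters().values():
        idxs = [pos[r] for r in members]
        base = idxs[0]
        for other in idxs[1:]:
            base = uf.union(base, other)

    rep: dict[int, int] = {}
    used: dict[int, set[int]] = {}
    for root in uf.roots():
        r = choose_representative(uf.members[root], scores, rng)  # type: ignore[arg-type]
        rep[root] = r
        used[root] = {r}

    def merged_root(ra: int, rb: int) -> int:
        """Union two roots, update scores and representative bookkeeping."""
        ru, rv = rep[ra], rep[rb]
        scores.increment(ru, rv)
        new = uf.union(ra, rb)
        su, sv = scores.counts[ru], scores.counts[rv]
        if su > sv:
            new_rep = ru
        elif sv > su:
            new_rep = rv
        else:
            new_rep = ru if rng.random() < 0.5 else rv
        merged_used = used[ra] | used[rb]
        for d in (ra, rb):
            rep.pop(d, None)
            used.pop(d, None)
        rep[new] = new_rep
        used[new] = merged_used
        return new

    replaced_once = False
    replace_streak = 0
    finish_streak = 0
    rounds = 0
    while rounds < params.step3_max_rounds:
        rounds += 1
        roots = uf.roots()
        r0 = sum(1 for r in roots if uf.size(r) == 1)
        live = [r for r in roots if has[rep[r]]]
        if len(live) >= 2:
            reps_arr = np.fromiter((rep[r] for r in live), dtype=np.int64,
                                   count=len(live))
            cols = rng.choice(params.m, size=params.k, replace=False)
            tuples = sig[reps_arr][:, cols]
            order = np.lexsort(tuples.T)
            sorted_tuples = tuples[order]
            boundary = np.any(np.diff(sorted_tuples, axis=0) != 0, axis=1)
            starts = np.concatenate([[0], np.flatnonzero(boundary) + 1,
                                     [len(live)]])
            for a, b in zip(starts[:-1], starts[1:]):
                if b - a < 2:
                    continue
                bucket = [live[order[i]] for i in range(a, b)]
                for ru, rv in _bucket_pairs(bucket, params.bucket_cap, rng):
                    ra, rb = uf.find(ru), uf.find(rv)
                    if ra == rb:
                        continue
                    iu, iv = rep[ra], rep[rb]
                    if merge_test(numsets[iu], numsets[iv], seqs[iu], seqs[iv], th):
                        merged_root(ra, rb)
        r1 = sum(1 for r in uf.roots() if uf.size(r) == 1)
        rho = (r0 - r1) / max(r0, 1)
        if trace is not None:
            trace.singleton_trajectory.append((r0, r1))
        stagnant = rho <= params.step3_replace_eps
        replace_streak = replace_streak + 1 if stagnant else 0
        finish_streak = finish_streak + 1 if rho <= params.step3_finish_eps else 0
        if replaced_once and finish_streak >= params.step3_finish_patience:
            break
        if replace_streak >= params.step3_replace_patience:
            for root in uf.roots():
                if uf.size(root) > 1:
                    r = choose_representative(
                        uf.members[root], scores, rng, exclude=used[root]  # type: ignore[arg-type]
                    )
                    rep[root] = r
                    used[root].add(r)
                    if len(used[root]) >= uf.size(root):
                        used[root] = {r}
            replaced_once = True
            replace_streak = 0
            finish_streak = 0
            if trace is not None:
                trace.representative_replacements += 1
    if trace is not None:
        trace.step3_rounds = rounds
    out = uf.to_clustering(reads.ids)
    logger.info(
        "stage 3: %d rounds, %d clusters (%d singletons)",
        rounds, out.n_clusters, out.singleton_count(),
    )
    return out


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def gradhc(
    reads: ReadSet,
    params: GradHCParams | None = None,
    trace: PipelineTrace | None = None,
) -> Clustering:
    """Run the full three-stage pipeline; deterministic given params.seed.

    Returns a partition of the read ids with dense integer cluster ids
    ordered by each cluster's first read in input order.  Pass a
    :class:`PipelineTrace` to capture stage boundaries and diagnostics.
    """
    params = params or GradHCParams()
    if len(reads) == 0:
        return Clustering({})
    rng1, rng2, rng3 = np.random.default_rng(params.seed).spawn(3)
    logger.info("gradhc: n=%d seed=%d", len(reads), params.seed)
    chunks = chunks_generation(reads, params, rng1, trace=trace)
    step2, scores, sig_table = clustering_per_chunk(chunks, reads, params, rng2)
    final = full_clustering(step2, reads, sig_table, scores, params, rng3,
                            trace=trace)
    final = final.relabeled(order=reads.ids)
    if trace is not None:
        trace.chunks = chunks
        trace.step2 = step2
        trace.final = final
    return final


def audit_partition(reads: ReadSet, clustering: Clustering) -> None:
    """Raise unless ``clustering`` is a partition of exactly these reads."""
    ids = set(reads.ids)
    got = set(clustering)
    if ids != got:
        raise AssertionError(
            f"partition mismatch: {len(ids - got)} missing, {len(got - ids)} extra"
        )
    if sum(clustering.sizes()) != len(reads):
        raise AssertionError("cluster sizes do not sum to n")
    if any(len(m) == 0 for m in clustering.clusters().values()):
        raise AssertionError("empty cluster present")


def refines(fine: Clustering, coarse: Clustering) -> bool:
    """True iff every cluster of ``fine`` lies inside one cluster of ``coarse``."""
    for members in fine.clusters().values():
        targets = {coarse[r] for r in members}
        if len(targets) != 1:
            return False
    return True
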