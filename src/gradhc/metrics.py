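"""Clustering validation against ground truth.

Both metrics compare a predicted clustering C-tilde with the true
clustering C of the same read universe through an *injective* map from
true clusters to predicted clusters (unmatched clusters map to the empty
set):

* **Threat Score** (critical success index): TP / (TP + FP + FN), where
  TP/FN/FP are counted under the injective map pi' that maximizes the
  total overlap  sum_i |C-tilde_{pi(i)} ∩ C_i|.  The maximization is
  solved exactly as a sparse maximum-weight bipartite assignment.

* **Accuracy(gamma)** for 0.5 < gamma <= 1: the fraction of true
  clusters matched by a predicted cluster that is a false-positive-free
  subset covering at least a gamma-fraction of the true cluster.
  Because a nonempty FP-free predicted cluster is a subset of exactly
  one true cluster, the maximum over injective maps decomposes per true
  cluster and is computed directly.

A helper labels reads of a wet-style dataset by their best edit-distance
design strand, producing a reference clustering when no generator ground
truth exists.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import min_weight_full_bipartite_matching

from .engine import Clustering
from .sequence_model import ReadSet
from .similarity import edit_distance


@dataclass(frozen=True)
class MatchResult:
    """An overlap-maximizing injective map true-cluster -> predicted-cluster.

    ``pairs`` contains only the matched true clusters (unmatched ones map
    to the empty set by convention); ``total_overlap`` is the achieved
    sum of pairwise intersections, at most n.
    """

    pairs: dict[int, int]
    total_overlap: int


def _check_universe(truth: Mapping[str, int], predicted: Mapping[str, int]) -> int:
    t, p = set(truth), set(predicted)
    if t != p:
        raise ValueError(
            f"clusterings cover different reads ({len(t ^ p)} ids differ)"
        )
    if not t:
        raise ValueError("cannot evaluate empty clusterings")
    return len(t)


def overlap_counts(
    truth: Mapping[str, int], predicted: Mapping[str, int]
) -> Counter:
    """Sparse contingency: (true cluster, predicted cluster) -> overlap size."""
    return Counter((truth[r], predicted[r]) for r in truth)


def best_injective_map(
    truth: Mapping[str, int], predicted: Mapping[str, int]
) -> MatchResult:
    """Exact overlap-maximizing injective map via sparse assignment.

    Each true cluster receives a zero-overlap fallback "dummy" column so
    the assignment problem always has a perfect row matching; dummy
    matches translate to unmatched-maps-to-empty-set.  Dummy weights are
    strictly smaller than any unit of real overlap, so they can never
    displace a real match.
    """
    n = _check_universe(truth, predicted)
    overlap = overlap_counts(truth, predicted)
    t_ids = sorted({truth[r] for r in truth})
    p_ids = sorted({predicted[r] for r in predicted})
    t_pos = {c: i for i, c in enumerate(t_ids)}
    p_pos = {c: j for j, c in enumerate(p_ids)}
    R, P = len(t_ids), len(p_ids)

    rows, cols, data = [], [], []
    for (ti, pj), cnt in overlap.items():
        rows.append(t_pos[ti])
        cols.append(p_pos[pj])
        data.append(-float(cnt))
    eps = 1.0 / (4.0 * (n + 1))
    for i in range(R):
        rows.append(i)
        cols.append(P + i)
        data.append(-eps)
    graph = sp.csr_matrix((data, (rows, cols)), shape=(R, P + R))
    row_ind, col_ind = min_weight_full_bipartite_matching(graph)

    pairs: dict[int, int] = {}
    total = 0
    for i, j in zip(row_ind, col_ind):
        if j < P:
            pairs[t_ids[i]] = p_ids[j]
            total += overlap.get((t_ids[i], p_ids[j]), 0)
    return MatchResult(pairs=pairs, total_overlap=int(total))


def threat_score(
    truth: Mapping[str, int], predicted: Mapping[str, int]
) -> float:
    """TP / (TP + FP + FN) under the overlap-maximizing injective map.

    With pi' matching true to predicted clusters: TP is the total matched
    overlap; every true-cluster member outside its matched predicted
    cluster is a FN; every predicted-cluster member outside its matched
    true cluster is a FP (members of unmatched clusters count wholly, per
    the empty-set convention).  Both tallies equal n - TP, hence
    TS = TP / (2n - TP).
    """
    n = _check_universe(truth, predicted)
    tp = best_injective_map(truth, predicted).total_overlap
    return tp / (2 * n - tp)


def _check_gamma(gamma: float) -> None:
    if not (0.5 < gamma <= 1.0):
        raise ValueError(f"gamma must satisfy 0.5 < gamma <= 1, got {gamma}")


def accuracy_gamma(
    truth: Mapping[str, int], predicted: Mapping[str, int], gamma: float
) -> float:
    """Fraction of true clusters recovered FP-free at coverage >= gamma.

    A true cluster C_i counts as recovered when some predicted cluster is
    a subset of C_i with size >= gamma * |C_i|.  Since gamma > 0.5 and
    FP-free predicted clusters belong to exactly one true cluster, the
    maximum over injective maps reduces to this per-cluster test.
    """
    _check_gamma(gamma)
    _check_universe(truth, predicted)
    true_sizes = Counter(truth.values())
    pred_label: dict[int, set[int]] = {}
    pred_sizes = Counter(predicted.values())
    for r in truth:
        pred_label.setdefault(predicted[r], set()).add(truth[r])
    recovered: set[int] = set()
    for pj, labels in pred_label.items():
        if len(labels) != 1:
            continue  # contains false positives
        (ti,) = labels
        # tolerance guards against binary-float artifacts in gamma * size
        if pred_sizes[pj] >= gamma * true_sizes[ti] - 1e-9:
            recovered.add(ti)
    return len(recovered) / len(true_sizes)


def accuracy_curve(
    truth: Mapping[str, int],
    predicted: Mapping[str, int],
    gammas: Sequence[float],
) -> list[tuple[float, float]]:
    """Accuracy(gamma) over a grid; non-increasing in gamma."""
    return [(g, accuracy_gamma(truth, predicted, g)) for g in gammas]


def label_by_best_edit(reads: ReadSet, design: Sequence[str]) -> Clustering:
    """Assign each read to the design strand with minimal edit distance.

    Ties break toward the lowest strand index, making the reference
    labeling deterministic.  Cluster ids are design indices; strands that
    attract no read simply do not appear.
    """
    if len(design) == 0:
        raise ValueError("design must contain at least one strand")
    assign: dict[str, int] = {}
    for read in reads:
        best_d = None
        best_i = 0
        for i, strand in enumerate(design):
            d = edit_distance(read.seq, strand)
            if best_d is None or d < best_d:
                best_d, best_i = d, i
        assign[read.id] = best_i
    return Clustering(assign)


def evaluation_report(
    truth: Mapping[str, int],
    predicted: Mapping[str, int],
    gammas: Sequence[float] = (0.6, 0.7, 0.8, 0.9, 0.95, 0.99, 1.0),
) -> dict:
    """Structured summary: TS, the Accuracy(gamma) grid, and count summaries."""
    match = best_injective_map(truth, predicted)
    n = len(truth)
    pred_sizes = Counter(predicted.values())
    report = {
        "n_reads": n,
        "n_true_clusters": len(set(truth.values())),
        "n_predicted_clusters": len(pred_sizes),
        "n_predicted_singletons": sum(1 for s in pred_sizes.values() if s == 1),
        "matched_overlap": match.total_overlap,
        "threat_score": match.total_overlap / (2 * n - match.total_overlap),
        "accuracy": {
            f"{g:g}": accuracy_gamma(truth, predicted, g) for g in gammas
        },
    }
    return report
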