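"""Independent brute-force oracles used to freeze expected test values.

These deliberately share no code with the package: edit distance by
memoized recursion on the textbook definition, metrics by exhaustive
enumeration of every injective map, numsets by literal window slicing.
"""

from functools import lru_cache
from itertools import permutations

BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


def naive_numset(s: str, q: int) -> set[int]:
    out = set()
    for start in range(len(s) - q + 1):
        gram = s[start : start + q]
        out.add(sum((4**i) * BASE[ch] for i, ch in enumerate(gram)))
    return out


def recursive_edit_distance(s1: str, s2: str) -> int:
    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        sub = d(i - 1, j - 1) + (s1[i - 1] != s2[j - 1])
        return min(sub, d(i - 1, j) + 1, d(i, j - 1) + 1)

    return d(len(s1), len(s2))


def _cluster_sets(mapping):
    sets: dict[int, set] = {}
    for rid, cid in mapping.items():
        sets.setdefault(cid, set()).add(rid)
    return list(sets.values())


def _injective_maps(n_true: int, n_pred: int):
    """All injective maps true-index -> pred-index or a dummy (empty set)."""
    targets = range(max(n_true, n_pred))
    return permutations(targets, n_true)


def enumerate_best_overlap(truth, predicted):
    """Max total overlap over all injective maps, with one optimal map."""
    true_sets = _cluster_sets(truth)
    pred_sets = _cluster_sets(predicted)
    P = len(pred_sets)
    best, best_map = -1, None
    for pi in _injective_maps(len(true_sets), P):
        total = sum(
            len(true_sets[i] & pred_sets[j]) if j < P else 0
            for i, j in enumerate(pi)
        )
        if total > best:
            best, best_map = total, pi
    return best, best_map, true_sets, pred_sets


def enumerate_threat_score(truth, predicted) -> float:
    """TS under an exhaustively found overlap-maximizing injective map,
    with TP/FP/FN tallied longhand from the definitions."""
    _, pi, true_sets, pred_sets = enumerate_best_overlap(truth, predicted)
    P = len(pred_sets)
    inverse = {j: i for i, j in enumerate(pi) if j < P}
    tp = fn = fp = 0
    for i, ts in enumerate(true_sets):
        matched = pred_sets[pi[i]] if pi[i] < P else set()
        tp += len(ts & matched)
        fn += len(ts - matched)
    for j, ps in enumerate(pred_sets):
        matched = true_sets[inverse[j]] if j in inverse else set()
        fp += len(ps - matched)
    return tp / (tp + fp + fn)


def enumerate_accuracy_gamma(truth, predicted, gamma: float) -> float:
    """max over injective maps of the fraction of true clusters whose image
    is a false-positive-free subset covering at least gamma of them."""
    true_sets = _cluster_sets(truth)
    pred_sets = _cluster_sets(predicted)
    P = len(pred_sets)
    best = 0
    for pi in _injective_maps(len(true_sets), P):
        hits = 0
        for i, j in enumerate(pi):
            img = pred_sets[j] if j < P else set()
            if img and img <= true_sets[i] and len(img) >= gamma * len(true_sets[i]) - 1e-9:
                hits += 1
        best = max(best, hits)
    return best / len(true_sets)
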