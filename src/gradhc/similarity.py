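"""Sequence similarity: Sørensen–Dice over numsets, Levenshtein distance,
and the two-threshold merge test used by the clustering stages.

The merge rule combines a cheap set-overlap proxy with an exact (banded)
edit-distance check:

    merge  iff  DSC >= theta_high
           or  (DSC >= theta_low  and  edit_distance <= thres)

where DSC(X, Y) = 2|X ∩ Y| / (|X| + |Y|).  The edit distance is only
ever computed when DSC lands in the ambiguous band [theta_low,
theta_high), and then only as a thresholded decision, which permits a
banded early-exit computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .sequence_model import QGramNumSet


class UndefinedSimilarityError(ValueError):
    """Sørensen–Dice is undefined when both numsets are empty."""


@dataclass(frozen=True)
class MergeThresholds:
    """Thresholds for one clustering stage.

    theta_high: Dice score above which two reads merge outright.
    theta_low:  Dice score above which an edit-distance check is allowed.
    thres:      absolute edit-distance cap for the middle band.
    """

    theta_high: float
    theta_low: float
    thres: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_low <= self.theta_high <= 1.0):
            raise ValueError("need 0 <= theta_low <= theta_high <= 1")
        if self.thres < 0:
            raise ValueError("thres must be >= 0")


def _as_sorted_array(numset) -> np.ndarray:
    if isinstance(numset, np.ndarray):
        return numset
    values = numset.values if isinstance(numset, QGramNumSet) else numset
    return np.fromiter(sorted(values), dtype=np.int64, count=len(values))


def sorensen_dice(x, y) -> float:
    """2|X ∩ Y| / (|X| + |Y|) for two numsets.

    Accepts :class:`~gradhc.sequence_model.QGramNumSet`, plain sets, or
    sorted-unique integer arrays (the engine's internal representation).
    Raises :class:`UndefinedSimilarityError` when both sets are empty;
    callers that only need a merge decision treat that as "dissimilar".
    """
    a = _as_sorted_array(x)
    b = _as_sorted_array(y)
    denom = a.size + b.size
    if denom == 0:
        raise UndefinedSimilarityError("Sørensen–Dice undefined for two empty sets")
    inter = np.intersect1d(a, b, assume_unique=True).size
    return 2.0 * inter / denom


def edit_distance(s1: str, s2: str) -> int:
    """Unit-cost Levenshtein distance (insertions, deletions, substitutions)."""
    if not s1 or not s2:
        return abs(len(s1) - len(s2)) or max(len(s1), len(s2))
    return edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]


def edit_within(s1: str, s2: str, cap: int) -> bool:
    """True iff edit_distance(s1, s2) <= cap, via banded early-exit DP."""
    if abs(len(s1) - len(s2)) > cap:
        return False
    if not s1 or not s2:
        return max(len(s1), len(s2)) <= cap
    return edlib.align(s1, s2, mode="NW", task="distance", k=cap)["editDistance"] != -1


def normalized_edit_distance(s1: str, s2: str) -> float:
    """Levenshtein distance divided by max(|s1|, |s2|).

    Two empty strings are identical: the distance is 0 by convention.
    """
    m = max(len(s1), len(s2))
    if m == 0:
        return 0.0
    return edit_distance(s1, s2) / m


def merge_test(nu, nv, su: str, sv: str, th: MergeThresholds) -> bool:
    """The two-threshold merge decision for a candidate read pair.

    Lazy: the edit distance is computed only when the Dice score falls in
    [theta_low, theta_high).  Pairs with an undefined Dice score (both
    numsets empty) never merge here.
    """
    try:
        dsc = sorensen_dice(nu, nv)
    except UndefinedSimilarityError:
        return False
    if dsc >= th.theta_high:
        return True
    if dsc >= th.theta_low:
        return edit_within(su, sv, th.thres)
    return False
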