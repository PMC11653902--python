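"""Hashing machinery: anchor-substring hashes and MinHash/LSH signatures.

Two hash families drive the pipeline:

* The *anchor hash* ``h_{y,t}``: given a random anchor ``y`` of length
  ``w``, a strand maps to the substring of length at most ``w + t``
  starting at the first occurrence of ``y`` (or to :data:`EPSILON` when
  the anchor is absent).  Strands from the same origin tend to share an
  error-free copy of that window, so identical anchor signatures are a
  cheap merge candidate filter for the coarse chunking stage.

* *MinHash* over q-gram numsets: for a random permutation pi of
  [0, 4**q), ``MinHash_pi(N) = min{pi[v] for v in N}``.  Two numsets
  agree on a MinHash component with probability equal to their Jaccard
  coefficient, so a k-tuple of MinHash components (an *LSH signature*)
  is a tunable-precision collision filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_model import DNA_ALPHABET, QGramNumSet, as_dna


class _Epsilon:
    """Distinguished 'anchor absent' value; never equal to any signature."""

    __slots__ = ()
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "EPSILON"

    def __bool__(self) -> bool:
        return False


EPSILON = _Epsilon()


@dataclass(frozen=True)
class AnchorHash:
    """One member h_{y,t} of the anchor-substring hash family H_{w,t}."""

    y: str
    t: int

    def __post_init__(self) -> None:
        as_dna(self.y, name="anchor")
        if len(self.y) < 1:
            raise ValueError("anchor must have length >= 1")
        if self.t < 0:
            raise ValueError("tail length t must be >= 0")

    @property
    def w(self) -> int:
        return len(self.y)


def anchor_hash(x: str, h: AnchorHash):
    """Apply h_{y,t}: the substring of x starting at the first occurrence of y.

    With i the (1-based) index of the first occurrence, the result is
    ``x_i .. x_{r'}`` where ``r' = min(r, i + w + t - 1)`` and r = |x|;
    i.e. at most ``w + t`` symbols beginning with ``y``, truncated at the
    strand end.  Returns :data:`EPSILON` if ``y`` does not occur in ``x``.
    """
    i = x.find(h.y)
    if i < 0:
        return EPSILON
    return x[i : i + len(h.y) + h.t]


def sample_anchor_pair(
    w: int, t: int, rng: np.random.Generator
) -> tuple[AnchorHash, AnchorHash]:
    """Draw two independent uniform anchors from Sigma**w (shared tail t)."""
    if w < 1:
        raise ValueError("w must be >= 1")
    codes = rng.integers(0, 4, size=2 * w)
    y1 = "".join(DNA_ALPHABET[c] for c in codes[:w])
    y2 = "".join(DNA_ALPHABET[c] for c in codes[w:])
    return AnchorHash(y1, t), AnchorHash(y2, t)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer: a bijection on the 64-bit integers."""
    z = x.astype(np.uint64, copy=True)
    z ^= z >> np.uint64(30)
    z *= np.uint64(0xBF58476D1CE4E5B9)
    z ^= z >> np.uint64(27)
    z *= np.uint64(0x94D049BB133111EB)
    z ^= z >> np.uint64(31)
    return z


#: materialize explicit permutation arrays only while they stay small
_EXPLICIT_Q_MAX = 8


class PermutationFamily:
    """m seeded permutations of {0, ..., 4**q - 1} for MinHash.

    For q <= 8 the permutations are materialized as arrays (at most
    65,536 entries each).  For larger q, each permutation is replaced by
    a keyed SplitMix64 mixing bijection on the 64-bit domain; taking the
    minimum over mixed images has the identical min-wise property with
    bounded memory.  Both variants are reproducible from the seed.
    """

    def __init__(self, q: int, m: int, seed: int | np.random.Generator):
        if q < 1 or m < 1:
            raise ValueError("q and m must be >= 1")
        self.q = q
        self.m = m
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        self.explicit = q <= _EXPLICIT_Q_MAX
        if self.explicit:
            domain = 4**q
            self._perms = np.stack(
                [rng.permutation(domain) for _ in range(m)]
            ).astype(np.int64)
            self._keys = None
        else:
            self._perms = None
            self._keys = rng.integers(1, 2**63, size=m, dtype=np.uint64)

    def perm(self, i: int) -> np.ndarray:
        """The i-th permutation as an explicit array (q <= 8 only)."""
        if not self.explicit:
            raise ValueError("explicit permutation arrays unavailable for q > 8")
        return self._perms[i]

    def mixed(self, i: int, values: np.ndarray) -> np.ndarray:
        """Images of ``values`` under the i-th (explicit or implicit) bijection."""
        if self.explicit:
            return self._perms[i][np.asarray(values, dtype=np.intp)]
        return _splitmix64(np.asarray(values, dtype=np.uint64) + self._keys[i])

    def signature(self, numset) -> np.ndarray:
        """m-long MinHash vector of one numset (see :func:`lsh_signature`)."""
        values = _numset_values(numset)
        if values.size == 0:
            raise ValueError("empty numset has no MinHash signature")
        if self.explicit:
            return self._perms[:, np.asarray(values, dtype=np.intp)].min(axis=1)
        mixed = _splitmix64(
            np.asarray(values, dtype=np.uint64)[None, :] + self._keys[:, None]
        )
        return mixed.min(axis=1).astype(np.int64)

    def signature_matrix(
        self, numsets: Sequence[np.ndarray], batch: int = 4096
    ) -> "SignatureTable":
        """MinHash vectors for many reads at once.

        Rows of reads with empty numsets are filled with the sentinel -1
        and flagged in :attr:`SignatureTable.has_signature`.
        """
        n = len(numsets)
        sig = np.full((n, self.m), -1, dtype=np.int64)
        has = np.zeros(n, dtype=bool)
        lengths = np.fromiter((len(v) for v in numsets), dtype=np.int64, count=n)
        order = np.argsort(lengths, kind="stable")
        pos = 0
        while pos < n:
            take = order[pos : pos + batch]
            pos += batch
            take = take[lengths[take] > 0]
            if take.size == 0:
                continue
            lmax = int(lengths[take].max())
            if self.explicit:
                pad = 4**self.q  # sentinel column mapping to +inf
                idx = np.full((take.size, lmax), pad, dtype=np.int64)
                for row, j in enumerate(take):
                    idx[row, : lengths[j]] = numsets[j]
                ext = np.concatenate(
                    [self._perms, np.full((self.m, 1), np.iinfo(np.int64).max)],
                    axis=1,
                )
                sig[take] = ext[:, idx].min(axis=2).T
            else:
                idx = np.zeros((take.size, lmax), dtype=np.uint64)
                mask = np.zeros((take.size, lmax), dtype=bool)
                for row, j in enumerate(take):
                    idx[row, : lengths[j]] = numsets[j].astype(np.uint64)
                    mask[row, : lengths[j]] = True
                for i in range(self.m):
                    mixed = _splitmix64(idx + self._keys[i])
                    mixed[~mask] = np.iinfo(np.uint64).max
                    sig[take, i] = mixed.min(axis=1).astype(np.int64)
            has[take] = True
        return SignatureTable(matrix=sig, has_signature=has, family=self)


@dataclass
class SignatureTable:
    """Per-read m-long MinHash vectors plus the empty-numset mask."""

    matrix: np.ndarray  # (n_reads, m) int64; -1 rows for signature-less reads
    has_signature: np.ndarray  # (n_reads,) bool
    family: PermutationFamily

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]


def _numset_values(numset) -> np.ndarray:
    if isinstance(numset, QGramNumSet):
        return np.fromiter(numset.values, dtype=np.int64, count=len(numset.values))
    arr = (
        numset
        if isinstance(numset, np.ndarray)
        else np.fromiter(numset, dtype=np.int64, count=len(numset))
    )
    return arr.astype(np.int64, copy=False)


def minhash(numset, perm) -> int:
    """min over v in numset of perm[v].

    ``perm`` may be an explicit permutation array or any callable
    mapping an integer array to its images.
    """
    values = _numset_values(numset)
    if values.size == 0:
        raise ValueError("MinHash is undefined for an empty numset")
    images = perm(values) if callable(perm) else np.asarray(perm)[values]
    return int(np.min(images))


def lsh_signature(numset, family: PermutationFamily) -> np.ndarray:
    """The m-long vector whose i-th entry is MinHash under permutation i."""
    return family.signature(numset)


def select_signature(table: SignatureTable | np.ndarray, indices: Iterable[int]) -> np.ndarray:
    """Per-read k-tuples: the stored MinHash columns at ``indices``, in order."""
    matrix = table.matrix if isinstance(table, SignatureTable) else table
    idx = np.asarray(list(indices), dtype=np.intp)
    if idx.size and (idx.min() < 0 or idx.max() >= matrix.shape[1]):
        raise ValueError(f"signature index out of range [0, {matrix.shape[1]})")
    return matrix[:, idx]
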