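"""DNA string handling and the q-gram integer encoding.

Reads are plain Python strings over the alphabet {A, C, G, T}.  All
similarity machinery in this package operates on *numsets*: the set of
integers obtained by encoding every overlapping length-q substring
(q-gram) of a read in base 4 with the symbol values A=0, C=1, G=2, T=3
and positional weight 4**i for the i-th symbol of the gram.  The
encoding is a bijection between length-q DNA strings and [0, 4**q).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

DNA_ALPHABET = "ACGT"
#: symbol values used by the q-gram encoding
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_DNA_TRANS = bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))
_VALID = frozenset(DNA_ALPHABET)


class AlphabetError(ValueError):
    """A sequence contains a symbol outside {A, C, G, T}."""


def as_dna(s: str, *, name: str = "sequence") -> str:
    """Validate that ``s`` is a DNA string over {A,C,G,T} and return it.

    The empty string is valid (a heavily deleted channel output can be
    empty).  Lowercase or ambiguity codes are rejected; case-folding, if
    wanted, is an ingest-time policy (see :func:`gradhc.io.read_sequences`).
    """
    if not _VALID.issuperset(s):
        bad = sorted(set(s) - _VALID)
        raise AlphabetError(f"{name} contains non-ACGT symbol(s): {bad!r}")
    return s


def dna_codes(s: str) -> np.ndarray:
    """Map a DNA string to a uint8 array of symbol values (A=0..T=3)."""
    return np.frombuffer(s.encode("ascii").translate(_DNA_TRANS), dtype=np.uint8)


def codes_to_dna(codes: np.ndarray) -> str:
    """Inverse of :func:`dna_codes`."""
    return _CODE_TO_BASE[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


class Read(NamedTuple):
    """A single sequenced strand: a stable opaque id plus its sequence."""

    id: str
    seq: str


class ReadSet:
    """An ordered collection of reads with unique ids.

    The input order is preserved and used as the canonical tie-break
    order wherever the pipeline needs one (e.g. dense cluster-id
    assignment).  Construction validates id uniqueness and the DNA
    alphabet.
    """

    def __init__(self, reads: Iterable[Read]):
        self._reads: list[Read] = [Read(str(r[0]), as_dna(r[1])) for r in reads]
        ids = [r.id for r in self._reads]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate read id {dup!r}")
        self._index = {r.id: i for i, r in enumerate(self._reads)}

    @classmethod
    def from_sequences(cls, seqs: Iterable[str], prefix: str = "") -> "ReadSet":
        return cls(Read(f"{prefix}{i}", s) for i, s in enumerate(seqs))

    def __len__(self) -> int:
        return len(self._reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self._reads)

    def __getitem__(self, i: int) -> Read:
        return self._reads[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self._reads]

    @property
    def sequences(self) -> list[str]:
        return [r.seq for r in self._reads]

    def seq_of(self, read_id: str) -> str:
        return self._reads[self._index[read_id]].seq

    def position_of(self, read_id: str) -> int:
        return self._index[read_id]

    def __repr__(self) -> str:  # pragma: no cover
        return f"ReadSet(n={len(self)})"


@dataclass(frozen=True)
class QGramNumSet:
    """The set of base-4-encoded q-grams of a read.

    ``values`` is a frozenset of integers in [0, 4**q).  A read shorter
    than q has an empty numset; such reads carry no signature and travel
    through the pipeline as singletons until (and unless) an edit-distance
    branch can claim them.
    """

    q: int
    values: frozenset[int]

    def __post_init__(self) -> None:
        if self.q < 1:
            raise ValueError("q must be >= 1")
        top = 4**self.q
        if any(v < 0 or v >= top for v in self.values):
            raise ValueError(f"numset values must lie in [0, 4**{self.q})")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[int]:
        return iter(self.values)


def encode_qgram(gram: str) -> int:
    """Encode a q-gram as sum_i 4**i * base[gram[i]].

    Bijective between length-q DNA strings and [0, 4**q); the first
    symbol carries the lowest positional weight.
    """
    if len(gram) < 1:
        raise ValueError("q-gram must have length >= 1")
    num = 0
    weight = 1
    for ch in gram:
        try:
            num += weight * BASE_CODE[ch]
        except KeyError:
            raise AlphabetError(f"non-ACGT symbol {ch!r} in q-gram") from None
        weight *= 4
    return num


def create_numset(s: str, q: int) -> QGramNumSet:
    """Collect the encodings of all overlapping q-grams of ``s``.

    Windows are taken with stride 1, left to right; duplicate grams
    collapse (set semantics).  A read shorter than q yields an empty
    numset rather than an error so that degenerate channel outputs stay
    clusterable downstream.
    """
    as_dna(s)
    return QGramNumSet(q, frozenset(numset_array(s, q).tolist()))


def numset_array(s: str, q: int) -> np.ndarray:
    """Sorted unique q-gram encodings of ``s`` as an int32 array.

    Fast path used by the clustering engine; equals
    ``sorted(create_numset(s, q).values)``.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    n = len(s)
    if n < q:
        return np.empty(0, dtype=np.int32)
    codes = dna_codes(s).astype(np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(codes, q)
    vals = windows @ (4 ** np.arange(q, dtype=np.int32))
    return np.unique(vals)


def bulk_numset_arrays(seqs: Sequence[str], q: int) -> list[np.ndarray]:
    """Numset arrays for many reads at once.

    Encodes the concatenation of all reads in one vectorized pass and
    splits per read, discarding windows that span read boundaries.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if not seqs:
        return []
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64, count=len(seqs))
    blob = "".join(seqs)
    if len(blob) < q:
        return [np.empty(0, dtype=np.int32) for _ in seqs]
    codes = dna_codes(blob).astype(np.int32)
    windows = np.lib.stride_tricks.sliding_window_view(codes, q)
    vals = windows @ (4 ** np.arange(q, dtype=np.int32))
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    out: list[np.ndarray] = []
    for st, ln in zip(starts, lengths):
        if ln < q:
            out.append(np.empty(0, dtype=np.int32))
        else:
            out.append(np.unique(vals[st : st + ln - q + 1]))
    return out
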