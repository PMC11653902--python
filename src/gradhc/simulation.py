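"""Synthetic DNA-storage data: designs, the ins/del/sub channel,
cluster-size models, and the pseudo-randomization design transform.

The generator emulates the retrieval side of a storage pipeline: a
*design* of equal-length original strands, a per-base error channel that
produces noisy copies, and a cluster-size model governing how many
copies each strand yields (sizes of 0 are legal — a strand may simply
never be sequenced).  Every output is a pure function of its
specification and seed, and each dataset carries ground-truth labels.

Channel event-order convention (all statistical tests in this package
are derived from it): scanning positions left to right, insertions are
attempted *before* each position and may repeat geometrically (k inserts
with probability p_ins**k * (1 - p_ins)); at the position itself a
single uniform draw either deletes the base (probability p_del),
substitutes it with a uniform choice of the other three symbols
(probability p_sub), or keeps it; a final insertion opportunity follows
the last position.  Marginal per-base deletion and substitution rates
therefore equal p_del and p_sub exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import edlib
import numpy as np
from scipy.stats import norm

from .engine import Clustering
from .sequence_model import ReadSet, Read, as_dna, codes_to_dna, dna_codes


@dataclass(frozen=True)
class Design:
    """An ordered list of original strands of common length."""

    strands: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.strands:
            raise ValueError("design must contain at least one strand")
        lengths = {len(s) for s in self.strands}
        if len(lengths) != 1:
            raise ValueError("all design strands must have the same length")
        for s in self.strands:
            as_dna(s, name="design strand")

    @property
    def length(self) -> int:
        return len(self.strands[0])

    def __len__(self) -> int:
        return len(self.strands)

    def __getitem__(self, i: int) -> str:
        return self.strands[i]

    def __iter__(self):
        return iter(self.strands)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution / insertion / deletion probabilities."""

    p_sub: float = 0.0
    p_ins: float = 0.0
    p_del: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_sub + self.p_del > 1.0:
            raise ValueError("p_sub + p_del must be <= 1 (one event per position)")
        if self.p_ins >= 1.0:
            raise ValueError("p_ins must be < 1 (insertion runs are geometric)")


@dataclass(frozen=True)
class ClusterSizeModel:
    """How many noisy copies each design strand contributes.

    ``uniform``: uniform integer in [low, high] (inclusive); ``fixed``:
    always ``size``; ``empirical``: sampled with replacement from a list
    of observed sizes.
    """

    kind: Literal["uniform", "fixed", "empirical"] = "uniform"
    low: int = 0
    high: int = 32
    size: int = 10
    sizes: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "uniform" and not (0 <= self.low <= self.high):
            raise ValueError("need 0 <= low <= high")
        if self.kind == "fixed" and self.size < 0:
            raise ValueError("size must be >= 0")
        if self.kind == "empirical" and (
            not self.sizes or any(s < 0 for s in self.sizes)
        ):
            raise ValueError("empirical model needs a nonempty list of sizes >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.integers(self.low, self.high + 1, size=n)
        if self.kind == "fixed":
            return np.full(n, self.size, dtype=np.int64)
        pool = np.asarray(self.sizes, dtype=np.int64)
        return pool[rng.integers(0, len(pool), size=n)]

    def describe(self) -> dict:
        if self.kind == "uniform":
            return {"kind": "uniform", "low": self.low, "high": self.high}
        if self.kind == "fixed":
            return {"kind": "fixed", "size": self.size}
        return {"kind": "empirical", "sizes": list(self.sizes)}


def generate_design(
    num_strands: int, length: int, rng: np.random.Generator
) -> Design:
    """i.i.d. uniform strands over {A,C,G,T}**length."""
    if num_strands < 1 or length < 1:
        raise ValueError("num_strands and length must be >= 1")
    codes = rng.integers(0, 4, size=(num_strands, length))
    return Design(tuple(codes_to_dna(row) for row in codes))


def corrupt(strand: str, em: ErrorModel, rng: np.random.Generator) -> str:
    """One noisy copy of ``strand`` under the channel convention above."""
    codes = dna_codes(strand).astype(np.int64)
    l = len(codes)
    if em.p_ins > 0.0:
        ins = rng.geometric(1.0 - em.p_ins, size=l + 1) - 1
    else:
        ins = np.zeros(l + 1, dtype=np.int64)
    u = rng.random(l)
    del_mask = u < em.p_del
    sub_mask = (~del_mask) & (u < em.p_del + em.p_sub)
    if sub_mask.any():
        shift = rng.integers(1, 4, size=int(sub_mask.sum()))
        codes[sub_mask] = (codes[sub_mask] + shift) % 4
    keep = ~del_mask
    total = int(ins.sum() + keep.sum())
    if total == 0:
        return ""
    out = rng.integers(0, 4, size=total)  # inserted bases; kept slots overwritten
    if l:
        pos = np.cumsum(ins[:l]) + np.concatenate(
            [[0], np.cumsum(keep[: l - 1])]
        )
        out[pos[keep]] = codes[keep]
    return codes_to_dna(out)


def generate_dataset(
    design: Design,
    csm: ClusterSizeModel,
    em: ErrorModel,
    rng: np.random.Generator,
) -> tuple[ReadSet, Clustering]:
    """Noisy reads plus ground truth for a whole design.

    Each strand contributes an independently drawn number of corrupted
    copies.  The emitted read order is shuffled and ids are assigned
    afterwards, so ids encode nothing about a read's origin.  The ground
    truth maps read id -> design index; strands with zero copies do not
    appear in it.
    """
    sizes = csm.draw(len(design), rng)
    origins: list[int] = []
    seqs: list[str] = []
    for i, strand in enumerate(design):
        for _ in range(int(sizes[i])):
            origins.append(i)
            seqs.append(corrupt(strand, em, rng))
    order = rng.permutation(len(seqs))
    width = max(6, len(str(max(len(seqs) - 1, 0))))
    reads = []
    truth: dict[str, int] = {}
    for new_pos, old_pos in enumerate(order):
        rid = f"r{new_pos:0{width}d}"
        reads.append(Read(rid, seqs[old_pos]))
        truth[rid] = origins[old_pos]
    return ReadSet(reads), Clustering(truth)


def xor_strands(a: str, b: str) -> str:
    """Symbol-wise XOR under the 2-bit encoding A=00, C=01, G=10, T=11."""
    ca, cb = dna_codes(a), dna_codes(b)
    if ca.size != cb.size:
        raise ValueError("XOR requires equal-length strands")
    return codes_to_dna(ca ^ cb)


def pseudo_randomize(design: Design, seed: int) -> Design:
    """XOR every design strand with a seeded pseudo-random mask strand.

    The masks match the design's length and strand count and are fully
    determined by the seed, so applying the transform twice with the same
    seed returns the original design (XOR is an involution and A is the
    identity symbol).  Storing the seed is the scheme's only redundancy.
    The purpose: near-duplicate designs — which defeat any
    substring-similarity-based clustering — become sets of strands far
    apart in edit distance, at no information cost.
    """
    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 4, size=(len(design), design.length))
    out = []
    for strand, mask in zip(design, masks):
        out.append(codes_to_dna(dna_codes(strand).astype(np.int64) ^ mask))
    return Design(tuple(out))


@dataclass(frozen=True)
class ChannelRateReport:
    """Observed per-base channel rates with Wilson confidence intervals."""

    n_bases: int
    sub_rate: float
    ins_rate: float
    del_rate: float
    sub_ci: tuple[float, float]
    ins_ci: tuple[float, float]
    del_ci: tuple[float, float]
    sub_count: int
    ins_count: int
    del_count: int


def _wilson(count: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 0.0)
    z = norm.ppf(0.5 + conf / 2.0)
    phat = count / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def channel_rate_report(
    reads: ReadSet, truth: Mapping[str, int], design: Design | Sequence[str]
) -> ChannelRateReport:
    """Tally observed sub/ins/del rates by aligning reads to their origins.

    Uses a unit-cost global alignment per read; adjacent error events can
    be compressed by the alignment, so observed counts are a (tight)
    lower bound on generated events.  Rates are per original base.
    """
    strands = list(design)
    subs = ins = dels = 0
    n_bases = 0
    for read in reads:
        origin = strands[truth[read.id]]
        n_bases += len(origin)
        if not read.seq:
            dels += len(origin)
            continue
        result = edlib.align(read.seq, origin, mode="NW", task="path")
        for count, op in _parse_cigar(result["cigar"]):
            if op == "X":
                subs += count
            elif op == "I":
                ins += count
            elif op == "D":
                dels += count
    return ChannelRateReport(
        n_bases=n_bases,
        sub_rate=subs / n_bases,
        ins_rate=ins / n_bases,
        del_rate=dels / n_bases,
        sub_ci=_wilson(subs, n_bases),
        ins_ci=_wilson(ins, n_bases),
        del_ci=_wilson(dels, n_bases),
        sub_count=subs,
        ins_count=ins,
        del_count=dels,
    )


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
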