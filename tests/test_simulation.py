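"""Error channel, designs, cluster-size models, pseudo-randomization."""

from itertools import product

import numpy as np
import pytest

import gradhc as g
from gradhc.simulation import (
    ClusterSizeModel,
    Design,
    ErrorModel,
    channel_rate_report,
    corrupt,
    generate_dataset,
    generate_design,
    pseudo_randomize,
    xor_strands,
)
from gradhc.metrics import label_by_best_edit
from gradhc.similarity import normalized_edit_distance


def test_design_validation():
    with pytest.raises(ValueError):
        Design(())
    with pytest.raises(ValueError):
        Design(("ACGT", "ACG"))
    d = Design(("ACGT", "TTTT"))
    assert d.length == 4 and len(d) == 2


def test_generate_design_deterministic_and_uniform():
    d1 = generate_design(10, 50, np.random.default_rng(42))
    d2 = generate_design(10, 50, np.random.default_rng(42))
    assert d1.strands == d2.strands
    # pooled symbol frequencies within 4 sigma of 1/4
    big = generate_design(2000, 100, np.random.default_rng(1))
    blob = "".join(big.strands)
    n = len(blob)
    sigma = np.sqrt(n * 0.25 * 0.75)
    for ch in "ACGT":
        assert abs(blob.count(ch) - n / 4) < 4 * sigma


def test_random_strand_pairs_agree_at_quarter_of_positions(rng):
    d = generate_design(2, 5000, rng)
    agree = sum(a == b for a, b in zip(d[0], d[1]))
    sigma = np.sqrt(5000 * 0.25 * 0.75)
    assert abs(agree - 5000 * 0.25) < 4 * sigma


def test_error_model_validation():
    with pytest.raises(ValueError):
        ErrorModel(p_sub=0.7, p_del=0.5)
    with pytest.raises(ValueError):
        ErrorModel(p_ins=1.0)
    with pytest.raises(ValueError):
        ErrorModel(p_sub=-0.1)


def test_corrupt_zero_noise_is_identity(rng):
    strand = "ACGTTGCAATCGGCTA" * 5
    assert corrupt(strand, ErrorModel(), rng) == strand


def test_corrupt_full_deletion_empties(rng):
    assert corrupt("ACGTACGT", ErrorModel(p_del=1.0), rng) == ""


def test_corrupt_substitution_rate(rng):
    """Mean mismatch count within 4 sigma of l*p_sub (subs always change)."""
    strand = "".join("ACGT"[c] for c in rng.integers(0, 4, size=1000))
    p = 0.022
    reps = 200
    mismatches = sum(
        sum(a != b for a, b in zip(strand, corrupt(strand, ErrorModel(p_sub=p), rng)))
        for _ in range(reps)
    )
    mean = mismatches / reps
    sigma = np.sqrt(1000 * p * (1 - p) / reps)
    assert abs(mean - 1000 * p) < 4 * sigma


def test_corrupt_expected_length_under_indels(rng):
    """E[len] = l(1-p_del) + (l+1)p_ins/(1-p_ins) under the gap convention."""
    l, p_ins, p_del = 100, 0.05, 0.04
    em = ErrorModel(p_ins=p_ins, p_del=p_del)
    strand = "".join("ACGT"[c] for c in rng.integers(0, 4, size=l))
    n = 10_000
    lengths = np.array([len(corrupt(strand, em, rng)) for _ in range(n)])
    expected = l * (1 - p_del) + (l + 1) * p_ins / (1 - p_ins)
    # generous bound: per-copy variance is O(l), mean over n draws
    assert abs(lengths.mean() - expected) < 4 * np.sqrt(l) / np.sqrt(n) * 2
    assert lengths.min() >= 0


def test_cluster_size_models(rng):
    uni = ClusterSizeModel(kind="uniform", low=0, high=32)
    draws = uni.draw(5000, rng)
    assert draws.min() >= 0 and draws.max() <= 32
    # total reads within 4 sigma of n*16 (sum of independent uniforms)
    var = (33**2 - 1) / 12
    assert abs(draws.sum() - 5000 * 16) < 4 * np.sqrt(5000 * var)
    fixed = ClusterSizeModel(kind="fixed", size=7).draw(3, rng)
    assert fixed.tolist() == [7, 7, 7]
    emp = ClusterSizeModel(kind="empirical", sizes=(2, 4)).draw(100, rng)
    assert set(emp.tolist()) <= {2, 4}
    with pytest.raises(ValueError):
        ClusterSizeModel(kind="empirical", sizes=())


def test_generate_dataset_truth_and_shuffling(rng):
    design = generate_design(20, 80, rng)
    reads, truth = generate_dataset(
        design, ClusterSizeModel(kind="fixed", size=10), ErrorModel(), rng
    )
    assert len(reads) == 200
    assert sorted(truth) == sorted(reads.ids)
    # zero-noise copies are labeled back perfectly by best-edit assignment
    relabeled = label_by_best_edit(reads, design)
    assert all(relabeled[r] == truth[r] for r in truth)
    # origins are not blocked in read order (shuffled): the first 10 reads
    # should not all share one origin
    first = {truth[reads[i].id] for i in range(10)}
    assert len(first) > 1


def test_generate_dataset_zero_sizes(rng):
    design = generate_design(3, 20, rng)
    reads, truth = generate_dataset(
        design, ClusterSizeModel(kind="fixed", size=0), ErrorModel(), rng
    )
    assert len(reads) == 0 and len(truth) == 0


def test_xor_worked_examples():
    assert xor_strands("AC", "CG") == "CT"  # 00^01=01=C, 01^10=11=T
    assert xor_strands("ACGT", "AAAA") == "ACGT"  # A is the identity
    with pytest.raises(ValueError):
        xor_strands("AC", "ACG")


def test_pseudo_randomize_involution_exhaustive_length3():
    """Applying the transform twice with one seed restores every design."""
    strands = ["".join(p) for p in product("ACGT", repeat=3)]
    design = Design(tuple(strands))
    once = pseudo_randomize(design, seed=99)
    twice = pseudo_randomize(once, seed=99)
    assert twice.strands == design.strands
    assert once.strands != design.strands


def test_pseudo_randomize_separates_near_duplicates():
    """100 copies of one strand become strands far apart in edit distance."""
    strand = "ACGTTGCAATCGGCTAACGGTTACGGATCCAA"
    design = Design(tuple([strand] * 100))
    masked = pseudo_randomize(design, seed=5)
    rng = np.random.default_rng(0)
    pairs = [(int(a), int(b)) for a, b in rng.integers(0, 100, size=(300, 2))
             if a != b]
    neds = [normalized_edit_distance(masked[i], masked[j]) for i, j in pairs]
    assert np.mean(neds) >= 0.4


def test_channel_rate_report_zero_noise(rng):
    design = generate_design(5, 50, rng)
    reads, truth = generate_dataset(
        design, ClusterSizeModel(kind="fixed", size=4), ErrorModel(), rng
    )
    rep = channel_rate_report(reads, truth, design)
    assert rep.sub_rate == rep.ins_rate == rep.del_rate == 0.0


def test_channel_rate_report_recovers_rates(rng):
    """Observed sub rate on 10^5 bases falls in the CI around p_sub=0.01."""
    design = generate_design(1, 1000, rng)
    reads, truth = generate_dataset(
        design, ClusterSizeModel(kind="fixed", size=100),
        ErrorModel(p_sub=0.01), rng,
    )
    rep = channel_rate_report(reads, truth, design)
    assert rep.n_bases == 100_000
    assert 0.008 <= rep.sub_rate <= 0.012
    assert rep.sub_ci[0] <= 0.01 <= rep.sub_ci[1]


def test_alignment_counts_bounded_by_true_events(rng):
    """Edit alignment can only compress adjacent events, never invent them."""
    design = generate_design(1, 200, rng)
    em = ErrorModel(p_sub=0.02, p_ins=0.02, p_del=0.02)
    reads, truth = generate_dataset(
        design, ClusterSizeModel(kind="fixed", size=100), em, rng
    )
    rep = channel_rate_report(reads, truth, design)
    total_rate = rep.sub_rate + rep.ins_rate + rep.del_rate
    assert 0 < total_rate <= 0.09  # <= ~1.5x the configured 6% total


def test_generator_determinism(rng):
    def build(seed):
        r = np.random.default_rng(seed)
        d = generate_design(5, 40, r)
        return generate_dataset(
            d, ClusterSizeModel(kind="uniform", low=0, high=8),
            ErrorModel(p_sub=0.02, p_ins=0.01, p_del=0.01), r,
        )

    reads1, truth1 = build(7)
    reads2, truth2 = build(7)
    assert reads1.sequences == reads2.sequences
    assert dict(truth1) == dict(truth2)
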