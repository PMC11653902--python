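"""Simulate a small DNA-storage retrieval and cluster it end to end.

Builds a design of 200 random strands, draws noisy copies through an
insertion/deletion/substitution channel, runs the three-stage clustering
pipeline, and scores the result against the generator's ground truth.
"""

import numpy as np

from gradhc import (
    ClusterSizeModel,
    ErrorModel,
    GradHCParams,
    accuracy_curve,
    generate_dataset,
    generate_design,
    gradhc,
    threat_score,
)

rng = np.random.default_rng(42)

# 200 original strands of length 120; each yields 0-20 noisy copies at
# roughly 3% total per-base error (a typical synthesis+sequencing budget).
design = generate_design(num_strands=200, length=120, rng=rng)
reads, truth = generate_dataset(
    design,
    ClusterSizeModel(kind="uniform", low=0, high=20),
    ErrorModel(p_sub=0.015, p_ins=0.0075, p_del=0.0075),
    rng,
)
print(f"simulated {len(reads)} reads from {len(design)} strands")

clustering = gradhc(reads, GradHCParams(seed=7))
print(f"pipeline found {clustering.n_clusters} clusters "
      f"({clustering.singleton_count()} singletons)")

# Threat Score: overlap-maximizing one-to-one match between predicted and
# true clusters, then TP/(TP+FP+FN).  1.0 means a perfect partition.
print(f"threat score: {threat_score(truth, clustering):.4f}")

# Accuracy(gamma): fraction of true clusters recovered by a predicted
# cluster with no foreign reads covering at least a gamma share.
for gamma, acc in accuracy_curve(truth, clustering, [0.6, 0.8, 0.95, 1.0]):
    print(f"accuracy(gamma={gamma:.2f}): {acc:.4f}")
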