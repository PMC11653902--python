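"""The two clustering metrics on a hand-sized example.

Shows how Threat Score and Accuracy(gamma) react differently to a split
cluster: TS degrades smoothly with misplaced reads, while Accuracy(gamma)
counts whole true clusters as recovered or not.
"""

from gradhc import accuracy_gamma, best_injective_map, threat_score

# ground truth: reads a,b together; c alone        -> C  = {{a,b},{c}}
truth = {"a": 0, "b": 0, "c": 1}
# prediction: a alone; b wrongly grouped with c    -> C~ = {{a},{b,c}}
predicted = {"a": 0, "b": 1, "c": 1}

match = best_injective_map(truth, predicted)
print(f"optimal matching pairs: {match.pairs}, total overlap {match.total_overlap}")

# TP=2 (a and c sit in their matched clusters), FN=1 (b missing from {a}),
# FP=1 (b foreign in {b,c}) -> TS = 2/4
print(f"threat score: {threat_score(truth, predicted):.3f}")

# {b,c} mixes both true clusters (it has a false positive), and {a}
# covers only half of {a,b} — below any admissible gamma > 0.5 — so no
# true cluster counts as recovered at either threshold.
for gamma in (0.6, 0.95):
    print(f"accuracy(gamma={gamma}): {accuracy_gamma(truth, predicted, gamma):.3f}")

# a perfect prediction scores 1.0 on both metrics
print(f"perfect TS: {threat_score(truth, truth):.3f}, "
      f"perfect accuracy(0.95): {accuracy_gamma(truth, truth, 0.95):.3f}")
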