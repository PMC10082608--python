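"""Score a prediction list against a gold standard, DREAM-style.

Writes a tiny gold standard and two hand-made prediction files — one good,
one shuffled — and prints AUROC/AUPR for each. Unpredicted gold edges
count against recall, so a truncated list cannot inflate its precision.
"""

import numpy as np

from agrn import GoldStandard, RankedEdgeList, RegulatorSet
from agrn.evaluation import evaluate_predictions

genes = tuple(f"G{i+1}" for i in range(8))
tfs = RegulatorSet(tf_ids=("G1", "G2"))
gold = GoldStandard(labeled_pairs={
    ("G1", "G3"): 1, ("G1", "G5"): 1, ("G2", "G4"): 1, ("G2", "G7"): 1,
})

good = RankedEdgeList(edges=(
    ("G1", "G3", 0.95), ("G2", "G4", 0.90), ("G1", "G5", 0.80),
    ("G1", "G8", 0.40), ("G2", "G7", 0.30),
))

rng = np.random.default_rng(0)
pairs = [(r, t) for r in tfs.tf_ids for t in genes if r != t]
scores = np.sort(rng.random(len(pairs)))[::-1]
shuffled = RankedEdgeList(edges=tuple(
    (pairs[i][0], pairs[i][1], float(s))
    for s, i in zip(scores, rng.permutation(len(pairs)))
))

for name, pred in (("informed ranking", good), ("shuffled ranking", shuffled)):
    result = evaluate_predictions(pred, gold, tfs, genes)
    print(f"{name}: AUROC = {result.auroc:.3f}, AUPR = {result.aupr:.3f} "
          f"({result.n_positives} positives / {result.n_negatives} negatives)")

print("\nAUROC 0.5 is chance level; AUPR baseline is the positive prevalence "
      f"({4 / len(pairs):.3f} here).")
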