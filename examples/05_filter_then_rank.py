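"""Candidate selection: filter with the classifier, rank with the regressor.

Mimics a screening workflow on a toy prediction table: poses scoring below
the classifier threshold are discarded, the survivors are ranked by the
regressor's DockQ estimate, and precision@K reports how many of the top K
ranked candidates are truly native-like.
"""

import numpy as np

from poseqa import ensemble_combine, topk_success

rng = np.random.default_rng(5)
n = 40
labels = rng.integers(0, 2, n)
clf = np.clip(0.55 * labels + rng.random(n) * 0.45, 0, 1)   # noisy classifier
reg = np.clip(labels * 0.5 + rng.random(n) * 0.5, 0, 1)      # noisy DockQ estimate

report = topk_success(clf, reg, labels, clf_threshold=0.5, k_list=(5, 10, 20))
for k, row in report.items():
    extra = " (fewer survivors than K)" if row["truncated"] else ""
    print(f"precision@{k:<3d} = {row['precision']:.2f}{extra}")

# two-model ensemble, following the 0.7/0.3 weighting convention
a, b = 0.91, 0.64
print(f"\nensemble of scores {a} and {b} with weights (0.7, 0.3): "
      f"{ensemble_combine([a, b], [0.7, 0.3]):.3f}")
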