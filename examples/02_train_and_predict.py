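"""Train the boosted-tree classifier on synthetic pairs and score new ones.

Generates a small interaction dataset with a planted physicochemical signal,
splits it in half, fits the gradient-boosted ensemble on one half and reports
accuracy and example probabilities on the other.
"""

import numpy as np

from ppiboost import (
    GBDTConfig,
    SyntheticConfig,
    feature_matrix,
    fit_gbdt,
    generate_ppi_dataset,
)

cfg = SyntheticConfig(n_proteins=400, n_pos=100, n_neg=100, effect=2.5, seed=11)
proteins, pairs = generate_ppi_dataset(cfg)
X, y = feature_matrix(pairs, proteins)

rng = np.random.default_rng(11)
order = rng.permutation(len(y))
train, test = order[:100], order[100:]

model = fit_gbdt(X[train], y[train],
                 GBDTConfig(n_trees=150, max_depth=3, shrinkage=0.1))
proba = model.predict_proba(X[test])
pred = (proba >= 0.5).astype(int)

print(f"trained on {len(train)} pairs, tested on {len(test)}")
print(f"final training deviance: {model.train_deviance[-1]:.4f} "
      f"(from {model.train_deviance[0]:.4f} at the constant model)")
print(f"test accuracy: {(pred == y[test]).mean():.3f}")
for i in test[:5]:
    p = pairs[i]
    print(f"  {p.id_a} x {p.id_b}: true={p.label} "
          f"P(interact)={model.predict_proba(X[i][None, :])[0]:.3f}")
print(
    "\nProbabilities near 1 mean the model sees the shared hydrophobicity\n"
    "profile planted in interacting (same-class) pairs; near 0, the\n"
    "mismatched profiles of cross-class non-interacting pairs."
)
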