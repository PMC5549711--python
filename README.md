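# ppiboost

Sequence-only prediction of protein-protein interactions (PPIs). Most
high-accuracy PPI predictors lean on structure, domain annotations or network
context; `ppiboost` is for the common case where only the primary sequences
are available. It encodes each protein at multiple physicochemical scales,
turns the encodings into a fixed-length descriptor vector, and classifies
protein pairs with a gradient-boosted decision-tree ensemble implemented from
first principles.

## The representation

A protein sequence S = s₁s₂⋯sₙ is encoded under 13 property channels: seven
*qualitative* properties that partition the 20 amino acids into three groups
(hydrophobicity, normalized van der Waals volume, polarity, polarizability,
charge, secondary-structure propensity, solvent accessibility) and six
*quantitative* per-residue scales (hydrophobicity H, side-chain volume VSC,
polarity P1, polarizability P2, solvent-accessible surface area SASA, net
charge index of side chains NCISC), each standardized over the 20 residues:
P′ᵢⱼ = (Pᵢⱼ − P̄ⱼ)/Sⱼ.

Five descriptor families are extracted:

| block | per channel | total |
|---|---|---|
| amino-acid frequency | 20 | 20 |
| composition C (fraction per group) | 3 × 7 | 21 |
| transition T (% adjacent group crossings) | 3 × 7 | 21 |
| distribution D (% chain position of 1st/25/50/75/100% occurrences) | 15 × 7 | 105 |
| auto-covariance AC(lag) = (1/(n−lag)) Σᵢ (vᵢ−v̄)(vᵢ₊ₗₐ𝓰−v̄), lag = 1..30 | 30 × 6 | 180 |

giving a **347-dimensional** protein vector; a pair is the **694-dimensional**
concatenation of its two proteins.

## The classifier

Binary gradient boosting with labels y ∈ {−1, +1} and two-class deviance
L(y, f) = log(1 + exp(−2yf)). The model f_M(x) = f₀ + ν Σₘ Tₘ(x) is grown
stage-wise: each round fits a CART regression tree to the pseudo-residuals
Rᵢ = 2yᵢ/(1 + exp(2yᵢfᵢ)) by least squares, then replaces each leaf value
with a single Newton step cⱼ = Σ Rᵢ / Σ |Rᵢ|(2 − |Rᵢ|). Predictions are
probabilities p(x) = 1/(1 + exp(−2f_M(x))). The implementation is this
package's own (deterministic splits, JSON-serializable models); scikit-learn
appears only as an independent cross-check in the test suite.

## Worked example

`python examples/03_cross_validation.py` runs stratified five-fold
cross-validation on a synthetic benchmark of 200 protein-disjoint pairs whose
interacting pairs share a planted hydrophobicity bias (`effect` controls its
strength), and prints the per-fold percent metrics:

```
=== effect = 2.0 (200 pairs) ===
         acc     sn    ppv  fscore    mcc
fold1  100.0  100.0  100.0   100.0  100.0
...
mean   100.0  100.0  100.0   100.0  100.0

=== effect = 0.0 (200 pairs) ===
         acc     sn    ppv  fscore    mcc
...
mean   53.00  52.00  53.00   52.30   6.06
```

At a strong planted signal the pipeline recovers the interaction rule almost
perfectly; with no signal (effect = 0) accuracy sits at chance, showing the
features and classifier do not manufacture discrimination. The metrics are
accuracy, sensitivity, positive predictive value, F-score and Matthews
correlation coefficient, all computed from the fold's confusion table.

`examples/01_encode_protein.py` shows the descriptor blocks of a single
protein and `examples/02_train_and_predict.py` trains on one half of a
synthetic dataset and scores the other. A thin CLI mirrors the pipeline:
`ppiboost synth | encode | train | predict | evaluate` (see `--help`).

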