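# Methods

## Model and procedure

`ppiboost` frames protein-protein interaction prediction as supervised binary
classification of protein *pairs* from primary sequence alone. The working
assumption is that interaction propensity is shaped by the physicochemical
character of the two chains — their hydrophobicity, charge, polarity, volume
and accessibility profiles — so the representation is built entirely from
per-residue physicochemical annotations, with no homology, structure or
network information.

### Property channels

Thirteen channels are built in (`encoding.py`). Seven qualitative properties
partition the 20 amino acids into three groups each; six quantitative scales
assign each residue a real value. Quantitative scales are standardized over
the 20 canonical residue values — P′ᵢⱼ = (Pᵢⱼ − P̄ⱼ)/Sⱼ with the population
mean and sd of the 20 table entries — *not* over the residues of a particular
sequence: the constants are properties of the scale, and sequence-level
centring happens again inside the auto-covariance. Two data points in the
shipped tables deserve note:

* the secondary-structure Strand group is recorded in its source with a
  duplicated T and no Y, covering only 19 residues; the package amends the
  duplicate to Y, which restores a complete partition and matches the
  standard CTD strand group. The verbatim original is kept in a comment next
  to the table.
* the Y entry of the NCISC scale (0.0323599) has one more digit than every
  other entry and is plausibly a misprint of 0.023599; it is nevertheless
  kept exactly as printed, since the package's contract is the printed table
  and the descriptor is scale-standardized anyway.

Tables are data, not code: `load_property_tables` merges a JSON override
file over the built-ins so alternative scales can be evaluated without
touching the source.

### Descriptors

Per protein (`descriptors.py`): frequency (20), and per qualitative channel
composition (3), transition (3) and distribution (15); per quantitative
channel auto-covariance at lags 1..30. Fixed block order — frequency, the
seven partitions in table order, the six scales in table order — yields 347
values; a pair vector concatenates the two proteins in pair order (694).

Conventions the definitions leave open, fixed here once:

* composition and frequency are fractions in [0, 1]; transition and
  distribution are percents in [0, 100]. Tree ensembles are invariant to
  per-feature monotone scaling, so this only pins the file format.
* the distribution quantile index is ⌈q·m⌉ over the m occurrences of a
  group, with "first" ≡ occurrence 1 and 100% ≡ occurrence m; a group with
  no occurrences contributes five zeros.
* the auto-covariance input is the scale-standardized encoding, and the
  per-sequence mean is subtracted again inside the sum — both centrings are
  applied, as the definitions state them.
* `max_lag` defaults to 30 (smaller lags were reported to lose signal,
  larger ones to add noise); any sequence must be longer than `max_lag`, so
  the practical minimum length is 31. Length is enforced at descriptor time,
  not parse time, so the FASTA reader stays reusable for other purposes.

### Classifier

`gbdt.py` implements stage-wise gradient boosting with CART regression trees,
specialized to two-class deviance L(y, f) = log(1 + exp(−2yf)), y ∈ {−1, +1}
(the loss itself is a free choice in the boosting framework; this is the
standard binary instantiation). The initial score is the deviance minimizer
f₀ = ½ log((1+ȳ)/(1−ȳ)). Each round fits a least-squares tree to the
pseudo-residuals and then re-optimizes each leaf with one Newton-Raphson
step, cⱼ = Σ R / Σ |R|(2−|R|) — the exact per-leaf argmin has no closed form
under deviance, and the single Newton step is the standard surrogate.
Shrinkage ν (default 0.1) scales every tree's contribution; ν = 1 recovers
the plain stage-wise update. Defaults M = 500 trees, depth 3, minimum 5 rows
per leaf — conventional values, exposed in `GBDTConfig`.

Numerical determinism: candidate thresholds are midpoints of consecutive
distinct sorted feature values; equal-gain ties resolve to the lowest feature
index, then the lowest threshold; a split must reduce the squared error by
more than 1e−12 or the node becomes a leaf. Degenerate inputs (single-class
labels, empty nodes) raise rather than guess. The training deviance trace is
recorded per iteration; with Newton leaves and ν ≤ 1 it is non-increasing,
and the tests assert this.

### Evaluation

`evaluation.py` computes ACC, SN, PPV, F-score and MCC from the confusion
table. A metric whose denominator vanishes (e.g. PPV with no positive
predictions) is reported as NaN with an explicit flag — never silently 0 —
so downstream summaries cannot absorb an undefined value unnoticed.
Cross-validation is a stratified random 5-way split (plain random splitting
can produce single-class folds on unbalanced data); summaries are mean ±
sample (n−1) standard deviation over folds.

## Synthetic benchmark

`synthetic.py` generates proteomes with two latent classes. Residues are
i.i.d. from a distribution in which the hydrophobic group {C,L,V,I,M,F,W}
is reweighted by exp(±effect) per class; interacting pairs join two proteins
of the same class, non-interacting pairs cross classes. The signal is
planted through the hydrophobicity partition deliberately: it feeds both the
composition/transition/distribution block and the H auto-covariance block,
so both halves of the representation are exercised.

Two design choices matter for interpretation:

* **Protein-disjoint pairs.** Each protein appears in at most one pair
  (requiring n_proteins ≥ 2(n_pos + n_neg); the default configuration is 800
  proteins for 400 pairs). With reused proteins a cross-validated classifier
  can score far above chance at zero planted signal by memorizing individual
  proteins shared between training and test pairs — a known leakage mode of
  PPI benchmarks. Disjoint pairs make the null honest: at effect = 0,
  accuracy is ≈ 0.5 by construction.
* **Defaults as study conditions.** Lengths are uniform on 50–300 (small to
  medium globular proteins; also comfortably above the lag-30 minimum),
  400 balanced pairs, single global seed from which all streams derive.

What the generator does *not* emulate: real interactome topology (hubs,
degree heterogeneity, shared partners), homology structure between proteins,
domain-level interaction grammar, or any correlation along the chain
(residues are i.i.d. given the class). Passing the synthetic suite therefore
shows that the pipeline recovers a planted physicochemical composition
signal and does not fabricate one — it says nothing about accuracy on real
interactomes, which depends on data this package does not ship.

## Problem sizes

The expensive checks run at deliberately modest scale, chosen once as the
package's benchmark conditions: end-to-end cross-validation uses 400 pairs
(800 proteins) with M = 200 trees at depth 3; the signal-monotonicity
property uses 80-pair datasets at effect ∈ {0, 1, 2, 3} with M = 60; the
descriptor-oracle comparison uses 200 random sequences of length 31–500
(20 in the acceptance script). On one CPU the full test suite finishes in a
few minutes.

## Known limitations

* The boosting core supports exactly one loss (two-class deviance) and no
  row/column subsampling or early stopping — deliberately, matching the
  plain stage-wise algorithm it implements.
* Pair vectors are order-dependent: (A,B) and (B,A) encode differently.
  `five_fold_cv` uses pairs as given; training with both orderings is left
  to the caller by augmenting the pair list.
* Distribution's ⌈q·m⌉ convention and the empty-group zeros are one of
  several CTD variants in circulation; comparisons against other toolkits
  should check this convention first.
* Sequences shorter than 31 residues cannot be featurized at the default
  lag; real datasets commonly exclude proteins under 50 residues anyway.
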