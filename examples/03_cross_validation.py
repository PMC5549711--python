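"""Five-fold cross-validation of the full pipeline, with and without signal.

Runs the stratified five-fold protocol on a synthetic benchmark at a strong
planted signal and at the null, printing the per-fold metric table (percent)
in the fold-rows-plus-Average/Std layout.
"""

from ppiboost import GBDTConfig, SyntheticConfig, five_fold_cv, generate_ppi_dataset

gcfg = GBDTConfig(n_trees=100, max_depth=3, min_samples_leaf=5, shrinkage=0.1)

for effect in (2.0, 0.0):
    cfg = SyntheticConfig(n_proteins=400, n_pos=100, n_neg=100,
                          effect=effect, seed=4)
    proteins, pairs = generate_ppi_dataset(cfg)
    result = five_fold_cv(pairs, proteins, gcfg, seed=4)
    print(f"\n=== effect = {effect} ({len(pairs)} pairs) ===")
    print(result.to_frame(percent=True).round(2).to_string())

print(
    "\nAt a strong planted signal every metric should sit far above 50%;\n"
    "at effect = 0 the proteins carry no class information and accuracy\n"
    "falls to chance, confirming the pipeline does not manufacture signal."
)
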