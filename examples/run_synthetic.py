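"""Select genes on a planted-signal synthetic dataset.

Generates 40 samples x 200 genes with 5 informative genes across 3
classes, runs the full hybrid search, and prints what it found. The
planted positions are known, so you can see directly whether the
selected subset contains real signal.
"""

from hicats import HicatsConfig, SyntheticSpec, make_synthetic, run_hicats

spec = SyntheticSpec(n_samples=40, n_genes=200, n_informative=5, n_classes=3,
                     effect_size=3.0, noise_sd=1.0, seed=1)
dataset, planted = make_synthetic(spec)
print(f"planted informative genes (1-based): {planted}")

config = HicatsConfig(cv=5, seed=1)  # stratified 5-fold keeps this quick
result = run_hicats(dataset, config)

print(f"best cross-validated accuracy: {result.best_accuracy * 100:.2f}%")
print(f"selected {result.best_n_selected} of {dataset.n} genes: {result.selected_genes}")
print(f"overlap with planted signal: {sorted(set(result.selected_genes) & set(planted))}")
print(f"classifier fits spent: {result.n_evaluations}")
# accuracy near 100% with a handful of genes, at least one of them
# planted, shows the wrapper search recovering the real signal rather
# than memorising noise
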