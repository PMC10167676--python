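"""Compare AE+CNN with PCA/SVM/RF baselines over shared splits.

Runs the six-method comparison (latent CNN; SVM and random forest on PCA
or flattened-latent features; raw-volume CNN) on identical site-stratified
splits and reports mean accuracies and the paired t-test of AE+CNN against
the strongest baseline. Shared splits make the per-split accuracies paired
observations.
"""

from dbmorph.autoencoder import encode_batch, train_autoencoder
from dbmorph.benchmark import benchmark_methods
from dbmorph.classifier import stratified_split
from dbmorph.stats import paired_accuracy_ttest
from dbmorph.synthetic import generate_cohort, strong_regions

dims = (24, 28, 24)
cohort = generate_cohort(n_cases=48, n_controls=48, dims=dims,
                         regions=strong_regions(dims), seed=4)
data = cohort.volume_array()
split = stratified_split(cohort, test_ratio=0.2, seed=4)
ae, _ = train_autoencoder(data, split, steps=600, seed=4)
latents = encode_batch(ae, data)

table = benchmark_methods(data, cohort.labels, cohort.sites, latents,
                          n_splits=8, seed=4,
                          cnn_kwargs=dict(max_steps=800, check_every=100))
means = table.groupby("method")["accuracy"].mean().sort_values(ascending=False)
print(means.to_string())

acc = table.pivot(index="split_id", columns="method", values="accuracy")
best_baseline = means.drop("ae_cnn").idxmax()
t = paired_accuracy_ttest(acc["ae_cnn"], acc[best_baseline])
print(f"\nAE+CNN vs {best_baseline}: mean diff {t['mean_diff']:+.3f}"
      + ("" if t["degenerate"] else f", t = {t['t']:.2f}, p = {t['p']:.3g}"))
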