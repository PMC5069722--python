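"""Rank feature/channel combinations by the Bhattacharyya separability index.

The SI of a column is the *minimum* pairwise Bhattacharyya distance between
the four motion-class distributions, pooled over all wrist positions — a
worst-case measure of how well that single feature/channel tells every pair
of postures apart.
"""

from emgsel import (
    EvalConfig,
    build_feature_matrix,
    default_layout,
    generate_dataset,
    preset,
    rank_features_si,
)

layout = default_layout(2, 1)
trials = generate_dataset(preset("amputee-like", layout=layout, repetitions=3, seed=1))
fm = build_feature_matrix(trials, "combined", "ALL", EvalConfig(increment_ms=100.0))

top, table = rank_features_si(fm)
print(f"ranked {fm.n_columns} columns; SI set keeps the top {len(top)} "
      f"(= 10 x {layout.n_channels} channels, the TDAR-set size)\n")

si = dict(zip(table.columns, table.si))
print("best 8 feature/channel combinations:")
for ch, feat in top[:8]:
    print(f"  {ch}:{feat:<7} SI = {si[(ch, feat)]:.3f}")
print("\nworst 4:")
order = sorted(table.columns, key=lambda c: si[c])
for ch, feat in order[:4]:
    print(f"  {ch}:{feat:<7} SI = {si[(ch, feat)]:.4f}")

print("\nAmplitude statistics dominate the top of the list; scale-invariant "
      "features (ZC, AR, spectral) score near zero because every class "
      "shares the same spectrum in this preset.  A large SI means even the "
      "closest pair of postures is well separated on that column.")
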