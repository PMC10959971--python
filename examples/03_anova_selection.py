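"""Find class-informative features with the one-way ANOVA F statistic.

Plants 10 informative columns (2-pooled-SD class shifts) among 200 noise
columns and shows that top-10 selection recovers them.
"""

from histospect import (FeatureTableSpec, anova_f_scores,
                        generate_feature_table, select_top_k)

fm, truth = generate_feature_table(FeatureTableSpec(
    n_samples=300, n_features=200, n_informative=10, effect_size=2.0, seed=42))

scores = anova_f_scores(fm)
sel = select_top_k(scores, 10)

print(f"true informative columns: {truth.tolist()}")
print(f"selected columns:         {sel.selected_indices.tolist()}")
hits = len(set(sel.selected_indices) & set(truth))
print(f"recovered {hits}/10; "
      f"mean F of selected {scores.f_values[sel.selected_indices].mean():.1f} "
      f"vs {scores.f_values.mean():.2f} overall")

# Informative columns score F in the hundreds while noise columns sit near
# E[F] ~ 1, so the top-10 set recovers the planted columns.
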