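"""Fit the leakage-safe preprocessing chain and inspect its guarantees.

Per-block principal components are fit on training data, every feature is
residualized on its block's PCs, continuous features are Z-scored, and the
stored parameters are applied unchanged to held-out samples.
"""

import numpy as np

from fedomics import CohortSpec, Preprocessor, generate_cohort

fm, _ = generate_cohort(CohortSpec(n_cases=80, n_controls=200, seed=3))
train = fm.subset_samples(np.arange(0, 200))
held = fm.subset_samples(np.arange(200, 280))

pre = Preprocessor(n_pcs=10, select=True, keep=50, n_trees=128)
pre.fit(train)
train_t = pre.transform(train)
held_t = pre.transform(held)

scores = pre.pca_transcriptomic.scores(train)
resid = train.subset_features(pre.pca_transcriptomic.feature_names)
print(f"transcriptomic PCs: {scores.shape[1]} components fitted on train")
print(f"explained variance (first 3): {pre.pca_transcriptomic.explained_variance[:3].round(2)}")
print(f"selected features after importance ranking + r^2<=0.36 pruning: {len(pre.selected_features)}")
print(f"  top 5: {pre.selected_features[:5]}")
print(f"held-out matrix after transform: {held_t.values.shape} (train stats applied, no refit)")
# Means of the transformed *training* matrix are 0 by construction; the
# held-out means are close but not exactly 0 — that asymmetry is the
# train/apply separation working as intended.
cont = [f for f in pre.z_params.mean if f in set(train_t.feature_names)]
j = [list(train_t.feature_names).index(f) for f in cont[:50]]
print(f"train column means (max |.|): {np.abs(train_t.values[:, j].mean(0)).max():.2e}")
jh = [list(held_t.feature_names).index(f) for f in cont[:50] if f in set(held_t.feature_names)]
print(f"held-out column means (max |.|): {np.abs(held_t.values[:, jh].mean(0)).max():.2f}")
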