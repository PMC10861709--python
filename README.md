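# rbp — Region Based Pooling for varying EEG channel systems

Deep-learning models for EEG are usually tied to one electrode montage: a
network trained on 129-channel recordings cannot ingest a 32-channel
recording.  **Region Based Pooling (RBP)** removes that constraint.  The
projected electrode montage is partitioned repeatedly into non-overlapping
geometric regions (each partition is a *montage split* `M_i = {R_1^(i), …,
R_{m_i}^(i)}`); for a recording from any channel system `C`, the channels
falling inside each region, `R_j^(i) ∩ C`, are pooled into a single *region
representation* time series; the representations of all splits are
z-normalized over time and row-concatenated.  Every compatible channel
system — whatever its channel count — therefore maps to the same
`Σ_i m_i × T` matrix, which any downstream time-series model can consume.

The package implements, in pure scientific Python:

- **Montage geometry** (`rbp.channel_systems`): plain-text montage files,
  azimuthal-equidistant projection to 2-D, nested subset systems.
- **Randomized angular partitioning** (`rbp.montage_split`): recursive
  equal-channel-count sector cuts driven by a split vector
  `k = (k_1, …, k_p)` with a `min_nodes` stopping rule evaluated against a
  declared minimum-resolution system, so any system at least that dense is
  compatible by construction.
- **Four pooling mechanisms** (`rbp.pooling`): channel average; channel
  attention scored linearly on frozen random-convolution (ROCKET) features
  (proportion-of-positive-values and maximum per kernel, precomputable per
  subject); continuous (per-timestep) channel attention with a small
  Inception scorer; and head-region pooling, where a designated region emits
  search embeddings `s = [(W₁Z) ⊙ softmax(W₂Z)]·1` that steer the other
  regions' attention through softmaxed cosine similarity.
- **The RBP layer** (`rbp.rbp_layer`): builds splits and per-region
  trainable parameters, registers channel systems, and persists everything
  to a single checksummed container file, bit-exactly.
- **Baselines** (`rbp.baselines`): zero-filling of missing channels and
  spherical spline interpolation (Perrin-style kernel
  `g(x) = (1/4π) Σₙ (2n+1)/(nᵐ(n+1)ᵐ) Pₙ(x)`), both reduced to precomputed
  linear maps.
- **A compact InceptionTime-style classifier** (`rbp.inception`) with a
  sigmoid scalar head, trained with Adam on binary cross-entropy over raw
  logits — running on a small built-in NumPy reverse-mode autodiff engine
  (`rbp.nn`).
- **Synthetic study data** (`rbp.synthetic`): nested 129/65/32 montages and
  recordings with 1/f background noise plus a spatially localized,
  class-dependent 8–12 Hz oscillation.
- **Evaluation harness** (`rbp.harness`): stratified k-fold cross-validation,
  75/25 train/validation splits, per-epoch model selection on the mean
  validation AUC across channel-system versions, and a
  `min_nodes × num_montage_splits` grid search.

## Worked example

```python
import numpy as np
from rbp import (
    SyntheticDatasetSpec, generate_dataset, build_rbp, RBPConfig,
    build_interpolator, interpolate, zero_fill,
)

data = generate_dataset(SyntheticDatasetSpec(n_subjects=4, seed=7))
base, s32 = data.systems["synthetic129"], data.systems["synthetic32"]

layer = build_rbp(
    RBPConfig(num_montage_splits=5, min_nodes=2, seed_splits=0, seed_weights=1),
    base, s32,
)
for name in data.system_names():
    layer.register_channel_system(data.systems[name])
print(f"layer: {len(layer.splits)} montage splits, {layer.total_regions} regions")

X129 = data.X_base[0]
X32 = data.recordings_for("synthetic32")[0]
print(X129.shape, "->", layer.transform(X129, "synthetic129").shape)
print(X32.shape, "->", layer.transform(X32, "synthetic32").shape)
```

prints

```
layer: 5 montage splits, 52 regions
(129, 256) -> (52, 256)
(32, 256) -> (52, 256)
```

The same layer maps the 129-channel and the 32-channel recording to the same
52-row representation — that is the fixed-dimension contract.  Each row has
temporal mean ≈ 0 and standard deviation ≈ 1 (here max |mean| 5.6e-17, max
|sd−1| 2.2e-08).  The baselines map the 32-channel recording back onto the
129-channel montage instead: `interpolate(X32, build_interpolator(s32,
base))` and `zero_fill(X32, s32, base)` both return a `(129, 256)` array.

A command-line interface mirrors the library:
`rbp synth`, `rbp build`, `rbp register`, `rbp transform`,
`rbp harmonize --method {zero_fill,spline}`, and `rbp experiment --config
run.yaml`.

## Documentation

`docs/methods.md` describes the model, the synthetic-data generator and its
calibration, the numerical choices, and known limitations.
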