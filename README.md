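# gastroql

Two-phase analysis of gastrointestinal endoscopy images:

1. **Classification** — a compact CNN is trained supervised on labelled
   frames, then frozen; its 64-d embedding becomes the *state* of a
   tabular Q-learning agent whose *actions* are class labels. The agent
   earns +1 for a correct prediction and −1 otherwise and learns a
   state→class policy stored in a Q-table.
2. **Segmentation** — an attention-gated U-Net delineates lesion regions
   (ulcers, polyps) as binary masks, trained with pixel-wise binary
   cross-entropy.

The package targets researchers who want a small, fully inspectable
reference implementation of this reinforcement-driven classification +
attention segmentation pipeline. Everything runs on plain numpy (the
networks are built on a minimal autograd engine included in
`gastroql.nn`), and deterministic synthetic fixtures emulate the class
structure of public endoscopy benchmarks (Kvasir, Nerthus, CVC-ClinicDB)
so the whole pipeline is testable without downloads.

## The models

**Q-learning classifier.** Images are resized to 64×64, scaled to
[0, 1], and passed through conv(32, 3×3) → ReLU → maxpool(2×2) →
conv(64, 3×3) → ReLU → maxpool(2×2) → flatten → dense(64) + ReLU. The
network is pretrained with AdamW (batch 32, element-wise binary
cross-entropy on one-hot targets), the head is detached and the backbone
frozen. The embedding *f* ∈ ℝ⁶⁴ is discretised into a state key *s* by
thresholding each component at its training-set median. Training runs
episodes of 100 image samples; at each step the agent picks an action by
the ε-greedy rule

    a = random action            with probability ε
    a = argmax_a Q(s, a)         otherwise

receives reward r ∈ {+1, −1}, and updates

    Q(s,a) ← Q(s,a) + α [ r + γ·max_a′ Q(s′,a′) − Q(s,a) ]

with s′ the next image's state (bootstrap term zero at the episode's
last step). Defaults: α = 0.1, γ = 0.6, ε = 0.1, 1000 episodes.
Prediction is the greedy argmax; accuracy is correct/total × 100.

**Attention U-Net.** Encoder blocks of two 3×3 conv + ReLU with 2×2 max
pooling, transpose-conv upsampling, and an additive attention gate on
each skip connection: with skip features x and coarser gating signal g,

    α_att = σ( ψ( ReLU( W_f·x + W_g·g ) ) ),   x′ = α_att · x

(1×1 projections; g bilinearly resized to x's resolution). Defaults:
input 128×128, depth 4, base 16 filters, Adam, batch 8, 50 epochs,
prediction threshold 0.5. Reported metrics: Dice = 2|y∩ŷ|/(|y|+|ŷ|),
IoU = |y∩ŷ|/(|y∪ŷ|+ϵ), and pixel accuracy.

## Worked example

```python
import numpy as np
from gastroql import (FixtureSpec, classification_arrays, normalize_intensity,
                      CNNFeatureExtractor, QLearningClassifier)

spec = FixtureSpec(task="classification", num_classes=4, n_per_class=50,
                   image_size=64, seed=1)
X, y = classification_arrays(spec)          # 200 synthetic endoscopy-style frames
X = np.stack([normalize_intensity(im) for im in X])
features = CNNFeatureExtractor(epochs=5, random_state=1).fit(X[::2], y[::2])
clf = QLearningClassifier(episodes=200, random_state=1)
clf.fit(features.transform(X[::2]), y[::2])
acc = clf.score(features.transform(X[1::2]), y[1::2])
print(f"held-out accuracy: {100*acc:.1f}%")
print(f"mean episode reward, first 10: {clf.reward_curve()[:10,1].mean():.1f}")
print(f"mean episode reward, last 10:  {clf.reward_curve()[-10:,1].mean():.1f}")
print(f"distinct Q-table states: {len(clf.q_table_)}")
```

prints

```
held-out accuracy: 100.0%
mean episode reward, first 10: 84.6
mean episode reward, last 10:  86.0
distinct Q-table states: 6
```

The four texture/colour populations are separable by construction, so
the frozen CNN collapses each class onto a few stable state keys (6
here), the agent's per-episode reward (sum of ±1 over 100 steps) sits
far above the chance level of −50, and the greedy policy classifies the
held-out half perfectly.

The same workflow is available from the shell:

```
gastroql generate-fixtures --task classification --out data/cls --seed 1
gastroql train-classifier --data data/cls --out runs/cls --episodes 200 --seed 1
gastroql generate-fixtures --task segmentation --out data/seg --size 64 --seed 1
gastroql train-segmenter --images data/seg/images --masks data/seg/masks \
    --out runs/seg --size 64 --epochs 10 --seed 1
```

`train-classifier` writes the Q-table (JSON), the reward curve,
confusion matrix and per-class precision/recall/F1 (CSV);
`train-segmenter` writes predicted masks, green-contour overlays, a
training-history CSV and per-image Dice/IoU/accuracy. A combined
`gastroql pipeline` command gates segmentation on the classifier's
predicted classes (`--segment-classes`).

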