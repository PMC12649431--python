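# Methods

## Overview

`gastroql` implements a two-phase pipeline for gastrointestinal
endoscopy frames: (i) image classification by a tabular Q-learning agent
operating on frozen CNN feature states, and (ii) binary lesion
segmentation by an attention-gated U-Net. This note records the models,
their assumptions, the parameters that matter, the synthetic data used
for validation, and the design choices made where the design was
genuinely open.

## Classification phase

### CNN feature extraction

The backbone is deliberately small: conv(32, 3×3, same) → ReLU →
maxpool(2×2) → conv(64, 3×3, same) → ReLU → maxpool(2×2) → flatten
(16·16·64 = 16384 for 64×64 input) → dense(64) + ReLU, followed by a
dense classification head. Same padding is the default so that pooling
yields the clean 64→32→16 spatial chain; a valid-padding mode exists
(odd intermediate sizes are cropped by the pooling operator).

The full network (backbone + head) is trained supervised with AdamW
(lr 10⁻³, decoupled weight decay 0.01), batch size 32. The default loss
is element-wise binary cross-entropy of sigmoid outputs against one-hot
targets — i.e. a multi-label BCE used for single-label data — with a
categorical softmax cross-entropy switch (`loss="softmax"`). The BCE
variant is the default because it keeps K-class training coherent while
using a plain binary cross-entropy per output unit; on the separable
fixtures both reach the same ceiling. Default pretraining length is 10
epochs (configurable); the separable fixtures converge in 3–5.

After pretraining the head is discarded and the backbone frozen.
Freezing is essential: tabular Q-learning assumes a stationary state
distribution, which would be violated if CNN weights kept moving during
agent training. All post-ReLU activations, including the 64-d embedding,
are non-negative by construction.

### State discretisation

A Q-table needs discrete keys, but CNN embeddings are continuous. The
encoder thresholds each of the 64 features at its **training-set
median** and serialises the resulting sign pattern (feature > threshold)
as a 64-bit key. This is deterministic, adapts to the training
distribution, never fails on unseen vectors, and bounds table size at
the number of distinct observed patterns. After supervised pretraining
on well-separated classes the embedding collapses strongly per class,
so each class occupies a handful of stable keys (6 states for the
4-class fixture); features that are dead (always 0) have threshold 0
and contribute a constant bit.

The cost of this scheme is that a test image whose bit pattern never
occurred in training reads an all-zero Q-row and falls back to action 0;
evaluation warns with the unseen-state rate when this happens. With
weakly clustered features the number of states grows exponentially and
generalisation degrades — the scheme relies on the pretraining stage
doing its job.

### Q-learning

Agent parameters (defaults): learning rate α = 0.1, discount γ = 0.6,
exploration ε = 0.1, 1000 episodes of max_steps = 100 image samples,
rewards fixed at +1 (correct) / −1 (incorrect). An episode samples 100
images with replacement from the training set (sampling without
replacement is a config option when the set is large enough);
classification has no natural dynamics, so the successor state s′ is
simply the state of the next sampled image and the bootstrap term is
zeroed at the episode's final step. Under |r| ≤ 1 this confines every
Q-value to [−1/(1−γ), 1/(1−γ)] = [−2.5, 2.5], which the tests assert.

Ties in the greedy argmax break toward the lowest action index, making
selection fully deterministic given the table. Prediction at test time
is purely greedy (ε = 0). Per-episode totals of ±1 rewards over 100
steps are always even — a parity invariant the episode logs must
satisfy.

### Evaluation

Accuracy is correct/total × 100. The confusion matrix uses rows = true
class, columns = predicted. Per-class precision, recall and F1 are
computed with zero-division reported as 0 plus a warning. Because
per-class "accuracy" is ambiguous in the field's reporting, the report
carries both the overall accuracy and each class's one-vs-rest accuracy,
labelled as such.

## Segmentation phase

### Architecture

A U-Net of configurable depth d (default 4) and base width b (default
16): encoder blocks of two 3×3 conv + ReLU with channel widths b·2ⁱ,
2×2 max pooling between levels, a bridge block, and a decoder using 2×2
stride-2 transposed convolutions. Input size must be divisible by 2^d.
The head is a 1×1 convolution with sigmoid, so outputs are per-pixel
probabilities strictly inside (0, 1).

Each skip connection passes through an additive attention gate before
concatenation. Skip features x and the gating signal g — the decoder's
coarser-resolution tensor, the standard choice — are projected by 1×1
convolutions to an intermediate width (half the skip channels); the
projected gate is bilinearly resized to the skip's resolution; the sum
passes through ReLU, a 1×1 single-channel projection ψ and a sigmoid to
give per-location coefficients α_att ∈ (0, 1); the gate returns
α_att·x. With all gate parameters zero the output is exactly 0.5·x
(σ(0) = ½), a property the tests pin down. Setting
`attention_on_skips=False` yields a plain U-Net with identical shapes.

### Training

Adam (lr 10⁻³), batch size 8, 50 epochs by default. The loss is mean
pixel-wise binary cross-entropy with predictions clipped at 10⁻⁷ to
avoid log 0; a uniform prediction of 0.5 gives exactly ln 2 per pixel.
Masks are binary {0, 1}; prediction thresholds probabilities at 0.5.
When validation pairs are supplied the per-epoch history records
validation loss, Dice and pixel accuracy on thresholded predictions,
and an optional `early_stop_dice` halts training once validation Dice
reaches the requested level.

### Metrics

Dice = 2|y∩ŷ|/(|y|+|ŷ|) with the 0/0 (both-empty) case defined as 1.0;
IoU = |y∩ŷ|/(|y|+|ŷ|−|y∩ŷ|+ϵ) with stabiliser ϵ = 10⁻⁷ by default;
pixel accuracy is the fraction of matching pixels. IoU ≤ Dice always,
with the algebraic identity IoU = Dice/(2−Dice) holding up to ϵ.

## Numerical engine

No deep-learning framework is used; both networks run on a small
reverse-mode autograd engine (`gastroql.nn`) over float32 numpy arrays
in NCHW layout. Convolutions use im2col with matrix multiplication;
transposed convolution and bilinear resizing are expressed with einsum
and separable interpolation matrices; 2×2 max pooling records argmax
indices for exact gradient routing. Every operation's gradient is
validated against central finite differences in the test suite. All
randomness (initialisation, shuffling, ε-greedy draws, episode
sampling) flows from explicit integer seeds through
`numpy.random.default_rng`, so fixed seeds reproduce runs exactly.

## Data handling

Images load from one-folder-per-class trees (labels assigned by the
caller's class-name order) and are resized bilinearly; masks resize by
nearest neighbour and are binarised at 0.5 after rescaling to [0, 1],
preserving the {0, 1} invariant the metrics assume. Intensity
normalisation is exactly I/255.

Flip augmentation returns the originals plus **exactly one** flipped
copy per original — the doubling that matches reported post-augmentation
dataset sizes (8000 → 16 000; 5525 → 11 050) — with the axis (horizontal
or vertical) drawn per record from a seeded generator and masks flipped
together with images.

The hold-out split (default fraction 0.5) shuffles within each class and
rounds the train count half-up, so per-class metrics are computable on
both sides; a class with fewer than two members goes to train with a
warning. The pipeline splits **before** augmenting and augments the two
halves independently: augmenting first would place near-duplicates
(mirror images) of training frames into the test half and inflate
scores.

## Synthetic fixtures

The classification generator draws K populations at 64×64×3: each class
has a distinct mean RGB (hue c/K, fixed saturation/value), a
class-specific sinusoidal texture (frequency 3+c, amplitude 15,
orientation πc/K), and additive Gaussian pixel noise (sd 10 on the
0–255 scale). Classes are separable from mean colour alone — verified
by a nearest-centroid oracle — so a sound pipeline's ceiling is 100%
and the ≥95% recovery check is meaningful rather than data-limited.

The segmentation generator places 1–3 brighter ellipses (semi-axes
between size/16 and size/8, random orientation) on a smooth textured
background (level 0.35, low-frequency texture, pixel noise sd 10) with
an intensity contrast of 0.4; the mask is the exact ellipse indicator.
Thresholding at the contrast midpoint recovers the mask almost
perfectly, which the tests use as a generative oracle. Contrast and
noise are monotone difficulty knobs.

These fixtures emulate the *statistical* structure the method assumes —
colour/texture-separable classes, bright compact lesions — not real
endoscopy: no specular highlights, occlusions, camera distortion or
inter-patient variability. Passing the recovery checks demonstrates the
pipeline's correctness and capacity on in-model data; it does not
predict clinical performance.

## Problem sizes for validation

The bundled checks run at reduced scale, chosen so the full suite
completes quickly on a single CPU while still exercising every stage:
4 classes × 50 images at 64×64 with 5 pretraining epochs and 200
episodes for classification recovery (the reference protocol's 1000
episodes are the library default), and 200 ellipse pairs at 64×64 with
depth 4 / base 16 and at most 10 epochs (with early stopping at Dice
0.90) for segmentation recovery. At these sizes classification recovery
reaches 100% held-out accuracy and validation Dice reaches 0.90–0.94
within 6–9 epochs across seeds.

## Known limitations

- The median-threshold state encoder depends on strong feature
  collapse; with overlapping classes the Q-table fragments into many
  states and unseen-state fallback (class 0) dominates.
- Tabular Q-learning cannot interpolate between states; it is a lookup
  policy, not function approximation.
- The numpy engine is single-threaded BLAS-bound; it is sized for the
  64–128 pixel regime, not for large-scale training.
- "Weighted IoU" variants beyond the stabilised Jaccard index above are
  not implemented.
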