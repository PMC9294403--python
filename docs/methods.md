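# Methods

## Problem setting

Cryo-electron tomography captures macromolecules *in situ* as small cubic
subvolumes ("subtomograms") at very low signal-to-noise ratio. Classifying
these subtomograms into structurally homogeneous groups is the gateway to
subtomogram averaging. Supervised 3D CNNs classify well but only for classes
seen in training; adapting them to a *novel* class normally needs thousands
of new labels. `fscc` implements a few-shot alternative: a class unseen
during training is learned from K ∈ {1..5} labeled examples.

The model is two-stage:

1. **Pre-training** on base classes (abundant labels). A six-block 3D
   convolutional feature extractor f_θ plus a linear softmax head is trained
   with the weighted objective

       L = L_CE + λ · L_SCL,        λ = 0.05 by default,

   where L_CE is mean cross-entropy and L_SCL is the supervised contrastive
   loss with temperature τ = 0.07: for each anchor i whose class has N_{y_i}
   ≥ 2 members in the batch,

       L_i = −(1/(N_{y_i}−1)) Σ_{j≠i, y_j=y_i}
              log [ exp(z_i·z_j/τ) / Σ_{k≠i} exp(z_i·z_k/τ) ],

   summed over the batch. Anchors exclude themselves from the positive set
   (the N−1 normalizer presumes this); singleton classes contribute zero
   with a warning. Embeddings z are L2-normalized inside the loss (τ = 0.07
   is calibrated for unit-norm embeddings) while the raw nonnegative
   features feed the classifier and stage 2; a flag disables normalization.
   Mini-batches are class-balanced so contrastive positives always exist;
   when the batch size is not a multiple of the class count the remainder
   goes to randomly chosen classes (per-class counts differ by ≤ 1).

2. **Classifier retraining by distribution calibration.** The extractor is
   frozen. For each novel support feature v: apply the Tukey ladder of
   powers ṽ = v^λ (log at λ = 0; default λ = 0.5) to make the feature
   distribution more Gaussian; find the k base classes (default k = 2)
   whose means are nearest to ṽ in Euclidean distance (ties by ascending
   class id); form the calibrated Gaussian

       μ′ = (Σ_{i∈S} μ_i + ṽ) / (k+1),    Σ′ = (Σ_{i∈S} Σ_i) / k,

   from the base-class means μ_i and unbiased covariances Σ_i (divisor
   n−1); draw 150 synthetic features per support example from N(μ′, Σ′ +
   εI); train a multinomial logistic classifier (ridge penalty 1.0, LBFGS
   to convergence) on the transformed support features plus all sampled
   features. Queries are classified after the same Tukey transform.

**Feature-space consistency.** The calibration equations compare and average
base-class means with the transformed support vector, so base statistics
must be computed *in the transformed space*. Computing them on raw features
while transforming support and query (a literal reading of the printed
recipe, which never mentions transforming base features) mixes two scales
and collapsed calibrated accuracy to near chance on our benchmark;
`compute_base_statistics(..., tukey_lambda=...)` therefore transforms the
base features first, and every pipeline entry point does so.

## Architecture

The extractor is six ConvBlocks (3×3×3 convolution, stride 1, 'same'
padding → batch normalization → ReLU → optional 2×2×2 max pooling),
followed by global average pooling, so the embedding width equals the last
convolution width and features are elementwise nonnegative — the domain the
Tukey transform requires. Pooling after every block is impossible for 32³
inputs (32/2⁶ < 1); the default pools after blocks 1–4, leaving a 2³ grid
before global pooling for both 32³ and 28³ inputs. When the package runs
reduced 16³ volumes it pools after blocks 1–3, preserving the same 2³
pre-pooling grid as the full-size layout. Channel widths default to 64 per
block (16 in the reduced setting). The exact widths/pooling of the original
description are not recoverable from its text; these defaults are declared
choices.

The network, batch normalization, pooling, Adam and the full backward pass
are implemented in NumPy (`fscc._nn`); every analytic gradient is checked
against central finite differences in the test suite. Checkpoints are
single `.npz` archives carrying parameters, running batch-norm statistics,
the architecture config and a version field.

## Optimization defaults

| parameter | default | note |
|---|---|---|
| λ (contrastive weight) | 0.05 | recommended operating point |
| τ (temperature) | 0.07 | standard contrastive value |
| optimizer / lr | Adam, 0.05 | published recipe; 0.05 is unusually high for Adam — the test suite trains at 1e-3 |
| batch / epochs | 128 / 5 (large data), 32 / 50 (small) | |
| Tukey λ | 0.5 | square root |
| k (neighbor base classes) | 2 | value used in the calibration literature; never stated by the source |
| sampled features per support | 150 | literature-scale; keeps retraining sub-second |
| ridge ε on Σ′ | 1e-6 × mean diagonal | Σ′ can be rank-deficient |
| Q (queries/class/episode) | 15 | episodic-evaluation convention |
| episodes per evaluation | 100 (reference protocol), 30 in the reduced run | |

Numerical choices: log-sum-exp with max subtraction inside the contrastive
loss; probabilities clamped at 1e-12 in cross-entropy; feature entries of
exactly 0 are legal at λ = 0.5 (0^0.5 = 0) and floored at 1e-6 only when
λ ≤ 0; covariance sampling uses the eigendecomposition method, which is
stable for PSD-up-to-roundoff matrices; distance ties in neighbor selection
break by ascending class id; all randomness flows from explicit integer
seeds (per-episode seeds are master_seed + task index), so every run is
bit-reproducible and CLI reports are written at fixed precision to be
byte-identical across reruns.

## Metrics

Episode accuracy is the fraction of correctly labeled queries, equivalently
(TP+TN)/(TP+TN+FP+FN) on pooled one-vs-rest counts. F1 = 2TP/(2TP+FN+FP)
per class one-vs-rest, macro-averaged; a vanishing denominator defines
F1 = 0 with a warning. Reports carry the full per-task accuracy list plus
mean, std and the 95% normal-theory half-width, because a bare "±" value is
ambiguous.

The fine-tuning baseline comparator freezes the same extractor and trains a
plain softmax head on the raw (untransformed) support features of one
support draw, by full-batch Adam (default 300 steps, lr 0.01 — effectively
to convergence). This is deliberately a *strong* baseline: an under-trained
head would flatter calibration. A 10-redraw variant of the comparison
condition found elsewhere is out of scope by default since it spends a 10×
label budget.

## Synthetic data

`fscc.synthetic` provides two generators.

**Subtomogram simulator.** Classes are geometric density phantoms (sphere,
ellipsoid, dumbbell, rod, hollow shell, L-tetromino primitives; binary
density, centered, background exactly 0). The default palette cycles
sphere/ellipsoid/dumbbell across shrinking size tiers so classes of the
same kind at adjacent sizes are confusable — the large/medium/small
difficulty structure of public subtomogram benchmarks — and any base/novel
split leaves each novel class a structurally similar base class, the regime
calibration presumes. Each sample is rotated by a uniformly random 3D
rotation (trilinear interpolation, zero fill; mass loss bounded at 5%),
optionally filtered by a missing wedge (Fourier coefficients beyond the
tilt half-angle from the in-plane axis zeroed; 90° = off, the default,
since real inputs already contain their wedge), and corrupted by additive
zero-mean Gaussian noise with variance var(signal)/SNR, the variance-ratio
SNR convention of public tomography contests. The drawn noise field is
standardized to the exact target variance, so measured SNR matches the knob
to floating precision. The reference datasets quote SNR = 0.02; that value
is available but the package's test default is 0.5, since 0.02 needs far
more training than a CPU test suite should spend.

**Feature benchmark.** Per-class multivariate Gaussians with known ground
truth: base means drawn isotropically (scale 1.0), per-class covariances
0.5·(0.8 I + 0.2 d uuᵀ) (isotropic floor plus one random correlated
direction), and — by default — each novel mean the average of two distinct
base means with the averaged covariance, making the "similar classes have
similar distributions" premise literally true and ground truth available
for recovery tests. All means are shifted by a common vector to sit ≥ 6
within-class standard deviations above zero so features are nonnegative
without materially truncating the Gaussians (stray negatives are clipped;
at 6σ this is ~never active). Defaults: 8 base / 5 novel classes, d = 16,
100 samples per class — moderate overlap, a 1-shot linear probe lands near
54%, leaving calibration room to act in either direction.

What these generators do **not** emulate: tilt-series projection and
reconstruction physics (CTF, alignment error), structural heterogeneity
within a class, non-Gaussian and correlated noise, crowding/neighbor
density, or localization error. Passing tests therefore demonstrate the
correctness and internal behavior of the method, not its accuracy on real
tomograms.

## Problem sizes used by the shipped evaluations

The reduced end-to-end evaluation simulates 7 classes (4 base / 3 novel) of
60 samples at 16³ and SNR 0.5, pre-trains the width-16 extractor for 20
epochs (batch 32, lr 1e-3, λ = 0.05), and evaluates 3-way 1- and 5-shot
over 30 episodes with Q = 15. The feature-benchmark evaluation uses the
default benchmark with 100 episodes of 5-way-1-shot.

## Known limitations

- Calibration helps when some base classes statistically resemble each
  novel class. On the reduced simulated run — only four base classes of
  geometric phantoms, highly separable features — the μ′ pull toward base
  means is mostly bias, and the calibrated classifier trails the converged
  linear-probe baseline by several points even though it beats chance by a
  wide margin and improves from 1-shot to 5-shot. On the feature benchmark,
  where the premise holds by construction, calibration adds ~9 accuracy
  points over the no-calibration ablation. Users should expect the benefit
  to track how well their base classes cover the novel classes' feature
  neighborhood.
- The NumPy training loop is single-threaded-CPU class: suitable for the
  reduced problem sizes above and for correctness work, not for training
  width-64 models on tens of thousands of 32³ volumes.
- Eq-form fidelity: the calibrated covariance is the plain average of the
  selected base covariances (no additive dispersion constant), and the
  sampled-feature budget is per support example, with the classifier
  retrained on the union.
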