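# Methods

This note documents the models and procedures the package implements, the
defaults it ships, and the choices made where the design was genuinely
open.

## Problem setting

The package classifies histopathological breast-tissue images as benign or
malignant. The pipeline has four stages: (1) impulse-noise removal by
median filtering followed by contrast enhancement, (2) fire-module
convolutional feature extraction, (3) a population-based metaheuristic
that tunes the extractor's training hyperparameters against a validation
error rate, and (4) a deep-belief-network (DBN) classifier trained with
the Adamax update rule. Evaluation uses stratified 80:20 and 70:30
train/test splits with per-class and averaged accuracy, sensitivity,
specificity, F-score and Matthews correlation coefficient (MCC).

## Preprocessing

The median filter uses a square window (default 3, odd, at most the image
side) with mirror-style reflect padding (the edge pixel is not
duplicated), so output shape equals input shape and each output pixel is a
value present in its window. RGB images are filtered per channel.

Contrast enhancement defaults to CLAHE (clip limit 0.01, 8x8 tile grid),
the standard choice for histology; plain histogram equalization is
selectable. Integer equalization maps a gray level with empirical CDF c to
`round_half_up(256·c) − 1`, the classic scaled-CDF lookup (a uniform
four-level image lands on 63/127/191/255). Constant images are returned
unchanged and the declared intensity range is never widened. An optional
ITU-R 601 luma conversion collapses RGB to grayscale before feature
extraction.

## Fire-module feature extractor

A *fire module* is a 1x1 "squeeze" convolution (ReLU) feeding two parallel
"expand" convolutions — 1x1 and 3x3, same padding — whose outputs are
channel-concatenated and passed through ReLU. The squeeze width must be
strictly smaller than the combined expand width; substituting 1x1 kernels
for 3x3 cuts the per-kernel weight count by exactly nine.

The default topology is desk scale: 32x32 grayscale input, an 8-channel
3x3 stem, fire modules (4,8,8), (8,16,16), (8,16,16) with 2x2 max pooling
after the first two, and global average pooling to a 32-dimensional
feature vector. The full SqueezeNet-v1.1 fire stack is available through
`ExtractorConfig.squeezenet_v11()`.

The network is implemented directly in numpy: stride-1 convolutions are
computed as sums of shifted tensor contractions over kernel offsets, and
the backward pass is hand-written and verified against central-difference
numerical gradients in the test suite (relative error below 1e-5 away
from the ReLU kink). Weights are He-uniform initialized from an explicit
seed. Training attaches a temporary softmax head and optimizes everything
with Adamax; the head is discarded (or returned for validation scoring)
after training. Default 5 epochs per fitness evaluation during tuning.

## Metaheuristic hyperparameter search

Candidates are objects immersed in a fluid, each carrying a position
x, density D, volume V (both in (0,1)) and acceleration A. Per iteration
t = 1..tmax:

- densities and volumes drift toward the best object by an independent
  uniform(0,1) fraction per component, so they remain in (0,1);
- the transfer operator `TF = exp((t − tmax)/tmax)` (strictly increasing,
  exactly 1 at t = tmax) gates the regime: TF ≤ 0.5 draws the
  acceleration source from a random population member (collision /
  exploration), TF > 0.5 from the best object (exploitation), via
  `A = (D_src + V_src·A_src)/(D_i·V_i)` with the denominator guarded at
  1e-12;
- accelerations are normalized per dimension across the population by
  `u·(A − min)/(max − min) + l` with l = 0.1, u = 0.9 (minimum maps to
  0.1, maximum to 1.0; an all-equal dimension maps to the midpoint 0.55);
- positions move by `x += c1·rand·Ā·d·(x_rand − x)` (exploration) or
  `x = x_best + F·c2·rand·Ā·d·T·(x_best − x)` (exploitation), where
  `d = exp((tmax − t)/tmax) − t/tmax` decays from e to 0,
  `T = clip(c3·TF, 0.3·c3, 1)`, and the direction flag F is +1 when
  `P = 2·rand − c4 ≤ 0.5`, else −1; positions are clamped to the box.

Constants: c1 = 2 and c2 = 6 (fixed by the method), c3 = 2 and c4 = 0.5
(taken from the source algorithm the method builds on; both exposed in the
config). Uniform draws are per-component for vector updates and scalar for
the flag draw. Iterations are evaluated before moving, so the recorded
best-fitness trace is non-increasing by construction. On the 2-D sphere
(population 20, 100 iterations) the 20-seed median final fitness is below
1e-12, comfortably beating an equal-budget uniform random search.

The hyperparameter tuner wraps the optimizer with a decodable search
space: linear reals, log10-scale reals, round-half-up integers and
floor-binned categoricals. The default space covers the extractor's
learning rate (10^-3..10^-1, log), epochs per evaluation (2..8) and batch
size ({8,16,32}). The fitness of a candidate is the percent error rate —
100 · misclassified/total — of the briefly trained extractor-plus-head on
a fixed, seeded inner 80/20 validation split, so the objective is
deterministic per position.

## DBN classifier

An RBM has energy `E(v,h) = −aᵀv − bᵀh − vᵀWh`; conditionals factorize
through sigmoids. CD-k updates use sampled Gibbs alternations with final
statistics on probabilities; the test suite checks the mean CD-1 update
direction against the exact enumerated log-likelihood gradient on 2x2
RBMs, and the two-layer greedy variational bound against the exact DBN
log-likelihood on enumerable models.

Real-valued feature vectors are min-max scaled to [0,1] (statistics
learned from the training partition) and treated as Bernoulli
probabilities by the first layer. Default layer sizes
[feature_dim, 64, 32] with a 2-way softmax head.

Greedy pretraining trains layer k by CD on the hidden-probability
transform of layer k−1. Up-down (wake-sleep) fine-tuning then runs, per
minibatch: a wake pass (recognition samples upward; untied generative
weights fitted by the delta rule to reconstruct each layer), a CD refresh
of the top RBM with the one-hot labels concatenated to its visible layer,
a sleep pass (generative samples downward; recognition weights fitted to
invert them), and a discriminative pass in which the softmax head — with
dropout 0.5 on its input — and the recognition weights receive the
cross-entropy gradient through an Adamax step. Generative updates run at
one tenth of the supervised learning rate so they regularize rather than
override the discriminative signal; with equal rates the per-batch
generative refresh of the top RBM can stall supervised training
completely. Initial weights are Gaussian with scale 0.1 — small enough
for stable CD, large enough that top-layer activations retain variance
for the head.

Reference training defaults: learning rate 0.01, dropout 0.5, batch
size 5; the desk-scale pipeline uses 10 pretraining and 30 fine-tuning
epochs, and `full_scale=True` raises both to 50.

## Adamax

Per step: `m ← β1·m + (1−β1)·g`, `u ← max(β2·u, |g|)`,
`w ← w − η·(m/(1−β1^t))/(u + ε)` with η = 0.01, β1 = 0.9, β2 = 0.999,
ε = 1e-8. Only the first moment is bias-corrected — the max recursion
makes the infinity-norm moment unbiased by construction. The absolute
value in the u-update is required for u to be a norm estimate. The first
step from a zero state moves by `−η·|g|/(|g|+ε) · sign(g)` and the
constant-gradient steady step approaches `−η·sign(g)`.

## Evaluation protocol

Stratified splits: the per-class test count is floor(test_fraction ·
n_class), the remainder trains; indices are seeded, disjoint and
exhaustive. Reports are in percent, MCC scaled by 100, rounded half-up to
two decimals. In a binary problem each class's sensitivity equals the
other's specificity, accuracy and MCC are shared between class rows, and
the average row is the arithmetic mean of the class rows — these
symmetries are asserted on every generated report. A degenerate
denominator (empty truth row or predicted column) reports 0 and sets a
flag rather than raising. Note that exact half-cases at the second
decimal depend on the rounding convention; this package always rounds
half up.

## Synthetic data generator

The generator emulates the structure of a BreakHis-style two-magnification
benchmark: 644/1437 benign/malignant images at 100x and 623/1390 at 200x
(about 1:2.2 imbalance), scalable by a factor in (0,1]. Each image is a
correlated background texture (Gaussian-filtered noise, correlation length
4 px, background level 170) with Poisson-many dark elliptical nuclei
(class-specific density, radius and intensity distributions), then
contrast-compressed toward mid-gray (factor 0.55) and corrupted with
salt-and-pepper noise (rate 0.02) — so the median filter and contrast
enhancement have real work to do. Two presets: *easy* (nucleus densities
6 vs 18 per 64x64 tile) for end-to-end checks, *hard* (9 vs 13) for
robustness tests. A trivial pixel-mean threshold already exceeds 70%
accuracy on the easy preset, so a ≥90% end-to-end target is attainable
but not vacuous.

What the generator does **not** model: H&E stain color and its variation,
tissue architecture (glands, stroma, ducts), slide artifacts, scanner
differences, or inter-patient heterogeneity. Passing end-to-end tests on
this data demonstrates that the pipeline's stages compose correctly and
can learn a texture-density signal — not that the method reaches any
particular accuracy on real histopathology.

## Pipeline

A single root seed feeds named substreams (data, split, tune, extractor,
dbn) via `SeedSequence`, so runs are exactly reproducible and changing one
consumer does not perturb the others. The extractor is tuned once on the
first split's training partition and reused across split ratios — at desk
scale the tuning budget (population 10 x 10 iterations, 5-epoch
evaluations) dominates the run time and per-ratio retuning would roughly
double it for little benefit. The DBN is retrained per split ratio.
Desk-scale problem size: the 100x benchmark layout at scale 0.1 (208
images of 64x64, resized to 32x32 after preprocessing).

One phrase in the method's description is ambiguous: an "Adamax
hyperparameter optimizer" for the classifier. Adamax is a weight
optimizer, not a hyperparameter search; it is implemented here as the
DBN's training rule, while the population metaheuristic is the
hyperparameter search for the extractor. An optional extension of the
search space to DBN layer sizes is possible through the same
`SearchDimension` mechanism.

## Known limitations

- The extractor trains from scratch at desk scale; no pretrained weights.
- Bernoulli RBMs only; real inputs enter as min-max probabilities rather
  than through Gaussian visible units.
- Wake-sleep here is the classic heuristic, not a variational-EM
  procedure; its generative quality is not evaluated, only its effect on
  classification.
- The tuner's fitness uses a briefly trained extractor, so the selected
  hyperparameters are those that help *early* training — a deliberate
  budget choice at desk scale.
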