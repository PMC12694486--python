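# Methods

This note records the models and procedures `fedfer` implements, the
parameters that matter, the choices made where a design was genuinely open,
and what the bundled synthetic task does and does not demonstrate.

## The CNN family

An architecture is a tuple of filter-block widths (length 3 or 4) plus a fixed
head. Each filter block is a 3×3 convolution (stride 1, **valid** padding,
bias), ReLU, then 2×2 max-pooling (stride 2, **floor** on odd extents). After
the blocks: flatten, dense 256 + ReLU, dense 128 + ReLU, dropout 0.2, dense 4
+ softmax over {neutral=0, happy=1, sad=2, angry=3}.

Two conventions here — valid padding and floor pooling — are not free: they
are pinned by the published complexity figures of the (64, 128, 256) model.
With them the 48×48 input traces 46→23→21→10→8→4, the flatten length is
4·4·256 = 4096, and the parameter count is exactly 1,451,908 (1.45 M); same
padding would give >2.3 M. FLOPs are counted as 2 per multiply–accumulate in
conv and dense layers only (conv MACs = out_h·out_w·c_out·9·c_in, dense MACs
= in·out); bias additions, pooling, activations and softmax are excluded,
which reproduces 107.4 MFLOPs. Serialized size is parameters × 4 bytes
(float32) in binary megabytes: 5.54 MB.

Unstated training details are fixed as: Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) at
the protocol learning rate 0.001; categorical cross-entropy (forced by the
softmax output); He-uniform initialization for conv/dense kernels with zero
biases, drawn from a single seeded Generator; one dropout layer after the
128-unit dense layer; no data augmentation. All tensors are float32.

## Federated simulation

Clients are in-process. `partition_clients` deals each class's (seeded,
shuffled) samples round-robin to the clients, so shards are equal to within
one sample per class, every shard contains all four classes, and earlier
clients receive remainders — the equal-and-stratified setting of the
reference protocol. Shards stay fixed across rounds.

Each round: broadcast the global weight set, train every client locally for
`local_epochs` (default 15) with batch 64 and lr 0.001, then aggregate with
the sample-count-weighted element-wise mean (accumulated in float64, cast
back to float32). Optimizer state is reset at the start of every local
training — the "broadcast global weights" reading of FedAvg. The default is a
fixed 20 rounds; an optional plateau rule (no accuracy gain > 0.001 over 3
rounds) exists but is off by default.

Determinism: the only randomness is NumPy's `default_rng` seeded from the run
seed; per-round, per-client batch order and dropout masks derive from
`round_seed(seed, round, client) = (seed·1000003 + round·10007 + client) mod
2³¹`. Because centralized training uses the same loop with
`round_seed(seed, 0, 0)`, a single-client, single-round federated run is
**bitwise identical** to centralized training — the degenerate-FedAvg check.
Determinism is per-machine: a different BLAS/CPU may round differently, which
is irrelevant to any identity asserted here (all are within one process).

## Grad-CAM++ and the combined overlay

The class score Y_c is the **pre-softmax logit**. First-order gradients
∂Y_c/∂A^k with respect to a block's post-ReLU (pre-pool) feature maps are
exact reverse-mode derivatives. For the α coefficients,

α_ij^k = g2 / (2·g2 + (Σ_ab A^k_ab)·g3),  zero where the denominator is 0,

the second/third partials g2, g3 are taken as the elementwise square and cube
of the first-order gradient — the standard closed-form treatment when the
feature map feeds linear+ReLU paths. Channel weights are w_k = Σ_ij α_ij^k ·
relu(∂Y_c/∂A^k_ij) and the raw map is relu(Σ_k w_k A^k). A loop-based
(non-vectorized) evaluation of the same formulas serves as the test oracle,
and central finite differences through `forward_from_block` validate the
first-order gradients.

Normalization is min–max with an 1e-8 guard (a constant map collapses to all
zeros), followed by bilinear upsampling to 48×48 and a second min–max so that
any non-constant map attains max 1 despite interpolation.

The channel-attention profile is computed **post hoc without trained
parameters**: per-channel score = global-average-pooled + global-max-pooled
activation, softmaxed over channels. The trained models contain no attention
blocks, so this parameter-free form is the minimal faithful reading of
"combined with a channel-attention map"; a shared-MLP variant could be
plugged in behind the same `AttentionProfile` interface. The final overlay is
the elementwise product of the normalized Grad-CAM++ map and the normalized
attention spatial map (Σ_k w_k·relu(A^k)), re-normalized to [0, 1] — product
being the natural suppression operator. One guard: a spatially *constant*
attention map carries no information and is treated as all-ones rather than
being normalized to zeros, so it leaves the Grad-CAM++ map unchanged instead
of annihilating it. The default explanation layer is the last filter block.

## Perturbation metrics

All metrics operate on saliency maps normalized to [0, 1] at input
resolution.

- **Binarization**: salient iff value ≥ θ, with θ = 0.5 (midpoint of the
  normalized range; configurable). Ties count as salient.
- **Active pixel ratio**: |mask| / 2304.
- **Deletion curve (DAUC)**: at fraction f, the top ⌊f·2304⌋ pixels by
  saliency (ties broken row-major) are set to 0 in the original image; the
  curve is the target-class probability over f ∈ {0, 1/n, …, 1} (n = 100 by
  default) and the AUC is trapezoidal. Endpoints are exact by construction:
  f=0 gives the original confidence, f=1 the all-zero-image confidence.
- **Insertion curve (IAUC)**: the same ranking progressively restores
  original pixels onto a Gaussian-blurred copy (σ = 5 px).
- **AD** = mean over samples of max(0, (p − o)/p) where o is the confidence
  after occluding the salient region (fill 0); samples with p = 0 are
  excluded with a warning. Higher is better under this polarity: the removed
  regions mattered.
- **IC** = fraction of samples whose confidence with only the salient region
  retained (background fill 0) *strictly* exceeds the full-image confidence.
- **ADA / accuracy-after-masking** = accuracy before minus after occluding
  the salient region, and the after value itself. On the evaluation subset
  (below) original accuracy is 1, so the two sum to exactly 1 — the
  consistency every published per-emotion pair exhibits.
- **Evaluation subset**: samples correctly classified by *all* models under
  comparison, so metric differences reflect explanation quality, not raw
  accuracy. Macro rows are unweighted means over the four emotions.

The fills (black occlusion and retention background), θ, step count and blur
σ are all configurable; the defaults above are declared conventions, not
values inferred from any published number.

## Multi-seed statistics and model selection

Precision/recall/F1 use support-weighted averaging, under which weighted
recall equals accuracy identically — the averaging scheme consistent with the
published per-dataset tables where the recall row equals the accuracy row.
Multi-seed summaries use the sample standard deviation (n−1) and Student-t
95% intervals, mean ± t₀.₉₇₅,ₙ₋₁·s/√n; this pair of conventions exactly
reproduces the published 10-seed CI endpoints recomputed from their printed
mean/std (one evaluation set reproduces at 2-decimal rounding; the others to
within ±0.01, the rounding step of their printed inputs). The default seed
list is {1, 3, 7, 17, 21, 33, 42, 55, 77, 100}.

The model-selection report ranks candidates lexicographically: mean accuracy
across test sets first, ties broken by a declared explanation composite
IAUC + IC + ADA − DAUC − active pixels (macro). The reference narrative
selects "on both performance and explanations" without a formula; the
composite is documented in the report output and configurable.

## The synthetic task

The generator emulates, at desk scale, a four-emotion image task whose
discriminative evidence is *known pixel-exactly*. Every 48×48 sample has a
face-oval outline and two eyes; class identity lives only in the mouth
curvature (up = happy, down = sad, flat = neutral/angry) and brow slant
(inward-down = angry). Angry and neutral share a flat mouth deliberately, so
the task is not separable from any single part and the neutral class is
"diffuse". The ground-truth mask is the dilated union of the mouth and brow
strokes (~4–5% of pixels). Per-sample nuisance variation: independent ±2 px
integer jitter of each part, ±5° whole-image rotation, ×[0.8, 1.2] contrast,
additive Gaussian noise σ = 0.05, clipped to [0, 1].

The face interior is deliberately black: the discriminative strokes are
bright marks on a zero background, so occluding them with the metric suite's
black fill genuinely erases the signal. (A filled-gray face would leave a
dark silhouette of the same shape under black-fill occlusion — an
occlusion-fill artifact that would make "deleting" the ground truth not
delete the evidence.)

What passing on this task shows: the training loop learns, FedAvg converges,
explanations localize to the true evidence, and informed saliency dominates
random saliency on insertion/deletion. What it does not show: performance or
explanation quality on real faces — no pose, identity, illumination or label
noise is modeled, and the classes are linearly much easier than real
expressions.

Default scale: 500 samples per class (2,000 images), 80/20 stratified split.
Trained-model experiments in the test suite and the acceptance script use the
(16, 32, 64) family member (8 centralized epochs, or 3–5 federated rounds),
which reaches ≥95% held-out accuracy in well under a minute per run; the
flagship (64, 128, 256) is exercised analytically and at the inference level.
The client-scaling sweep runs at batch 16 with 8 rounds × 5 local epochs on
800 samples: a 15-client shard holds ~53 samples, less than one batch at the
protocol's 64, so the smaller batch keeps several optimizer steps per local
epoch and lets every client count converge before comparison.

## Known limitations

- No non-IID partitioner: heterogeneity beyond per-sample jitter is out of
  scope, as are secure aggregation, differential privacy and real transport.
- The closed-form g², g³ treatment of higher-order terms is an approximation
  outside strictly linear+ReLU paths from the explained layer (max-pool
  switches make the score only piecewise linear in the activations); the
  loop oracle bounds the formula's evaluation, not this modeling choice.
- Checkpoints are NumPy `.npz` archives (config echo + ordered named arrays);
  they round-trip bitwise but are not interchange formats.
- The FER2013/image-folder readers assume pre-cropped faces; no detection or
  alignment is performed.
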