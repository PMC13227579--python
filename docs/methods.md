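# Methods

## Problem and model

`fi2ffa` translates color fundus images (FI) into fundus fluorescein
angiography (FFA) appearance and back. FI is cheap and non-invasive; FFA
requires injecting fluorescein dye, which some patients cannot tolerate, so
a faithful FI→FFA translation is clinically interesting. The hard part of
the translation is *structural* fidelity: the retinal vasculature of the
input must survive the style change, neither dropped nor hallucinated.

The model is a cycle-consistent GAN with two additions:

1. **Structure self-supervision (SSM).** A classical, fully deterministic
   extraction pipeline (below) turns any FI or FFA image into a binary
   vessel-structure raster. These rasters are free labels: each generator
   carries an auxiliary decoder that must reproduce the structure of its
   *input* image, trained with an L1 loss against the extracted label and
   judged by a dedicated structure discriminator. Because the labels come
   from the input itself, no manual annotation is needed.
2. **Cycle learning (CL) with norm-only intermediates.** Each direction is
   closed into a cycle (FI → fake FFA → reconstructed FI and vice versa).
   The cycle reconstruction and its predicted structure receive only L1
   (first-order norm) penalties against the source image and its extracted
   structure — no adversarial term is applied to cycle intermediates.

Training data are *pseudo-paired*: FI/FFA images of the same eye that are
similar but not pixel-aligned (acquisitions minutes apart; the eye moves).
The λ-weighted paired L1 generation loss is therefore a soft anchor, and
the adversarial + structure terms carry the fine detail.

### Networks

The generator is U-shaped: an encoder of 3×3 convolution blocks
(instance norm, leaky ReLU 0.2) each followed by 2×2 max-pooling, and a
primary decoder of 2×2 stride-2 transposed convolutions with encoder skip
connections, ending in a tanh image head (range [−1, 1]; images are mapped
to that range for the networks and back to [0, 1] for I/O). The auxiliary
structure decoder mirrors the primary decoder; at each resolution it
concatenates its own upsampled features with the primary decoder's features
at that resolution and ends in a sigmoid head (range [0, 1], matching its
binary L1 target). Information flows one way: the image output has exactly
zero gradient with respect to auxiliary-branch parameters (verified by an
autodiff test), while structure-loss gradients do flow back through the
primary decoder and encoder — that back-pressure on the shared trunk is the
point of the auxiliary task.

Discriminators are PatchGAN critics: 4×4 convolutions, stride 2 except the
last two layers (stride 1), instance norm, leaky ReLU 0.2, and a raw
1-channel patch-score map (no sigmoid; the least-squares objective operates
on raw scores). Four critics run during training: fake-vs-real FI, FFA, FI
structure and FFA structure (the structure critics take 1-channel input).
One caveat documented in `DiscriminatorConfig`: instance-norm statistics
couple every pixel, so the classical receptive-field recursion describes the
convolutional path only; the footprint test runs with `use_norm=False`.

The layer counts of the original full-scale model are not reconstructible
from its reported parameter total, so the defaults are depth 7 with 64 base
channels (capped at 512), and a `tiny()` preset (depth 3, 16 channels) is
used for all CPU experiments here.

### Objective

With x an FI image, y its pseudo-paired FFA, and s(·) the classical
extractor:

* structure: `L1(x'_s, s(x))` and `L1(y'_s, s(y))`, weight λ_struct = 1;
* generation: `λ1·L1(x', x)` and `λ2·L1(y', y)`, λ1 = λ2 = 10;
* adversarial (least-squares GAN, real = 1, fake = 0, generator target 1;
  discriminator side carries the conventional ½ factor), one term per
  critic;
* cycle: `λ_cyc·L1(x'', x)` and `λ_cyc·L1(x''_s, s(x))` (and symmetrically
  for y), λ_cyc = 10, no adversarial term.

λ_struct and λ_cyc are not pinned by the method description; 1 and 10 are
the package defaults (the cycle weight mirrors λ1) and both are exposed in
`LossConfig`. The least-squares coding (0/1/1) is likewise configurable.

The backward generator's input during the cycle is configurable
(`cycle_input_mode`): `image` (default — the fake image, keeping inference
a one-image operation), `structure` (the predicted structure replicated to
three channels), or `image_plus_structure` (4-channel concatenation; the
generators are then built with 4 input channels and inference extracts the
structure channel with the classical pipeline).

### Training procedure

Per batch: critics are updated first on detached fakes, then both
generators on the combined objective. One RMSProp optimizer per network
(six total), lr 2e-4, batch size 3, α = 0.99, ε = 1e-8. The learning rate
is constant for the first 150 of 200 epochs and then decays linearly to
exactly zero (the tiny preset scales this to 20 of 30). Augmentation:
resize to the load size, one shared random crop to the crop size and an
optional shared horizontal flip applied identically to FI, FFA and both
structure labels (labels are resampled nearest-neighbor and stay binary);
vertical flips are off because fundus orientation is anatomically
meaningful. Structure labels are extracted once from the full-size images
and augmented alongside them — re-extracting per crop would move the Otsu
threshold with every crop and make the label a moving target. All
randomness (init, ordering, crops, flips) derives from the config seed.
Ablation switches: `use_ssm=False` drops the auxiliary outputs, structure
losses and structure critics; `use_cl=False` drops the cycle pass.

## Classical structure extraction

Shared pipeline (FFA differs only by an initial intensity inversion so both
modalities present dark vessels): green channel → field-of-view mask →
5×5 Gaussian smoothing (σ = 1.1) → global histogram equalization followed
by CLAHE on a 10×10 tile grid → homomorphic filtering (log-domain Gaussian
high-emphasis, γ_high = 1.5, γ_low = 0.5, cutoff 30 frequency pixels) →
gamma correction (γ = 1.5) → oriented line detector (length 10, width 1,
12 orientations at 15° steps; response = line-window mean minus
surrounding-square mean on the negated image, max-pooled over orientation)
→ zero outside the mask → min-max stretch → Otsu threshold over a 256-bin
histogram of masked pixels only (background pixels would bias the split).

Choices where the procedure was under-determined: the Gaussian smooths the
image (not the mask); the two equalizations run sequentially; the FFA
inversion sits immediately after green-channel extraction; grayscale
stretching is plain min-max; homomorphic parameters are standard
illumination-equalization values, all exposed in `ExtractionParams`. The
FOV detector assumes a dark border (bright pixels → largest connected
component → hole fill → 3-step erosion with border value 1); callers
working with pre-inverted images pass a precomputed mask. Degenerate inputs
(constant image, empty mask) yield an all-zero structure with a warning,
never an exception.

## Synthetic phantom generator

Clinical FI/FFA pairs are private; the generator provides pseudo-paired
data with exact ground truth. A vessel tree grows from the optic disc by
recursive binary branching (each segment below the depth limit splits in
two with probability `branch_prob`, else continues with heading jitter;
child width = parent width × U[0.6, 0.9]; endpoints clamped inside the
field). The same geometry is rendered twice: FI as a warm-toned background
with radial illumination falloff, dark vessels (strongest contrast in
green), bright disc, darker fovea; FFA as a dark background with bright
vessels, optional diffuse hyperfluorescent leakage blobs, replicated to
three channels. Both get additive Gaussian noise (σ = 0.02 by default) and
are exactly zero outside the circular field. The FFA render is displaced by
a random rigid transform with translation bounded by `max_misalign_px`
(default 3 px at 256; rotation bounded by 0.25°/px of that budget),
emulating the displacement of real pseudo-pairs. Ground-truth masks come
from the geometry alone and never depend on rendering noise.

Appearance parameters were calibrated once so that the classical extractor
succeeds on clean renders (mean Dice ≈ 0.7 against ground truth at 256²)
— the generator has no quantitative clinical reference to match. What the
phantoms do **not** model: choroidal texture, pathology other than generic
leakage blobs, temporal FFA phases, non-rigid eye motion, acquisition
artifacts. Passing tests therefore demonstrate that the machinery works and
that the structural supervision behaves as designed, not clinical-grade
translation quality.

## Evaluation

FID is the Fréchet distance between Gaussian fits of feature embeddings;
the product square root is computed by eigendecomposition of the
symmetrized product `C1^{1/2} C2 C1^{1/2}` with negative round-off
eigenvalues clipped and the result floored at zero. KID is the unbiased
squared MMD with kernel `(a·b/D + 1)^3`, reported as a single estimate over
the full sets (a subset-averaged protocol was considered and rejected as
the default because no protocol is pinned; the single unbiased estimate is
the simplest reproducible choice). Both are embedding-agnostic; the
built-in `toyconv` embedding (three fixed-seed random conv layers, ReLU,
mean+std global pooling, D = 128, inputs resized to 64²) runs fully
offline. The conventional Inception embedding needs downloaded weights and
is registered only as an informative stub. Structure preservation is the
Dice overlap between the classical extractions of an input and of its
translation.

## Benchmark problem sizes

All shipped experiments run on one CPU with the tiny preset:

* end-to-end check: 20 pseudo-pairs rendered at 72² (load 72, crop 64),
  30 epochs, seeds 0–2; asserts the final-epoch FFA generation L1 is below
  half its first-epoch value and that trained structure preservation beats
  an untrained generator, each in ≥ 2 of 3 seeds;
* ablation check: 8 pairs rendered at 56² (crop 48), 12 epochs, 5 seeds;
  asserts the structure-preservation ordering full ≥ without-CL ≥
  without-SSM-and-CL in ≥ 3 of 5 seeds.

These sizes are the package's reproducibility benchmark, not a claim about
full-scale behavior; both checks are stochastic by nature, hence the
majority-of-seeds form.

## Numerical notes and limitations

The tensor engine is float32 with reverse-mode autodiff over an explicit
tape; convolutions are im2col + BLAS with the non-overlapping 2×2/stride-2
case reduced to a reshape. Gradients of every primitive are tested against
central finite differences. Otsu ties break toward the lowest threshold
bin. Dice of two empty masks is defined as 1. KID may be slightly negative
(unbiased estimator). Checkpoints are `.npz` archives holding all six
state dicts, optimizer state, config and data-RNG state; the loader rejects
architecture mismatches. Known limitations: no GPU path, no image-history
buffer for critic updates, no registration step (rigid registration of real
pairs is a user-side preprocessing concern), and the full-scale
depth-7/200-epoch configuration is untested at scale in this repository.

One further dtype rule: loss functions preserve float64 when handed plain
double-precision arrays (so their analytic identities hold to machine
precision), while scalar weights and all network tensors stay float32.
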