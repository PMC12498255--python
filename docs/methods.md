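# Methods

## The problem and the model

Intravascular OCT (IVOCT) pullbacks image coronary cross-sections at a
constant axial speed, so neighbouring frames show nearly the same anatomy.
Lumen segmentation from single frames fails exactly where it matters
clinically: residual blood scatters the beam and erases parts of the lumen
boundary in individual frames, while the neighbouring frames are often
clean.  TR-Unet exploits this temporal redundancy.  Its input quantum is a
*sequence unit*: the T−1 frames preceding the segmentation target x_t plus
x_t itself, logically a (C, H, W, T) tensor with x_t last.

Three components process a unit:

1. **Spatial branch** — a residual U-Net over x_t only.  The encoder is the
   50-layer bottleneck topology (stem: 7×7 stride-2 conv + BN + ReLU + 3×3
   stride-2 max pool; stages of 3, 4, 6, 3 bottleneck blocks
   `y = ReLU(F(x) + shortcut)`, inter-stage downsampling carried by the
   stride-2 3×3 convolution inside the first block of each stage).  The
   feature pyramid is taken after the stem convolution (/2) and each stage
   (/4 … /32).  The decoder runs four symmetric modules {k=2, s=2
   transposed conv → concatenate skip → 3×3 conv + ReLU} and a final D0
   module (transposed conv + 3×3 conv) producing one logit channel at the
   input resolution.
2. **Temporal branch** — every slice passes an E0-like stem (7×7 stride-4
   conv + BN + ReLU) and is average-pooled to a fixed coarse grid (8×8 at
   the 512-px reference size); a two-layer ConvLSTM stack consumes the
   slices oldest→newest from zero-initialised memory.  The ConvLSTM cell is
   the peephole formulation: convolutional input-to-state and
   state-to-state transitions, per-channel Hadamard peepholes, and an
   output gate that reads the *new* cell state.  The final hidden state
   passes a small convolutional head and per-scale 1×1 channel-matching
   convolutions, and is resized (nearest-neighbour) to each skip
   resolution.
3. **Coordinate-attention fusion** — at each of the four skip levels the
   spatial and temporal features are concatenated, passed through a 1×1
   convolution, refinement 3×3 convolutions (concentrated at the /2 and /4
   levels), a 1×1 convolution back to the skip width, and a coordinate
   attention block: height- and width-pooled descriptors, a shared 1×1
   transform with ReLU, and sigmoid gates applied as
   Y[c,i,j] = X[c,i,j]·g_h[c,i]·g_w[c,j].

The output weight map is the sigmoid of the decoder logits; post-processing
binarises at 0.5, keeps the largest 4-connected component and fills
interior holes.

### Ablation variants and exact budget additivity

The variant semantics were chosen so the component budgets are exactly
additive, mirroring the published complexity tables:

| variant    | skip path                                            |
|------------|------------------------------------------------------|
| full       | CA(fusion convs(concat(spatial, temporal)))          |
| −CA        | spatial + temporal (parameter-free addition)         |
| −ConvLSTM  | fusion stack kept, temporal input slice fed zeros    |
| ResUnet    | raw spatial skip                                     |

Removing a branch removes exactly its parameters, so
params(full) − params(−ConvLSTM) = params(−CA) − params(ResUnet) holds as
an integer identity (the ConvLSTM budget, 260,618 params), and
symmetrically for the CA/fusion stack (7,490,209 params).

### Width calibration

The reference tables pin only component totals — ResUnet 59.44 M params /
123.59 G MACs, ConvLSTM branch +0.26 M / ≈0.04 G, CA/fusion stack +7.49 M /
≈126.27 G, full model 67.19 M / 249.89 G at 512² input and T=3 — not layer
widths.  The shipped calibration (`tr-unet-512/v1`) was found once by
integer search against those totals using the package's analytic profiler
and is frozen in `trunet/calibration.py`:

* decoder widths 960/560/368/141, D0 width 27;
* temporal stem 6 channels, ConvLSTM hidden 20 (2 layers), head 129/62,
  8×8 grid;
* fusion widths 136/565/163/141 with 2/2/0/0 refinement convs, CA
  reduction 16.

Two consequences of the printed numbers are worth stating.  The tiny MAC
footprint of the ConvLSTM branch (~0.04 G against 0.26 M params) forces it
to operate at a very coarse grid — parameters applied at /64 resolution
cost 64 pixels each, at /4 they would cost 16,384 — hence the pooled 8×8
grid and the parameter-free nearest-neighbour resizing of temporal
features.  Conversely the CA/fusion budget (7.49 M params carrying ~126 G
MACs, ~17 k pixels per parameter) forces the fusion capacity to the /2 and
/4 levels.  The published MAC roundings are also mutually inconsistent at
the last digit (the ConvLSTM MAC delta prints as 0.04 G in one row pair
and 0.03 G in the other); the calibration sits where all four printed
values round correctly simultaneously.

MAC convention: convolutions count Cin·Cout·k² per output position,
transposed convolutions per input position, the ConvLSTM pays its per-step
convolution cost T times; elementwise operations, batch norm, activations
and pooling are free.  Parameter counts include every trainable scalar
(conv/transposed-conv kernels and biases, BN affine terms, ConvLSTM
kernels/peepholes/biases, attention convolutions); BN running statistics
are not trainable.

## Numerical engine

No GPU framework is used: `trunet.nn` is a small reverse-mode autodiff
engine on numpy (conv2d / transposed conv via shift-and-matmul, batch
norm with per-batch statistics in training and running statistics in
eval, max/avg pooling, the elementwise ops).  Gradients of every operator
are verified against central finite differences in the test suite, and
the end-to-end Dice-loss gradient is spot-checked the same way at 64-bit
precision.  Forward passes in eval mode are deterministic; training is
fully reproducible from (config, seed) in this single-threaded setting.

## Training

Soft Dice loss `1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1 (the smoothing
term keeps the loss defined for empty masks; evaluation metrics instead
use the raw formulas with the documented empty-mask convention: 0/0 counts
as perfect only when both masks are empty).  Optimiser: SGD with classical
momentum 0.9 and constant learning rate.  Two profiles ship:

* full-scale (reference recipe): lr 0.1, batch 8, 100 epochs;
* desk-scale: lr 0.01, batch 4 — lr 0.1 routinely diverges at quarter
  widths, and desk runs use few epochs.

Each batch draws one augmentation op per unit (horizontal/vertical flip,
rotations by multiples of 90° — exact, resampling-free) and applies it to
every slice and the mask.  ConvLSTM memory starts at zero for every unit.
Dataset splits are drawn by manifest lists from independently seeded
phantoms.

## The phantom generator

The generator emulates the structure the method exploits, not OCT physics.
A star-shaped lumen contour r(θ) = R + Σ_k a_k·cos(kθ + φ_k) (harmonics
k ≤ 4, Σ|a_k| ≤ 0.3 R so the lumen never collapses onto the catheter)
drifts along the pullback as a bounded Gaussian random walk (`seq_noise`
pixels per frame; 1 px keeps consecutive-mask IoU above 0.95, the temporal
coupling the model needs).  Rendering uses fixed intensity levels
(background 0.05, lumen 0.10, wall 0.80, catheter 0.95) plus a guidewire
shadow sector and multiplicative Gaussian speckle.  Blood artifacts are
Gaussian bumps (σ = 5 % of image size) centred on contour points inside a
contiguous angular window of width `severity`·2π, truncated to that window
so the occluded angular fraction matches `severity` within ±0.05; they
corrupt only the image, never the mask.  Masks follow clinical contouring:
the labeled lumen is the full star region (simply connected, catheter
footprint and shadow included).  Randomness uses a documented splitting
rule (SeedSequence spawned per frame) so phantoms are bit-reproducible.

What the phantom does **not** model: realistic OCT speckle statistics,
polarisation, NURD distortion, stents, eccentric catheters, bifurcations.
Passing the synthetic experiments therefore demonstrates the mechanism
(temporal context restores occluded boundaries) rather than clinical
accuracy.

## The desk-scale robustness replica

The clinical dataset behind the published accuracy numbers is not
available, so artifact robustness is checked as a direction-only synthetic
replica: the full model and a −ConvLSTM twin are trained on identical
phantoms with identical seeds and schedules, and compared on the
artifact-flagged test subset.  Problem sizes were chosen once to keep the
whole run a few minutes on one CPU with the numpy engine: 64-px frames,
quarter widths, T=3, six training and three test pullbacks of 10 frames
(60 training / 30 test units), 10 epochs, test-target blood severity 0.4,
three seeds.  The asserted outcomes are the ones the experiment actually
supports at this scale: the temporal model wins artifact-subset Dice in at
least 2 of 3 seeds, and training loss decreases in every run.  Absolute
Dice values at this scale are far below converged full-scale training and
are not compared to published numbers; at these short schedules the full
model also converges faster than the twin on clean frames, so no
clean-subset equality is asserted beyond a loose same-league bound.

## Numerical choices and edge cases

* Polar→Cartesian resampling: bilinear with angular wrap-around (θ = 0
  along +x, counter-clockwise, polar row 0 at θ = 0); radii beyond the
  last depth column map to 0.  Early targets (t < T−1) replicate the first
  frame so every frame yields a unit.
* Intensities: 8-bit inputs divided by 255, no per-image standardisation.
* BN: eps 1e-5, momentum 0.1, unbiased running variance.
* He initialisation everywhere; no pretrained weights — the artifact is
  self-contained (checkpoints can load external weights via the ordinary
  state-dict mechanism).
* Coordinate attention: shared transform is conv + ReLU (no BN, no
  hard-swish); descriptor concatenation order [z_h, z_w], split at H;
  reduction floor of 8 channels.
* Post-processing ties: the largest component is chosen by pixel count
  (first label wins ties); empty foregrounds return all-zero masks with a
  warning.
* `width_multiplier` scales every channel width (floor 4); the temporal
  grid stays 8×8 down to 32-px inputs (where it becomes the full /4 map).

## Known limitations

The numpy engine is single-threaded and desk-scale only; full-size (512²)
training is out of reach and is not attempted — full-size models are built
only for complexity profiling and shape contracts.  The phantom's
simplicity means segmentation at desk scale is easy in absolute terms; the
experiments here are mechanism demonstrations and calibration checks, not
clinical validation.
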