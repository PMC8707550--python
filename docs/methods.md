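# Methods

`augforge` implements eleven label-preserving augmentation protocols
(App1–App11) for small labeled image collections — the regime typical of
microscopy, bark/texture and other specialist benchmarks where a deep
classifier would otherwise overfit — plus a sum-rule ensemble harness that
trains one classifier per protocol and fuses their per-class scores.

All images are carried internally as float64 arrays in [0, 1] with shape
H×W×C, C ∈ {1, 3}. Every augmenter preserves H, W and C and clips its output
to [0, 1] as its final step; intermediate arithmetic (PCA, DCT, DWT, CQT
reconstructions) is unconstrained. Grayscale images are never silently
promoted to RGB: the three color protocols (App6–App8) refuse 1-channel
input, and the ensemble layer excludes them for grayscale sets.

## Randomness contract

All draws flow through `RandomSource`, a thin wrapper over NumPy's
`Generator` seeded by a `SeedSequence`. Identical seed + identical call
sequence gives bit-identical outputs. Whole-set operations fork one child
stream per image (`spawn`), so per-image results do not depend on processing
order and parallel execution cannot change them.

## The protocols

**App1–App3 (geometric).** A single affine warp about the image center,
composed reflect → scale → rotate → shear → translate. Reflections are
independent fair coin flips per axis; axis scales are Uniform[1, 2]
(upscale-only, so restoring the original frame is a center crop and no empty
borders appear); rotation Uniform[−10, 10]°; translations Uniform[0, 5] px
per axis (applied toward positive axis directions; a random-sign switch is
available as `geo.random_shift_sign`); shears Uniform[0, 30]° per axis.
App1 uses reflection + scaling only (3 outputs); App2 adds rotation,
translation and shear (6 outputs); App3 is App2 without shear (4 outputs).
App2's six outputs are six independent parameter draws, not designed
sub-combinations. Warping uses bilinear interpolation with edge replication,
so outputs never leave the input's value range.

**App4 (PCA jittering, 3 outputs).** A PCA basis is fit per channel on the
vectorized training images (training data only, fit globally over all
classes rather than per class). Components with eigenvalue above
max(1e−10·λ₁, 1e−12) are kept — near-lossless for training images — with
each component's sign normalized so its largest-magnitude entry is positive,
making the basis invariant to training-set order. Each output applies one of
three operators to the projected coefficient vector of every channel:

- *zero*: each element independently set to 0 with probability 0.5;
- *noise*: each element shifted by (u − 0.5)·std(v)/2, u ~ Uniform(0, 1) —
  the amplitude is half the coefficient vector's own spread, so a degenerate
  (constant) vector passes through unchanged;
- *swap*: each element replaced with probability 0.05 by the same-index
  element of one of five same-class peer images (peer chosen uniformly per
  element).

Peers are drawn without replacement when the class has ≥ 5 other members,
with replacement when it has 1–4, and an empty peer pool is an error. This
policy is shared by every peer-based protocol (App5, App8, App10, App11).

**App5 (DCT jittering, 3 outputs).** Same three operators applied to the
flattened orthonormal 2-D type-II DCT of each channel. The (0, 0) DC
coefficient — proportional to the channel mean — is flagged and exempt from
all three operators, exactly (checked before the final clip).

**App6 (3 outputs).** Contrast stretch between bounds a ~ U{0..50},
b ~ U{205..255} on the 8-bit scale (v<a → 0, v>b → 255, linear between);
sharpening; and a per-channel integer color shift drawn from U{−30..30}.
Sharpening is implemented as unsharp masking, out = img + (img − blur(img, σ=1)),
which boosts edges while keeping a class-preserving appearance; the bare
difference img − blur is available behind `photo.sharpen_literal`.

**App7 (7 outputs).** Four HSV jitters with offsets drawn from hue
[0.05, 0.15] (added modulo 1), saturation [−0.4, −0.1] and brightness
[−0.3, −0.1] (added, clipped), and contrast [1.2, 1.4] (value channel scaled
about mid-gray); a Gaussian blur with σ ~ U[1, 6]; unsharp masking with
radius 1 and strength 2; and an App6-style color shift.

**App8 (2 outputs).** One target image is drawn uniformly from the same
class (never the query image itself) and shared by both outputs: per-channel
histogram specification (monotone CDF matching), and Reinhard color transfer
— per-channel mean/spread matching in the decorrelated Ruderman lαβ
log-opponent space, the standard stain-normalization recipe in microscopy.
A zero-spread source channel (spread below 1e−12 in log space, i.e. flat) is
mean-shifted with unit scale. LMS values are floored at 1e−8 before the
logarithm.

**App9 (elastic, 6 outputs).** Per-pixel displacement fields
Δx, Δy ~ Uniform[−1, 1], applied by bilinear sampling with coordinates
clamped to the image rectangle. Three outputs use raw fields with
α ∈ {7000, 1000, 13000}; three use fields low-pass filtered by a circular
averaging kernel (radius 5), a Gaussian kernel (7×7, σ 1.5) or a
Laplacian-of-Gaussian kernel (7×7, σ 0.5; zero-sum), scaled by α = 3000.
α is divided by the pixel count by default (`elastic.alpha_mode =
per_pixel`), giving sub-pixel-to-few-pixel displacements at typical working
resolutions, since a literal 7000-pixel displacement would collapse to
edge-clamped noise; the literal scaling remains available as a config
switch. Kernel convolution uses symmetric padding.

**App10 (wavelet, 3 outputs).** Single-level db1 (Haar) analysis of each
channel with half-point symmetric boundary extension — subband side
⌈n/2⌉, so a 227×227 channel gives four 114×114 matrices — then one of three
perturbations and the inverse transform (cropped to the input size, exact to
1e−10 when unperturbed):

- *zero*: each element of all four subbands zeroed with probability 0.5;
- *additive*: one constant c = std(channel) + Uniform(−0.5, 0.5), added to
  every element of every subband;
- *swap*: each element replaced with probability 0.05 by the matching
  element of one of five same-class peers' matching subbands.

**App11 (constant-Q, 3 outputs).** Each image column is treated as a 1-D
signal and analyzed by a constant-Q filter bank: center frequencies run
geometrically from 2/H cycles/sample to Nyquist at 12 bins per octave,
preceded by a DC band; each (bin, frame) atom is a Hann-windowed complex
exponential whose window length is Q/f (capped at the column length), placed
on uniformly spaced time frames. The atoms stacked row-wise form a linear
analysis operator K; synthesis solves the least-squares problem through
pinv(K), an exact left inverse because the atoms span the signal space
(measured round-trip relative error ~1e−12, far inside the 1e−6 contract).
The number of frequency bins follows from the column length and bins per
octave rather than being hard-coded. The same three perturbations act on the
complex coefficients — zeroing and swapping treat complex values as units;
the additive constant c = std(channel) + Uniform(−0.5, 0.5) is added to the
real parts (a magnitude-domain variant preserving phase sits behind
`spectral.cqt_perturb_domain`) — then the inverse transform's real part is
taken and clipped. Row-wise analysis is available via `spectral.cqt_axis`.

Working resolution is everywhere a property of the input, not a constant:
the subband geometry (e.g. 114 at 227, 12-bin octave ladders) follows from
the image actually supplied.

## Ensemble harness

`build_training_set` concatenates the originals with one method's augmented
copies, so a base of N images becomes N·(1 + images_per_input); labels are
inherited. One classifier is trained per ensemble member; per-class softmax
scores are summed across members (sum rule) and the fused prediction is the
row argmax with ties broken toward the lowest class index. Named
configurations: `ensda_all` (one member per applicable method — the color
methods are dropped for grayscale sets), `ensda_5` (App1–App5), `ensbase` /
`ensbase_5` (eleven / five members all trained on App3, same-method
controls), `noda` (a single unaugmented member).

The default backbone is deliberately small: a one-hidden-layer MLP
(64 units) on images downsampled to 16×16, batch size 30, learning rate
0.001 — sized so a 3-class 64×64 fixture problem trains in seconds on one
CPU. `TrainConfig.backbone` also accepts any callable
`f(train, test, cfg, seed) -> ScoreMatrix`, which is how a full
convolutional backbone plugs in for real experiments; no test requires one.

## Synthetic fixtures

`make_fixtures` generates class-structured sets: class c is an oriented
sinusoid grating with class-specific orientation (πc/n_classes) and spatial
frequency (0.06 + 0.05c cycles/pixel), a class-specific per-channel
amplitude profile for RGB, per-image random phase and Gaussian pixel noise
(σ 0.05). Same-class images therefore share a texture family (making
class-conditional swaps meaningful) while remaining separable by simple
texture features. The generator is a pure function of its arguments.

What the fixtures do *not* emulate: natural-image statistics, inter-class
imbalance, acquisition artifacts, scale variation, or the resolution of real
benchmarks. Passing tests therefore demonstrate the correctness of the
augmentation and fusion machinery — counts, geometry, reconstruction,
perturbation statistics, accounting — not classification performance on
real data, which additionally depends on a full-scale backbone.

## Numerical choices

- One clip to [0, 1] at the end of each protocol; transforms run unclipped.
- PCA eigenvalue cutoff max(1e−10·λ₁, 1e−12); deterministic sign convention.
- DWT boundary: half-point symmetric extension (round trip exact to machine
  precision after cropping).
- CQT synthesis via SVD pseudo-inverse, cached per (column length, bins per
  octave); minimum column length 8.
- Argmax ties toward the lowest class index; member score matrices must
  share sample ids and class order or fusion refuses them.
- Reinhard flat-channel guard at 1e−12 log-space spread; LMS floor 1e−8.
- Disk write quantizes to 8-bit PNG; read/write round trip is bounded by
  1/255 per channel.

## Problem sizes in tests and the reproduction script

Tests and `scripts/acceptance.py` run on fixture sets of 6–1000 images at
16×16 to 64×64, with the training-set size law exercised at the canonical
1000-image size and transform geometry at the canonical 227×227; ensemble
smoke runs use 3 classes × 8 training images. These sizes exercise every
code path in seconds on one CPU while keeping the statistical checks
(binomial rate bands, uniform-law means) well powered.

## Known limitations

- The literal α elastic mode at α ≥ 1000 saturates to edge-clamped noise on
  small images; it exists for completeness, not recommended use.
- The constant-Q pseudo-inverse is exact but dense: O((bins·frames)·H) per
  column length. Fine at desk scale; a frame-theoretic dual window would be
  the optimization path for very tall images.
- The built-in backbone is intentionally weak; reported fixture accuracies
  say nothing about real-benchmark accuracy.
- PCA bases are fit globally on the training set, not per class.
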