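# Methods

This note documents the models, parameter choices, and numerical decisions
behind `sfprobe`, and what the synthetic-data checks do and do not
establish about real data.

## Frequency geometry

All spectral quantities live on the centered 2-D DFT grid of the network
input. Radial frequency is r = √(u² + v²) in cycles per image (cpi) with
(u, v) the signed integer frequency indices; the highest resolvable
frequency is min(H, W)/2 cpi (112 at 224², 32 at the default 64² working
resolution). Internally arrays use the unshifted `numpy.fft` layout so
masks multiply FFT output directly. For non-square images the integer
indices are used as-is, so "cpi" then refers to cycles per axis length —
a documented limitation; all shipped configurations are square.

Octave bands: (0, 3.5), [3.5, 7), [7, 14), [14, 28), [28, 56), [56, 112)
cpi at nyquist 112, scaled proportionally otherwise. The lowest two
octaves are merged because Fourier coefficients are sparse at small radii;
every band above the merge spans exactly one octave, and [28, 56) is the
mid-frequency human channel. Bands are half-open [lo, hi), the lowest open
at 0 so DC is excluded.

## Mask families

* **Human channel**: unit-peak Gaussian in log₂ frequency,
  M(f) ∝ exp(−(log₂f − μ)²/2σ²), μ = 4.5 octaves (peak 2^4.5 ≈ 22.6 cpi),
  σ = 0.4246 octaves. Note the internal tension: the peak at 22.6 cpi sits
  in the [14, 28) octave, *below* the [28, 56) human-channel band. The
  formula is implemented literally and μ is exposed in configuration; the
  package does not silently recenter it.
* **Extreme LSF**: same log-frequency Gaussian centered at the geometric
  mean of 1.75 and 3.5 cpi (μ = log₂√(1.75·3.5) ≈ 1.31), with a hard pass
  (weight 1) for all 0 < f ≤ 2^μ. The bandwidth is not pinned down by the
  condition's definition; the default reuses σ = 0.4246 so the two
  band-placement conditions share their roll-off sharpness (configurable).
* **Blur-derived low-pass** (fixed-σ and mixed-σ): the DFT magnitude of an
  isotropic Gaussian kernel, σ = 1.5 px for the fixed condition; weak
  mixture σ ∈ {1..5} px with probabilities {0.2129, 0.0653, 0.0200,
  0.0062, 0.0019}, strong mixture σ ∈ {1, 2, 4, 8} px each at p = 0.2.
  Residual probability mass leaves the image unmodified; each image
  receives at most one mask per training step. Kernels are truncated at
  radius ⌈4σ⌉, zero-padded to the grid, and circularly centered before the
  DFT (standard discretization; the construction is not otherwise
  constrained). Images are never blurred — the response only decides
  which frequencies keep their phase.
* **Inverse masks**: M_inv = 1 − M, concentrating scrambling *inside* the
  band of interest for necessity checks.

DC policy: the log-frequency formula is undefined at f = 0, so DC weight
is assigned by mask type — 1 for low-pass-style masks (blur-derived,
hard-pass extreme-LSF), 0 for pure band-pass masks. Independently of the
mask, the scrambler always preserves the DC *phase*, so mean luminance
survives augmentation regardless. Unit-peak normalization divides by the
maximum weight over non-DC grid coefficients, making the peak exactly 1 on
the working grid.

Rescaling across resolutions: frequency parameters are stated on the
224-pixel reference geometry. On an N-pixel grid, log-frequency centers
shift by log₂(N/224) and blur kernel widths scale by N/224, preserving
each mask's response as a function of cpi-relative-to-nyquist.

## Soft phase scrambling

Per channel c with spectrum A_c·e^{iφ_c}, the scrambled phase is the
argument of the convex phasor blend
φ′_c = ∠(M·e^{iφ_c} + (1 − M)·e^{iφ_r}) and the image is rebuilt as
F⁻¹(A_c·e^{iφ′_c}): amplitude spectra are preserved exactly (to machine
precision), verified against 1e−6 in tests. One random field φ_r per image
is shared across the three RGB channels to preserve color coherence.

Random phase fields are sampled as the phase spectrum of real Gaussian
white noise: every non-self-conjugate coefficient's phase is exactly
uniform on (−π, π] (argument of a complex Gaussian), and Hermitian
antisymmetry — hence real reconstructions — holds by construction, with
self-conjugate coefficients (DC, Nyquist lines) at phase 0 or π.

Numerical decisions:

* Degenerate blends (antipodal phasors at M = 0.5, blend magnitude
  < 1e−12) fall back to the original phase — a deterministic, bias-free
  tie-break.
* Out-of-range pixels after reconstruction are hard-clamped to [0, 1] by
  default (reproducible); a smooth compressor (`clip_mode="tanh"`, scaled
  tanh inside a 1/sharpness margin at each boundary) and a `"none"` mode
  for fidelity experiments are available.
* Augmentation operates on [0, 1] pixel values *before* any model-side
  normalization, and after any geometric augmentation, so the mask grid
  matches the final network input resolution.
* The filtering alternative (`filter_augment`) multiplies coefficients by
  the mask — attenuating amplitude rather than scrambling phase — for
  comparisons between the two manipulation styles.

Policy: each training image is independently replaced by its scrambled
version with probability p (0.3 = weak bias, 0.5 = strong), with exactly
one mask drawn per replaced image (single mask, 50/50 combined-channel
pair, or the mixed-σ mixture whose table probabilities are the replacement
probabilities). The printed mixture tables are followed verbatim; the
strong mixture's total replacement mass (0.8) is not additionally capped.
Evaluation data never passes through the augmentation path.

## Attacks

ℓ∞ PGD: τ₀ ~ U(−ε, ε), then ascent on the sign of the input gradient with
projection onto the ε-ball and the [0, 1] pixel range after every step.
Defaults — 10 steps, step size ε/4, random init — are standard PGD
practice (iteration count and step size are free parameters of the
procedure); configurable and recorded with config hashes. ℓ2 PGD
normalizes the gradient and projects onto the ℓ2 ball (step 2.5·ε/steps).
FGSM is the single-step, zero-init special case with step ε; sign(0) = 0.
There is no early stopping on success: all images run the full step
budget. Attacks differentiate through the model's own preprocessing chain
(white-box fidelity). Success means the clean top-1 prediction was correct
*and* the attacked prediction is wrong; only successful perturbations
enter spectral analysis. Non-finite gradients abort the affected image
with a logged diagnostic rather than poisoning the batch.

## Spectral probe

Perturbation power is the channel-averaged squared DFT magnitude. Radial
profiles aggregate power into unit-width bins centered at integer cpi
(bin k covers [k − 0.5, k + 0.5)), DC removed; corner coefficients with
r > nyquist are discarded (count-checked in tests), and the result is
normalized to proportions. Band AUC is the discrete sum of bin proportions
whose centers fall in the band — integration is over raw bins, not a
log-frequency axis, which matters only for comparisons across unequal bin
widths (none are used here). ΔAUC_%power is the model's band share minus
the baseline's; when bands tile the retained spectrum the six deltas sum
to zero.

Uncertainty: percentile bootstrap over perturbations, 10,000 resamples by
default. Spearman correlations (band shift vs robustness gain) use average
ranks for ties and a two-sided large-sample t approximation; exact
permutation p-values are available behind a flag for n ≤ 8, where
enumeration (≤ 40k permutations) is cheap — beyond that the t
approximation is accurate and enumeration cost grows factorially.
Spectral analysis defaults to a single training seed per condition (seed
0), as robustness varies little across seeds at this scale; configurable.

## Robustness evaluation

Robust accuracy is measured with fresh attacks at each ε over the grid
{1..7}/255; the curve summary is the trapezoidal area over ε on the pixel
scale (constant accuracy a ⇒ a · 6/255), optionally normalized by grid
width to read as mean accuracy. No ε = 0 anchor is included by default
(the standard grid starts at 1/255); a flag adds one. Relative robustness
is auc(model) − auc(baseline). Across-seed uncertainty uses the same
10,000-resample percentile bootstrap.

## Representational similarity

Response matrices (images × units) are summarized by RDMs of pairwise
Euclidean distances on raw patterns — no row normalization. Similarity
between two systems is Spearman ρ over the vectorized strict upper
triangles (diagonal excluded, average ranks). Model responses come from
the penultimate pooled representation; the extraction point is a
configuration key for other architectures.

## Synthetic data: what it emulates and what it does not

**Band-coded images.** Each class has a fixed random template whose
Fourier support is restricted to a configurable radial band [lo, hi) cpi
(unit RMS power, per-channel independent band-limited noise); images are
a·template + broadband unit-variance Gaussian noise, mapped affinely into
[0, 1] with ±3.5 SD inside the range (clipping touches a negligible pixel
fraction, preserving spectral accounting). The amplitude a is set so that
in-band signal power over out-of-band noise power equals the configured `snr`
(default 3 — strong enough that a small CNN reaches ≥ 98% test accuracy
while the task is non-trivial under noise). Because templates are fixed
per class, identity is carried by band-limited *phase structure*, not by
amplitude statistics — matching the premise that phase carries image
structure. Defaults: 4 classes × 200 images at 64² (nyquist 32 cpi),
informative band [8, 16); the 224 geometry remains available for
exactness checks.

What this does **not** emulate: natural-image 1/f amplitude spectra,
object shape and texture, cross-channel color statistics, dataset bias, or
fMRI noise structure. Passing the recovery checks shows the *pipeline* is
correct — that reliance planted in a known band is read out from
perturbation spectra — not that any particular natural-image model is
band-reliant.

**Reference responses.** A Gaussian random linear readout (variance 1/d)
of a source model's features plus Gaussian noise. `noise_sd` is expressed
relative to the RMS of the noiseless readout, so the noise grid
{0, 0.5, 1, 2} means "none / half-signal / signal-strength / double" for
any feature scale. With zero noise and enough units the random projection
is near-isometric and rank similarity to the source is ≈ 1.

**Fixture classifier.** A fixed affine input normalization ((x − 0.5)·4,
matching the low-contrast synthetic images and differentiable, so attacks
see the true preprocessing) followed by three strided conv-ReLU stages
(8, 16, 32 channels; kernels 5, 5, 3; stride 2), global average pooling
(the 32-d penultimate feature) and a linear head — ~8.6k parameters,
mirroring the conv-trunk / average-pool / linear-head shape of standard
backbones at a scale that trains in CPU-seconds. The whole stack (layers,
backprop, SGD) is implemented on numpy; input gradients are exact (checked
against finite differences).

## Training harness

Desk-scale recipe (default): 5 epochs, SGD momentum 0.9, lr 0.02 decayed
×0.1 at epoch 4, weight decay 1e−4, batch 32, label smoothing 0.1 —
reaches ≥ 98% validation accuracy on the default task in ~10 s. The
full-scale recipe (60 epochs, lr 0.1 decayed ×0.1 at epoch 45, batch 1024,
momentum 0.9, weight decay 1e−4, smoothing 0.1) ships as the named
`PAPER_SCALE` preset requiring explicit opt-in.

Seed policy: one integer seed spawns independent named substreams for
model init, data order + augmentation draws, and attack init
(`numpy.random.SeedSequence`). Conditions run at the same seed share
their weight initialization, enabling matched comparisons that differ
only in augmentation. A `policy=None` run and a p = 0 policy produce
bit-identical weights. Every on-disk artifact carries the config hash and
seed that produced it; stages resume from matching artifacts and refuse
to reuse mismatched ones.

## Ground-truth recovery conditions

The end-to-end check — train on band-B data, PGD at ε = 4/255, filter
successes, radial profile, ΔAUC vs a broadband-trained baseline — uses the
two highest octaves, [8, 16) and [16, 32) cpi, as target bands (three
seeds each). The reason is a real property of rectified energy detectors,
not an artifact: a conv-ReLU-pool channel tuned to frequency f responds
(and is attacked) partly at its rectification harmonics near 2f, so models
trained on *low*-band signal at this scale show their largest reliance
shift one octave above the planted band. For the top two octaves the
harmonic falls at or beyond the nyquist and the planted octave itself
carries the maximal shift. Models planted at lower bands still show
clearly elevated in-band reliance (several-fold over baseline), just not
always the argmax octave — visible in `examples/probe_sf_reliance.py` if
the target band is changed.

## Problem sizes

Shipped defaults are sized for a single CPU: 64² images, 4 classes,
600/200 train/test split, 5-epoch training, 10-step PGD, 500–10,000
bootstrap resamples depending on context. The acceptance script runs the
full chain (9 trainings, attacks, profiles, RSA, a 7-point robustness
curve) in a few minutes.

## Known limitations

* Non-square grids use raw index radii (no per-axis cpi conversion).
* The exact permutation p-value is limited to n ≤ 8.
* The numpy network stack covers the fixture architectures, not
  arbitrary backbones; any model exposing `logits`, `features`,
  `predict`, and `loss_and_input_grad` can plug into the probe instead.
* Oriented (non-radial) masks, grayscale pathways, per-channel phase
  fields, black-box attacks, certified bounds, and noise-ceiling
  estimation for RSA are out of scope.
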