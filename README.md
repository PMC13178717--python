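# sfprobe

Tools for asking *which spatial frequencies an image classifier relies on*
and *how that reliance relates to adversarial robustness* — the measurement
problem at the heart of comparing artificial and biological vision. Human
object recognition depends critically on a narrow, one-octave mid-frequency
"human channel" (28–56 cycles per image at 224 × 224 resolution), while
conventionally trained convolutional networks lean on a broader, higher
frequency range. `sfprobe` provides the machinery to steer a classifier's
spectral diet during training, measure the resulting reliance, and relate
it to robustness and representational geometry:

- **Band-selective soft phase scrambling** — a training-time augmentation
  that preserves the Fourier phase structure inside a chosen frequency band
  and randomizes it outside, while keeping the amplitude spectrum exactly
  intact. Mask families: the human-channel band-pass, an extreme
  low-spatial-frequency (LSF) low-pass, blur-derived low-pass masks
  (fixed-σ and the weak/strong mixed-σ mixtures), 50/50 combined-channel,
  and inverse masks for necessity checks.
- **An adversarial-perturbation spectral probe** — bounded attacks spend a
  fixed energy budget on the input dimensions the model is most sensitive
  to, so the radial power spectrum of *successful* perturbations is a
  readout of spatial-frequency reliance.
- **Robustness curves** over an ε grid with area-under-curve summaries.
- **Representational similarity analysis** (Euclidean RDMs, Spearman ρ over
  upper triangles) against reference response matrices.
- **Synthetic ground truth** — band-coded labeled images whose class signal
  is confined to a known octave, synthetic reference responses with a known
  representational source, and compact fixture CNNs — so the entire chain
  is verifiable end to end on one CPU, without downloads.

## The measurements

An adversarial perturbation τ for image *x* with label *y* maximizes the
classification loss within a norm ball (ℓ∞ by default, ε = 4/255):

    τ* = argmax_{‖τ‖∞ ≤ ε}  ℓ(f_θ(x + τ), y)

solved by projected gradient descent (PGD) with random initialization, or
by the fast gradient sign method (FGSM). Perturbations that flip an
originally correct prediction are Fourier-analyzed:

    P(u, v) = (1/3) Σ_c |F(τ*_c)(u, v)|²

then rotationally averaged over unit-width radial bins r = √(u² + v²)
(cycles per image, DC removed) and normalized to a proportion-of-energy
profile. Per-octave reliance shifts against a baseline model are reported
as ΔAUC<sub>%power</sub> — the model's in-band energy share minus the
baseline's — over the octave partition
(0, 3.5), [3.5, 7), [7, 14), [14, 28), [28, 56), [56, 112) cpi
(rescaled proportionally on smaller grids).

The scrambling augmentation blends original and random phase per
coefficient, weighted by a radially symmetric mask M ∈ [0, 1]:

    φ′_c(u, v) = ∠( M·e^{iφ_c} + (1 − M)·e^{iφ_r} ),
    x′_c = F⁻¹( A_c · e^{iφ′_c} )

with one random phase field φ_r ~ U(−π, π] per image shared across RGB
channels, and the human-channel mask a unit-peak Gaussian in log frequency,
M(f) ∝ exp(−(log₂f − μ)²/2σ²) with μ = 4.5 octaves, σ = 0.4246.

## Worked example

`examples/probe_sf_reliance.py` trains a small CNN on synthetic 64 × 64
images whose class signal lives only in the [8, 16) cpi octave, attacks it
with ℓ∞ PGD at ε = 4/255, and compares perturbation spectra against a
broadband-trained baseline:

```
band-coded model  : test accuracy 1.00, 118 successful perturbations
broadband baseline: test accuracy 0.98, 135 successful perturbations

octave (cpi)   model share    baseline   delta-AUC
(0,1)                0.000       0.000      +0.000
[1,2)                0.002       0.001      +0.000
[2,4)                0.005       0.005      +0.001
[4,8)                0.032       0.022      +0.010
[8,16)               0.380       0.172      +0.208  <-- informative band
[16,32)              0.551       0.771      -0.220

Largest positive shift: [8,16) (delta +0.208) — the probe recovered the
octave that carries the class signal.
```

The model allocates 38% of its perturbation energy to the informative
octave versus the baseline's 17%, and the largest positive ΔAUC lands
exactly on the band that carries the class information: the probe reads
out ground truth. The other examples demonstrate the scrambling operator
(`scramble_conditions.py`), robustness curves under augmentation
(`robustness_curve.py`), and RSA source recovery (`rsa_reference.py`).

## Layout

```
src/sfprobe/
  frequency.py    DFT geometry, SF masks, octave bands
  scramble.py     soft phase scrambling, filtering, augmentation policy
  nn.py           numpy conv-net stack (training + input gradients)
  attacks.py      PGD (linf/l2), FGSM, success filtering
  reliance.py     perturbation spectra, radial profiles, band statistics
  robustness.py   robustness curves and AUC summaries
  rsa.py          RDMs and representational similarity
  synthetic.py    band-coded datasets, reference responses, fixture CNNs
  pipeline.py     conditions, seed policy, training harness, orchestration
```

See `docs/methods.md` for modeling assumptions, parameter choices, and
limitations.
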