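"""Synthetic inputs with known spatial-frequency ground truth.

Every stage of the probe is testable without downloads:

* **Band-coded labeled images** — each class has a fixed random template
  whose Fourier support is confined to a configurable radial band; images
  are that template plus broadband Gaussian noise at a controlled
  signal-to-noise ratio.  Class identity therefore lives in the *phase
  structure of one frequency band*, giving the reliance probe an exact
  ground truth: a classifier that solves the task must read that band.
* **Reference response matrices** — a noisy random linear readout of a
  source model's features, standing in for measured response patterns
  (e.g. voxels) whose representational geometry is known by construction.
* **Fixture classifiers** — compact conv nets (tens of thousands of
  parameters) that train to high accuracy on the band-coded task in
  CPU-seconds and expose penultimate features and input gradients.

All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequency import build_frequency_grid
from .nn import Classifier, Conv2d, GlobalAvgPool, Linear, Normalize, NumpyNet, ReLU
from .rsa import ResponseMatrix

__all__ = [
    "BandCodedDatasetSpec",
    "BandCodedDataset",
    "SyntheticReferenceSpec",
    "generate_band_coded_dataset",
    "generate_reference_responses",
    "make_fixture_classifier",
    "save_dataset",
    "load_dataset",
    "export_png",
]


@dataclass(frozen=True)
class BandCodedDatasetSpec:
    """Recipe for a band-coded labeled image set.

    ``informative_band`` is the half-open radial interval [lo, hi) cpi that
    carries all class-discriminative structure; ``snr`` is the ratio of
    in-band class-signal power to out-of-band noise power.  The default
    64 x 64 geometry (nyquist 32 cpi) keeps runtimes at desk scale.
    """

    n_classes: int = 4
    images_per_class: int = 200
    image_size: int = 64
    informative_band: tuple[float, float] = (8.0, 16.0)
    snr: float = 3.0
    seed: int = 0
    contrast_sigmas: float = 3.5  # pixel range maps +-this many SDs into [0, 1]

    def __post_init__(self) -> None:
        lo, hi = self.informative_band
        nyq = self.image_size / 2
        if not (0 < lo < hi <= nyq):
            raise ValueError(
                f"informative band [{lo}, {hi}) must lie within (0, {nyq}]"
            )
        if self.snr <= 0:
            raise ValueError("snr must be > 0")


@dataclass(frozen=True)
class BandCodedDataset:
    """Images in [0, 1] with labels, plus the generating ground truth."""

    images: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    templates: np.ndarray = field(repr=False)  # (n_classes, H, W, 3), unit power
    spec: BandCodedDatasetSpec = field(default_factory=BandCodedDatasetSpec)
    signal_amplitude: float = 1.0
    pixel_gain: float = 1.0

    def split(self, n_train_per_class: int):
        """Deterministic class-balanced (train, test) split.

        Returns ``(train_images, train_labels, test_images, test_labels)``.
        """
        tr, te = [], []
        for k in range(self.spec.n_classes):
            idx = np.flatnonzero(self.labels == k)
            tr.extend(idx[:n_train_per_class])
            te.extend(idx[n_train_per_class:])
        tr, te = np.asarray(tr), np.asarray(te)
        return self.images[tr], self.labels[tr], self.images[te], self.labels[te]


def _bandpass_noise(
    rng: np.random.Generator, size: int, band_mask: np.ndarray, channels: int = 3
) -> np.ndarray:
    """Real white noise restricted to the band in the Fourier domain, unit power."""
    out = np.empty((size, size, channels))
    for c in range(channels):
        spec = np.fft.fft2(rng.standard_normal((size, size))) * band_mask
        field_c = np.fft.ifft2(spec).real
        out[:, :, c] = field_c
    rms = np.sqrt(np.mean(out**2))
    return out / rms


def generate_band_coded_dataset(spec: BandCodedDatasetSpec) -> BandCodedDataset:
    """Generate labeled images whose class information lives in one SF band.

    Per class, a fixed band-limited random template (unit RMS power, all of
    it inside ``informative_band``); per image, broadband unit-variance
    Gaussian noise.  The template amplitude ``a`` is set so that
    ``a**2 / (out-of-band fraction of noise power) == snr``, then an affine
    map places ``contrast_sigmas`` standard deviations of the mix inside
    [0, 1] (residuals are clipped; at the default 3.5 SD this touches a
    negligible pixel fraction, so spectral accounting is preserved).
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    grid = build_frequency_grid(size, size)
    lo, hi = spec.informative_band
    band_mask = (grid.radial_freq >= lo) & (grid.radial_freq < hi)
    if not band_mask.any():
        raise ValueError("informative band contains no Fourier coefficients")

    templates = np.stack(
        [_bandpass_noise(rng, size, band_mask) for _ in range(spec.n_classes)]
    )
    out_band_frac = 1.0 - band_mask.mean()
    a = float(np.sqrt(spec.snr * out_band_frac))

    n_total = spec.n_classes * spec.images_per_class
    labels = np.repeat(np.arange(spec.n_classes), spec.images_per_class)
    mix_sd = np.sqrt(a**2 + 1.0)
    gain = 0.5 / (spec.contrast_sigmas * mix_sd)
    images = np.empty((n_total, size, size, 3))
    for i, k in enumerate(labels):
        noise = rng.standard_normal((size, size, 3))
        raw = a * templates[k] + noise
        images[i] = np.clip(0.5 + gain * raw, 0.0, 1.0)
    return BandCodedDataset(
        images=images,
        labels=labels,
        templates=templates,
        spec=spec,
        signal_amplitude=a,
        pixel_gain=gain,
    )


@dataclass(frozen=True)
class SyntheticReferenceSpec:
    """Recipe for a synthetic reference response matrix.

    ``noise_sd`` is expressed relative to the RMS of the noiseless
    projected responses, so a fixed noise grid is meaningful regardless of
    the source model's feature scale (noise_sd = 1 means noise as strong
    as the signal).
    """

    n_units: int = 64
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_reference_responses(
    source_features: ResponseMatrix | np.ndarray, spec: SyntheticReferenceSpec
) -> ResponseMatrix:
    """Noisy random linear readout of source features (images x n_units).

    The readout weight matrix is Gaussian with variance 1/feature_dim;
    additive Gaussian noise has SD ``noise_sd * RMS(noiseless readout)``.
    With zero noise and enough units the representational geometry of the
    source is preserved up to the (near-isometric) random projection.
    """
    feats = (
        source_features.values
        if isinstance(source_features, ResponseMatrix)
        else np.asarray(source_features, dtype=float)
    )
    ids = (
        source_features.image_ids if isinstance(source_features, ResponseMatrix) else ()
    )
    rng = np.random.default_rng(spec.seed)
    d = feats.shape[1]
    w = rng.standard_normal((d, spec.n_units)) / np.sqrt(d)
    clean = feats @ w
    scale = float(np.sqrt(np.mean(clean**2)))
    noise = rng.standard_normal(clean.shape) * (spec.noise_sd * scale)
    return ResponseMatrix(values=clean + noise, image_ids=ids, source="reference")


def save_dataset(dataset: BandCodedDataset, path) -> None:
    """NPZ (images, labels, templates) plus a JSON spec manifest inside."""
    import json
    from dataclasses import asdict

    np.savez_compressed(
        path,
        images=dataset.images.astype(np.float32),
        labels=dataset.labels,
        templates=dataset.templates.astype(np.float32),
        manifest=np.array(
            json.dumps(
                {
                    **asdict(dataset.spec),
                    "signal_amplitude": dataset.signal_amplitude,
                    "pixel_gain": dataset.pixel_gain,
                }
            )
        ),
    )


def load_dataset(path) -> BandCodedDataset:
    import json

    with np.load(path, allow_pickle=False) as npz:
        manifest = json.loads(str(npz["manifest"]))
        amplitude = manifest.pop("signal_amplitude")
        gain = manifest.pop("pixel_gain")
        manifest["informative_band"] = tuple(manifest["informative_band"])
        return BandCodedDataset(
            images=npz["images"].astype(np.float64),
            labels=npz["labels"],
            templates=npz["templates"].astype(np.float64),
            spec=BandCodedDatasetSpec(**manifest),
            signal_amplitude=amplitude,
            pixel_gain=gain,
        )


def export_png(images: np.ndarray, out_dir, prefix: str = "img") -> list[str]:
    """Write [0, 1] float images as 8-bit PNGs; returns the file names."""
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = []
    for i, im in enumerate(np.atleast_1d(images) if images.ndim == 4 else images[None]):
        arr = np.clip(np.round(im * 255), 0, 255).astype(np.uint8)
        name = f"{prefix}-{i:04d}.png"
        Image.fromarray(arr).save(out / name)
        names.append(name)
    return names


def make_fixture_classifier(
    image_size: int = 64,
    n_classes: int = 4,
    seed: int = 0,
    widths: tuple[int, int, int] = (8, 16, 32),
    label_smoothing: float = 0.1,
) -> Classifier:
    """A small strided conv net: conv-ReLU x3, global average pool, linear.

    Under 100k parameters, differentiable w.r.t. its input, trainable to
    >90% accuracy on a separable band-coded task in CPU-seconds; the pooled
    representation before the classification head is exposed as
    ``features``.
    """
    if image_size < 16:
        raise ValueError("image_size must be >= 16")
    rng = np.random.default_rng(seed)
    w1, w2, w3 = widths
    layers = [
        Normalize(shift=0.5, scale=4.0),
        Conv2d(3, w1, kernel_size=5, stride=2, rng=rng),
        ReLU(),
        Conv2d(w1, w2, kernel_size=5, stride=2, rng=rng),
        ReLU(),
        Conv2d(w2, w3, kernel_size=3, stride=2, rng=rng),
        ReLU(),
        GlobalAvgPool(),
        Linear(w3, n_classes, rng=rng),
    ]
    net = NumpyNet(layers, feature_index=len(layers) - 2)
    return Classifier(net, n_classes=n_classes, label_smoothing=label_smoothing)
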