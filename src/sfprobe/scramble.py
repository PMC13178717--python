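"""Band-selective soft phase scrambling and the filter-based alternative.

Phase scrambling randomizes Fourier phases while keeping the amplitude
spectrum, destroying image structure without changing spectral energy.  The
soft, band-selective variant blends the original and a random phase in the
complex plane, weighted per coefficient by a spatial-frequency mask M::

    phi'_c(u, v) = angle( M * exp(i phi_c) + (1 - M) * exp(i phi_r) )
    x'_c = IFFT( A_c * exp(i phi'_c) )

so M = 1 preserves the original phase, M = 0 fully scrambles, and
intermediate weights scramble partially.  One random phase field phi_r is
drawn per image and shared across the three RGB channels to preserve color
coherence; the amplitude spectrum A_c is retained exactly.

Images are H x W x 3 float arrays in [0, 1]; scrambling operates on this
pixel scale, before any dataset normalization, and evaluation images are
never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequency import FrequencyGrid, SFMask

__all__ = [
    "PhaseField",
    "AugmentationPolicy",
    "sample_phase_field",
    "phase_scramble",
    "filter_augment",
    "apply_policy",
    "soft_clip",
]

# blended phasors shorter than this are treated as degenerate (antipodal
# phasors at M = 0.5); the original phase is kept there
_DEGENERATE_NORM = 1e-12


@dataclass(frozen=True)
class PhaseField:
    """Per-coefficient random phase in (-pi, pi], shared across channels.

    Hermitian-antisymmetric (``value(-u, -v) = -value(u, v)``) so that an
    image reconstructed with these phases is real; self-conjugate
    coefficients (DC and Nyquist lines) carry phase 0 or pi.
    """

    values: np.ndarray = field(repr=False)
    grid: FrequencyGrid = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("phase field shape does not match grid")

    def is_hermitian(self, atol: float = 1e-9) -> bool:
        v = self.values
        mirrored = v[
            np.mod(-self.grid.u.astype(int), self.grid.height)[:, :1],
            np.mod(-self.grid.v.astype(int), self.grid.width)[:1, :],
        ]
        # phases compare on the circle: exp(i a) == exp(-i b)
        return bool(np.allclose(np.exp(1j * mirrored), np.exp(-1j * v), atol=atol))


def sample_phase_field(grid: FrequencyGrid, seed: int | np.random.Generator) -> PhaseField:
    """Draw a uniform random phase field with exact Hermitian symmetry.

    The field is taken as the phase spectrum of real white noise: for every
    non-self-conjugate coefficient the DFT value is complex Gaussian, whose
    argument is uniform on (-pi, pi], and the conjugate-pair structure of a
    real signal enforces the antisymmetry by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    values = np.angle(np.fft.fft2(noise))
    return PhaseField(values=values, grid=grid)


def soft_clip(x: np.ndarray, mode: str = "clamp", sharpness: float = 10.0) -> np.ndarray:
    """Map out-of-range pixels back into [0, 1].

    ``clamp`` (default) is a hard clip — reproducible and exact inside the
    range.  ``none`` skips range handling entirely (the raw reconstruction,
    which conserves the amplitude spectrum exactly).  ``tanh`` compresses values near and beyond each boundary into a
    margin of width ``1/sharpness`` inside it with a scaled tanh (continuous,
    slope 1 at the margin edge, asymptotic to the boundary), leaving pixels
    further than the margin from both boundaries untouched.
    """
    if mode == "none":  # raw reconstruction, for fidelity checks
        return x
    if mode == "clamp":
        return np.clip(x, 0.0, 1.0)
    if mode == "tanh":
        out = x.copy()
        scale = 1.0 / sharpness
        hi = x > 1.0 - scale
        lo = x < scale
        out[hi] = (1.0 - scale) + scale * np.tanh((x[hi] - (1.0 - scale)) / scale)
        out[lo] = scale - scale * np.tanh((scale - x[lo]) / scale)
        return out
    raise ValueError(f"unknown clip mode {mode!r}")


def _check_image(image: np.ndarray, grid: FrequencyGrid) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[:2] != grid.shape:
        raise ValueError(
            f"image shape {img.shape[:2]} does not match mask grid {grid.shape}"
        )
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def phase_scramble(
    image: np.ndarray,
    mask: SFMask,
    random_phase: PhaseField,
    clip_mode: str = "clamp",
) -> np.ndarray:
    """Soft band-selective phase scramble of one RGB image.

    Per channel the amplitude spectrum is preserved exactly; the phase is
    replaced by the complex-plane blend of the original and random phasors
    weighted by the mask.  The DC phase is always preserved (mean luminance
    is untouched up to range handling).  Degenerate blends — antipodal
    phasors at weight 0.5, where the blend has no direction — fall back to
    the original phase.
    """
    img = _check_image(image, mask.grid)
    if random_phase.grid.shape != mask.grid.shape:
        raise ValueError("random phase field and mask are on different grids")
    if not random_phase.is_hermitian():
        raise ValueError("random phase field is not Hermitian-antisymmetric")

    m = mask.weights.copy()
    m[0, 0] = 1.0  # DC phase always preserved
    phi_r = random_phase.values
    out = np.empty_like(img)
    for c in range(3):
        spec = np.fft.fft2(img[:, :, c])
        amp = np.abs(spec)
        phi = np.angle(spec)
        blend = m * np.exp(1j * phi) + (1.0 - m) * np.exp(1j * phi_r)
        degenerate = np.abs(blend) < _DEGENERATE_NORM
        phi_new = np.where(degenerate, phi, np.angle(blend))
        recon = np.fft.ifft2(amp * np.exp(1j * phi_new))
        out[:, :, c] = recon.real
    return soft_clip(out, mode=clip_mode)


def filter_augment(image: np.ndarray, mask: SFMask, clip_mode: str = "clamp") -> np.ndarray:
    """Multiply Fourier coefficients by the mask weights (amplitude filter).

    The commonly used filtering alternative to phase scrambling: spectral
    energy outside the passband is attenuated rather than phase-randomized,
    so the amplitude spectrum is *not* preserved.
    """
    img = _check_image(image, mask.grid)
    out = np.empty_like(img)
    for c in range(3):
        spec = np.fft.fft2(img[:, :, c]) * mask.weights
        out[:, :, c] = np.fft.ifft2(spec).real
    return soft_clip(out, mode=clip_mode)


@dataclass(frozen=True)
class AugmentationPolicy:
    """Probabilistic per-image augmentation during training.

    Each training image is independently replaced by its scrambled version
    with probability ``replace_prob`` (p = 0.3 imposes a weak bias, p = 0.5
    a strong one).  ``masks``/``mask_probs`` describe the mask distribution:
    a single mask, the 50/50 combined-channel pair, or a mixed-sigma
    mixture whose per-mask probabilities replace ``replace_prob`` when
    ``mixture_mode`` is set (residual mass leaves the image unmodified).
    Exactly one mask is applied per replaced image.
    """

    masks: tuple[SFMask, ...]
    replace_prob: float = 0.3
    mask_probs: tuple[float, ...] | None = None
    mixture_mode: bool = False
    use_filter: bool = False
    clip_mode: str = "clamp"

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("policy needs at least one mask")
        if not self.mixture_mode and not 0.0 <= self.replace_prob <= 1.0:
            raise ValueError("replace_prob must lie in [0, 1]")
        if self.mask_probs is not None:
            if len(self.mask_probs) != len(self.masks):
                raise ValueError("need one probability per mask")
            if sum(self.mask_probs) > 1.0 + 1e-9:
                raise ValueError("mask probabilities must sum to <= 1")

    def _branch_probs(self) -> np.ndarray:
        """Probability of each mask branch plus the identity branch (last)."""
        if self.mixture_mode:
            p = np.asarray(self.mask_probs, dtype=float)
        else:
            if self.mask_probs is None:
                p = np.full(len(self.masks), self.replace_prob / len(self.masks))
            else:
                p = self.replace_prob * np.asarray(self.mask_probs, dtype=float)
        return np.append(p, 1.0 - p.sum())


def apply_policy(
    batch: np.ndarray | list[np.ndarray],
    policy: AugmentationPolicy,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Apply the augmentation policy to a batch of training images.

    Returns a new (N, H, W, 3) array; each image is independently either
    left unchanged or replaced by a scrambled (or filtered) version under
    exactly one sampled mask, with a fresh random phase field per image.
    Evaluation data must never pass through this function.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    imgs = np.stack([np.asarray(im, dtype=np.float64) for im in batch])
    grid = policy.masks[0].grid
    probs = policy._branch_probs()
    if probs[-1] < -1e-9:
        raise ValueError("total replacement probability exceeds 1")
    probs = np.clip(probs, 0.0, None)
    probs = probs / probs.sum()
    branches = rng.choice(len(probs), size=len(imgs), p=probs)
    out = imgs.copy()
    for i, b in enumerate(branches):
        if b == len(policy.masks):  # identity branch
            continue
        mask = policy.masks[b]
        if policy.use_filter:
            out[i] = filter_augment(imgs[i], mask, clip_mode=policy.clip_mode)
        else:
            phase = sample_phase_field(grid, rng)
            out[i] = phase_scramble(imgs[i], mask, phase, clip_mode=policy.clip_mode)
    return out
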