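"""DFT frequency geometry and spatial-frequency mask families.

Everything downstream — phase-scrambling augmentation, the adversarial
perturbation spectral probe, octave-band statistics — is defined on the
two-dimensional DFT grid of the network input.  Frequencies are measured in
cycles per image (cpi): the radial frequency of coefficient ``(u, v)`` is
``r = sqrt(u**2 + v**2)`` with ``u, v`` the signed integer frequency indices,
and the highest resolvable frequency on an ``H x W`` grid is ``min(H, W)/2``
cpi (112 cpi at the ImageNet-standard 224 x 224 resolution).

Arrays are stored in the *unshifted* ``numpy.fft.fft2`` layout so that masks
can be applied directly to FFT output without ``fftshift`` round trips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FrequencyGrid",
    "SFMask",
    "OctaveBands",
    "MaskMixture",
    "build_frequency_grid",
    "gaussian_logfreq_mask",
    "extreme_lsf_mask",
    "blur_magnitude_mask",
    "mixed_sigma_policy",
    "invert_mask",
    "constant_mask",
    "save_mask",
    "load_mask",
    "radial_response",
    "export_radial_response_csv",
]

#: Octave band edges (cpi) used on a 224 x 224 grid.  The two lowest octaves,
#: (0, 1.75) and [1.75, 3.5), are merged into a single extreme-LSF band
#: because Fourier coefficients are sparse at the lowest radii; every band
#: above 3.5 cpi spans exactly one octave and the [28, 56) band is the
#: mid-frequency "human channel".
DEFAULT_BAND_EDGES_224 = (0.0, 3.5, 7.0, 14.0, 28.0, 56.0, 112.0)

#: Human-channel mask parameters: a Gaussian envelope in log2-frequency
#: centred at 2**4.5 ~ 22.6 cpi with bandwidth 0.4246 octaves.
HUMAN_CHANNEL_MU = 4.5
HUMAN_CHANNEL_SIGMA = 0.4246

#: Centre of the extreme-LSF mask: geometric mean of 1.75 and 3.5 cpi.
EXTREME_LSF_MU = float(np.log2(np.sqrt(1.75 * 3.5)))


@dataclass(frozen=True)
class FrequencyGrid:
    """Radial-frequency geometry of a 2-D DFT.

    Attributes
    ----------
    height, width : int
        Spatial dimensions in pixels.
    u, v : ndarray of shape (height, width)
        Signed integer frequency indices (rows / columns) in the unshifted
        ``fft2`` layout; ``u`` varies along axis 0.
    radial_freq : ndarray of shape (height, width)
        ``sqrt(u**2 + v**2)`` in cycles per image.
    nyquist_cpi : float
        Highest resolvable axis frequency, ``min(height, width) / 2``.
    """

    height: int
    width: int
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)
    radial_freq: np.ndarray = field(repr=False)
    nyquist_cpi: float

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def self_conjugate(self) -> np.ndarray:
        """Boolean map of coefficients that are their own conjugate partner.

        These are the coefficients where (-u, -v) == (u, v) modulo the grid:
        DC and, for even dimensions, the Nyquist rows/columns.  Their DFT
        values are real for real images, so their phase is 0 or pi.
        """
        um = np.mod(-self.u, self.height) == np.mod(self.u, self.height)
        vm = np.mod(-self.v, self.width) == np.mod(self.v, self.width)
        return um & vm


def build_frequency_grid(height: int, width: int) -> FrequencyGrid:
    """Build the radial-frequency map for an ``height x width`` DFT.

    Raises
    ------
    ValueError
        If either dimension is smaller than 2.
    """
    if height < 2 or width < 2:
        raise ValueError(f"grid dimensions must be >= 2, got {height}x{width}")
    u = (np.fft.fftfreq(height) * height).astype(np.float64)
    v = (np.fft.fftfreq(width) * width).astype(np.float64)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    radial = np.hypot(uu, vv)
    return FrequencyGrid(
        height=height,
        width=width,
        u=uu,
        v=vv,
        radial_freq=radial,
        nyquist_cpi=min(height, width) / 2.0,
    )


@dataclass(frozen=True)
class SFMask:
    """Radially symmetric per-coefficient weights in [0, 1] on a DFT grid.

    ``weights[u, v] = 1`` preserves the original Fourier phase at that
    coefficient during scrambling; ``0`` replaces it entirely with random
    phase.  ``condition`` records the mask family (``human_channel``,
    ``extreme_lsf``, ``fixed_sigma_lsf``, ``mixed_sigma_lsf``,
    ``inverse_*``, ``custom``).
    """

    weights: np.ndarray = field(repr=False)
    grid: FrequencyGrid = field(repr=False)
    condition: str = "custom"
    mu_octaves: float | None = None
    sigma: float | None = None
    unit_peak: bool = False
    inverse: bool = False

    def __post_init__(self) -> None:
        w = self.weights
        if w.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {w.shape} does not match grid {self.grid.shape}"
            )
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("mask weights must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def metadata(self) -> dict:
        return {
            "condition": self.condition,
            "mu_octaves": self.mu_octaves,
            "sigma": self.sigma,
            "unit_peak": self.unit_peak,
            "inverse": self.inverse,
            "height": self.grid.height,
            "width": self.grid.width,
        }


def constant_mask(grid: FrequencyGrid, value: float, condition: str = "custom") -> SFMask:
    """Uniform mask (useful for identity / full-scramble limits)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("mask value must lie in [0, 1]")
    return SFMask(
        weights=np.full(grid.shape, float(value)),
        grid=grid,
        condition=condition,
        unit_peak=value == 1.0,
    )


def gaussian_logfreq_mask(
    grid: FrequencyGrid,
    mu_octaves: float,
    sigma_octaves: float,
    hard_pass_below_center: bool = False,
    condition: str | None = None,
) -> SFMask:
    """Gaussian band-pass mask in log2-frequency, unit peak.

    The weight at radial frequency ``f > 0`` is proportional to
    ``exp(-(log2 f - mu)**2 / (2 sigma**2))`` and the map is normalized so
    the largest non-DC coefficient weight is exactly 1.  With
    ``hard_pass_below_center`` every coefficient with ``0 < f <= 2**mu``
    is fully preserved (weight 1), turning the band-pass into a low-pass
    with a Gaussian roll-off — the construction used for the extreme-LSF
    condition.

    DC is excluded from the log-frequency formula; its weight is 1 for
    hard-pass (low-pass) masks, 0 for pure band-pass masks, so that
    band-pass scrambling never depends on mean luminance while low-pass
    masks keep it intact.
    """
    if sigma_octaves <= 0:
        raise ValueError(f"sigma_octaves must be > 0, got {sigma_octaves}")
    r = grid.radial_freq
    w = np.zeros(grid.shape)
    nz = r > 0
    w[nz] = np.exp(-((np.log2(r[nz]) - mu_octaves) ** 2) / (2.0 * sigma_octaves**2))
    if hard_pass_below_center:
        w[nz & (r <= 2.0**mu_octaves)] = 1.0
    peak = w[nz].max()
    w[nz] /= peak
    w[~nz] = 1.0 if hard_pass_below_center else 0.0
    np.clip(w, 0.0, 1.0, out=w)
    if condition is None:
        condition = "extreme_lsf" if hard_pass_below_center else "human_channel"
    return SFMask(
        weights=w,
        grid=grid,
        condition=condition,
        mu_octaves=float(mu_octaves),
        sigma=float(sigma_octaves),
        unit_peak=True,
    )


def extreme_lsf_mask(
    grid: FrequencyGrid,
    sigma_octaves: float = HUMAN_CHANNEL_SIGMA,
    mu_octaves: float = EXTREME_LSF_MU,
) -> SFMask:
    """Low-pass mask preserving the lowest two octaves (f < 3.5 cpi at 224).

    Gaussian in log-frequency centred at the geometric mean of 1.75 and
    3.5 cpi, with a hard pass for all frequencies below the centre.  The
    bandwidth is configurable; by default it reuses the human-channel
    roll-off so the two conditions differ only in band placement.
    """
    return gaussian_logfreq_mask(
        grid,
        mu_octaves=mu_octaves,
        sigma_octaves=sigma_octaves,
        hard_pass_below_center=True,
        condition="extreme_lsf",
    )


def human_channel_mask(
    grid: FrequencyGrid,
    mu_octaves: float = HUMAN_CHANNEL_MU,
    sigma_octaves: float = HUMAN_CHANNEL_SIGMA,
) -> SFMask:
    """Band-pass mask for the mid-frequency human channel (peak 2**mu cpi)."""
    return gaussian_logfreq_mask(
        grid, mu_octaves=mu_octaves, sigma_octaves=sigma_octaves, condition="human_channel"
    )


def _gaussian_kernel_2d(sigma_px: float) -> np.ndarray:
    radius = int(np.ceil(4.0 * sigma_px))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma_px**2))
    k = np.outer(g, g)
    return k / k.sum()


def blur_magnitude_mask(
    grid: FrequencyGrid, sigma_px: float, condition: str = "fixed_sigma_lsf"
) -> SFMask:
    """Low-pass mask from the magnitude response of an isotropic Gaussian.

    The kernel (standard deviation ``sigma_px`` pixels, truncated at radius
    ``ceil(4 sigma)``) is zero-padded to the grid size, circularly centred
    at the origin, and its DFT magnitude — unit-peak at DC — becomes the
    mask.  Images are *not* blurred: the response only decides which
    frequencies keep their phase during scrambling.
    """
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    k = _gaussian_kernel_2d(sigma_px)
    kh, kw = k.shape
    if kh > grid.height or kw > grid.width:
        raise ValueError(
            f"kernel support {kh}x{kw} exceeds grid {grid.height}x{grid.width}"
        )
    padded = np.zeros(grid.shape)
    padded[:kh, :kw] = k
    # roll so the kernel centre sits at index (0, 0): even (real) DFT
    padded = np.roll(padded, shift=(-(kh // 2), -(kw // 2)), axis=(0, 1))
    w = np.abs(np.fft.fft2(padded))
    w /= w.max()
    np.clip(w, 0.0, 1.0, out=w)
    return SFMask(
        weights=w,
        grid=grid,
        condition=condition,
        sigma=float(sigma_px),
        unit_peak=True,
    )


def invert_mask(mask: SFMask) -> SFMask:
    """Elementwise ``1 - weights``: scramble the formerly preserved band.

    Used for the necessity-check conditions, where phase scrambling is
    concentrated *within* the band of interest and the rest of the spectrum
    is left intact.  Involutive: ``invert_mask(invert_mask(m))`` recovers
    ``m`` (to one ulp of the complement).
    """
    condition = (
        mask.condition.removeprefix("inverse_")
        if mask.inverse
        else f"inverse_{mask.condition}"
    )
    return SFMask(
        weights=1.0 - mask.weights,
        grid=mask.grid,
        condition=condition,
        mu_octaves=mask.mu_octaves,
        sigma=mask.sigma,
        unit_peak=False,
        inverse=not mask.inverse,
    )


# ---------------------------------------------------------------------------
# mixed-sigma low-pass mixtures


#: (sigma_px, probability) pairs for the two mixture variants.  Residual
#: probability mass leaves the image unmodified; each image receives at most
#: one mask per training step.
MIXED_SIGMA_TABLES = {
    "weak": ((1.0, 0.2129), (2.0, 0.0653), (3.0, 0.0200), (4.0, 0.0062), (5.0, 0.0019)),
    "strong": ((1.0, 0.2), (2.0, 0.2), (4.0, 0.2), (8.0, 0.2)),
}


@dataclass(frozen=True)
class MaskMixture:
    """Discrete distribution over blur-derived masks plus an identity branch."""

    sigmas: tuple[float, ...]
    probabilities: tuple[float, ...]
    variant: str

    @property
    def p_unmodified(self) -> float:
        return 1.0 - sum(self.probabilities)

    def masks(self, grid: FrequencyGrid) -> list[SFMask]:
        return [
            blur_magnitude_mask(grid, s, condition="mixed_sigma_lsf") for s in self.sigmas
        ]

    def sample_sigma(self, rng: np.random.Generator) -> float | None:
        """Draw a kernel width, or None for the unmodified-image branch."""
        p = np.asarray(self.probabilities + (self.p_unmodified,))
        idx = rng.choice(len(p), p=p)
        return None if idx == len(self.sigmas) else self.sigmas[idx]


def mixed_sigma_policy(variant: str) -> MaskMixture:
    """The mixed-sigma low-pass mixture for the given bias strength.

    weak: sigma in {1..5} px with probabilities {0.2129, 0.0653, 0.0200,
    0.0062, 0.0019}; strong: sigma in {1, 2, 4, 8} px each with p = 0.2.
    """
    try:
        table = MIXED_SIGMA_TABLES[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; expected 'weak' or 'strong'"
        ) from None
    sigmas, probs = zip(*table)
    return MaskMixture(sigmas=sigmas, probabilities=probs, variant=variant)


# ---------------------------------------------------------------------------
# octave bands


@dataclass(frozen=True)
class OctaveBands:
    """Ordered, disjoint frequency bands in cpi.

    Bands are half-open ``[lo, hi)`` except the lowest, which is open at 0
    so the DC coefficient is excluded.  The default partition at nyquist 112
    is (0, 3.5), [3.5, 7), [7, 14), [14, 28), [28, 56), [56, 112): one
    merged extreme-LSF band followed by exact octaves, [28, 56) being the
    human channel.
    """

    edges_cpi: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_cpi)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("band edges must be strictly increasing")
        if len(self.labels) != len(e) - 1:
            raise ValueError("need one label per band")

    @classmethod
    def default(cls, nyquist_cpi: float = 112.0) -> "OctaveBands":
        """The standard six-band partition, rescaled to an arbitrary nyquist."""
        scale = nyquist_cpi / 112.0
        edges = tuple(x * scale for x in DEFAULT_BAND_EDGES_224)
        labels = tuple(
            (f"({edges[i]:g},{edges[i+1]:g})" if i == 0 else f"[{edges[i]:g},{edges[i+1]:g})")
            for i in range(len(edges) - 1)
        )
        return cls(edges_cpi=edges, labels=labels)

    @property
    def n_bands(self) -> int:
        return len(self.edges_cpi) - 1

    def assign(self, freqs: np.ndarray) -> np.ndarray:
        """Band index per frequency; -1 for DC / out-of-range frequencies."""
        f = np.asarray(freqs, dtype=float)
        idx = np.searchsorted(self.edges_cpi, f, side="right") - 1
        idx[(f <= self.edges_cpi[0]) | (f >= self.edges_cpi[-1])] = -1
        return idx

    def human_channel_index(self) -> int | None:
        """Index of the one-octave band starting at 28 cpi (rescaled)."""
        scale = self.edges_cpi[-1] / 112.0
        for i in range(self.n_bands):
            if np.isclose(self.edges_cpi[i], 28.0 * scale):
                return i
        return None


# ---------------------------------------------------------------------------
# serialization


def save_mask(mask: SFMask, path: str | Path) -> None:
    """Write mask weights + JSON metadata to an NPZ file."""
    np.savez(
        path,
        weights=mask.weights,
        metadata=np.array(json.dumps(mask.metadata())),
    )


def load_mask(path: str | Path) -> SFMask:
    with np.load(path, allow_pickle=False) as npz:
        weights = npz["weights"]
        meta = json.loads(str(npz["metadata"]))
    grid = build_frequency_grid(meta["height"], meta["width"])
    return SFMask(
        weights=weights,
        grid=grid,
        condition=meta["condition"],
        mu_octaves=meta["mu_octaves"],
        sigma=meta["sigma"],
        unit_peak=meta["unit_peak"],
        inverse=meta["inverse"],
    )


def radial_response(mask: SFMask) -> tuple[np.ndarray, np.ndarray]:
    """One-dimensional magnitude response: mean weight per unit radial bin.

    Bin k covers [k - 0.5, k + 0.5) cpi for k = 1..nyquist; DC excluded.
    """
    r = mask.grid.radial_freq
    nyq = int(mask.grid.nyquist_cpi)
    k = np.rint(r).astype(int)
    keep = (r > 0) & (k >= 1) & (k <= nyq)
    counts = np.bincount(k[keep], minlength=nyq + 1)[1:]
    sums = np.bincount(k[keep], weights=mask.weights[keep], minlength=nyq + 1)[1:]
    f = np.arange(1, nyq + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        resp = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return f, resp


def export_radial_response_csv(mask: SFMask, path: str | Path) -> None:
    """CSV with columns f_cpi, weight (for 1-D magnitude-response plots)."""
    f, resp = radial_response(mask)
    import pandas as pd

    pd.DataFrame({"f_cpi": f, "weight": resp}).to_csv(path, index=False)
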