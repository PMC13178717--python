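"""Band-selective phase scrambling under every mask condition.

Builds the five augmentation masks on a 64 x 64 grid (nyquist 32 cpi),
scrambles one synthetic image under each, verifies that the amplitude
spectrum survives untouched, and writes the scrambled images as PNGs with
a JSON manifest.  Phase coherence with the original image shows which band
each condition protects: near 1 inside the preserved band, near 0 where
phases were randomized.
"""

import json
from pathlib import Path

import numpy as np

from sfprobe import (
    BandCodedDatasetSpec,
    blur_magnitude_mask,
    build_frequency_grid,
    extreme_lsf_mask,
    generate_band_coded_dataset,
    human_channel_mask,
    invert_mask,
    phase_scramble,
    sample_phase_field,
)
from sfprobe.synthetic import export_png

OUT = Path("scramble-demo")

grid = build_frequency_grid(64, 64)
masks = {
    "human_channel": human_channel_mask(grid, mu_octaves=3.0),
    "extreme_lsf": extreme_lsf_mask(grid, mu_octaves=0.3),
    "fixed_sigma_lsf": blur_magnitude_mask(grid, sigma_px=1.5 * 64 / 224),
    "mixed_sigma_lsf": blur_magnitude_mask(
        grid, sigma_px=2.0 * 64 / 224, condition="mixed_sigma_lsf"
    ),
    "inverse_human": invert_mask(human_channel_mask(grid, mu_octaves=3.0)),
}

image = generate_band_coded_dataset(
    BandCodedDatasetSpec(n_classes=1, images_per_class=1, seed=7)
).images[0]

manifest = []
print(f"{'condition':<18}{'amp err':>10}{'coh@pass':>10}{'coh@stop':>10}")
for i, (name, mask) in enumerate(masks.items()):
    field = sample_phase_field(grid, seed=100 + i)
    out = phase_scramble(image, mask, field, clip_mode="none")
    spec_in = np.fft.fft2(image[:, :, 0])
    spec_out = np.fft.fft2(out[:, :, 0])
    amp_err = np.abs(np.abs(spec_out) - np.abs(spec_in)).max() / np.abs(spec_in).max()
    # phase coherence = cos(phase difference), averaged over a radial ring
    # at the mask's most-preserved and most-scrambled frequencies
    coh = np.cos(np.angle(spec_out) - np.angle(spec_in))
    r = grid.radial_freq
    valid = (r > 0) & (r <= grid.nyquist_cpi)
    w = np.where(valid, mask.weights, np.nan)
    pass_r = r[np.unravel_index(np.nanargmax(w), r.shape)]
    stop_r = r[np.unravel_index(np.nanargmin(w), r.shape)]
    coh_pass = float(coh[np.abs(r - pass_r) < 1].mean())
    coh_stop = float(coh[np.abs(r - stop_r) < 1].mean())
    print(f"{name:<18}{amp_err:>10.1e}{coh_pass:>10.2f}{coh_stop:>10.2f}")
    names = export_png(np.clip(out, 0, 1)[None], OUT, prefix=name)
    manifest.append({"file": names[0], "condition": name, "phase_seed": 100 + i})

(OUT / "manifest.json").write_text(json.dumps(manifest, indent=2))
print(f"\nwrote {len(manifest)} scrambled images + manifest.json to {OUT}/")
print(
    "Amplitude error ~1e-16 in every condition: scrambling only touches phase.\n"
    "Coherence is ~1 where a mask's weight peaks (phase preserved) and ~0\n"
    "where it vanishes (phase randomized); the inverse mask scrambles exactly\n"
    "the band its parent protected."
)
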