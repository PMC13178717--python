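"""Recover a classifier's informative frequency band from its adversarial
perturbations.

Trains one fixture CNN on synthetic images whose class signal lives only
in the [8, 16) cpi octave and a baseline CNN on broadband class signal,
attacks both with l-inf PGD at eps = 4/255, and compares the radial power
profiles of the successful perturbations.  The largest positive per-octave
power shift (delta-AUC of percent power) should land exactly on the
informative octave.
"""

import numpy as np

from sfprobe import (
    AttackConfig,
    BandCodedDatasetSpec,
    OctaveBands,
    band_delta_auc,
    build_frequency_grid,
    filter_successful,
    generate_band_coded_dataset,
    make_fixture_classifier,
    mean_profile_with_ci,
    pgd_attack,
    profiles_from_perturbations,
    train_model,
)
from sfprobe.pipeline import DESK_SCALE

grid = build_frequency_grid(64, 64)
bands = OctaveBands.default(grid.nyquist_cpi)
attack = AttackConfig(epsilon=4 / 255, steps=10, seed=7)


def train_and_profile(band, label):
    spec = BandCodedDatasetSpec(informative_band=band, seed=100)
    ds = generate_band_coded_dataset(spec)
    tr_x, tr_y, te_x, te_y = ds.split(150)
    clf = make_fixture_classifier(seed=0)
    train_model(clf, tr_x, tr_y, DESK_SCALE, seed=0)
    acc = clf.accuracy(te_x, te_y)
    perts = filter_successful(pgd_attack(clf, te_x, te_y, attack))
    prof = mean_profile_with_ci(
        profiles_from_perturbations(perts, grid), n_boot=1000, seed=1
    )
    print(f"{label}: test accuracy {acc:.2f}, {len(perts)} successful perturbations")
    return prof


target = (8.0, 16.0)
model_prof = train_and_profile(target, "band-coded model  ")
base_prof = train_and_profile((1.0, 32.0), "broadband baseline")

stats = band_delta_auc(model_prof, base_prof, bands, model_id="band-8-16")
print(f"\n{'octave (cpi)':<14}{'model share':>12}{'baseline':>12}{'delta-AUC':>12}")
for i, label in enumerate(bands.labels):
    lo, hi = bands.edges_cpi[i], bands.edges_cpi[i + 1]
    m = model_prof.band_share(lo, hi)
    b = base_prof.band_share(lo, hi)
    mark = "  <-- informative band" if (lo, hi) == target else ""
    print(f"{label:<14}{m:>12.3f}{b:>12.3f}{stats.delta_auc_pct_power[i]:>+12.3f}{mark}")

best = stats.argmax_band()
print(
    f"\nLargest positive shift: {bands.labels[best]} "
    f"(delta {stats.delta_auc_pct_power[best]:+.3f}) — the probe recovered the "
    "octave that carries the class signal."
)
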