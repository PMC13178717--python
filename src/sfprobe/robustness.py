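"""Robust-accuracy curves over an epsilon grid and their AUC summary.

For each perturbation bound eps in the grid (default the seven thresholds
1/255 .. 7/255), fresh adversarial examples are generated at that eps and
top-1 accuracy is measured on the attacked set.  The curve is summarized by
its trapezoidal area over the eps axis (robust AUC, higher = more robust);
differences in robust AUC against an unguided baseline quantify improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attacks import AttackConfig, fgsm_attack, pgd_attack

__all__ = [
    "DEFAULT_EPS_GRID",
    "RobustnessCurve",
    "evaluate_robustness",
    "robust_auc",
    "relative_auc",
    "bootstrap_mean_ci",
]

#: The seven standard perturbation thresholds on the [0, 1] pixel scale.
DEFAULT_EPS_GRID = tuple(k / 255 for k in range(1, 8))


@dataclass(frozen=True)
class RobustnessCurve:
    epsilons: np.ndarray = field(repr=False)
    accuracies: np.ndarray = field(repr=False)
    clean_accuracy: float = float("nan")
    model_id: str = ""

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilons, dtype=float)
        if np.any(np.diff(eps) <= 0):
            raise ValueError("epsilons must be strictly increasing")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def auc(self) -> float:
        return robust_auc(self)


def evaluate_robustness(
    model,
    images: np.ndarray,
    labels: np.ndarray,
    eps_grid=DEFAULT_EPS_GRID,
    attack_config: AttackConfig | None = None,
    attack: str = "pgd",
    include_clean_anchor: bool = False,
    model_id: str = "",
) -> RobustnessCurve:
    """Top-1 accuracy under attack at each eps, from fresh attacks per eps.

    Evaluation images are never augmented.  ``include_clean_anchor``
    prepends an eps = 0 point equal to clean accuracy (off by default: the
    printed grid starts at 1/255).
    """
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    eps_grid = tuple(eps_grid)
    if not eps_grid:
        raise ValueError("eps grid must be nonempty")
    base = attack_config or AttackConfig()
    clean_acc = model.accuracy(images, labels)
    accs = []
    for eps in eps_grid:
        if attack == "pgd":
            perts = pgd_attack(model, images, labels, replace(base, epsilon=eps))
        elif attack == "fgsm":
            perts = fgsm_attack(model, images, labels, eps)
        else:
            raise ValueError(f"unknown attack {attack!r}")
        accs.append(np.mean([p.adv_label == p.true_label for p in perts]))
    eps_arr = np.asarray(eps_grid, dtype=float)
    acc_arr = np.asarray(accs, dtype=float)
    if include_clean_anchor:
        eps_arr = np.concatenate([[0.0], eps_arr])
        acc_arr = np.concatenate([[clean_acc], acc_arr])
    return RobustnessCurve(
        epsilons=eps_arr, accuracies=acc_arr, clean_accuracy=clean_acc, model_id=model_id
    )


def robust_auc(curve: RobustnessCurve, normalized: bool = False) -> float:
    """Trapezoidal area under the accuracy-vs-eps curve.

    Units are accuracy x eps on the pixel scale (a constant accuracy ``a``
    over [1/255, 7/255] gives ``a * 6/255``); ``normalized`` divides by the
    grid width so the value reads as a mean accuracy.
    """
    eps = np.asarray(curve.epsilons, dtype=float)
    if len(eps) < 2:
        raise ValueError("need at least 2 grid points for an AUC")
    area = float(np.trapezoid(curve.accuracies, eps))
    if normalized:
        area /= float(eps[-1] - eps[0])
    return area


def relative_auc(model_curve: RobustnessCurve, baseline_curve: RobustnessCurve) -> float:
    """auc(model) - auc(baseline); positive = more robust than baseline."""
    if not np.allclose(model_curve.epsilons, baseline_curve.epsilons):
        raise ValueError("robustness curves evaluated on different eps grids")
    return robust_auc(model_curve) - robust_auc(baseline_curve)


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float]:
    """Mean and percentile bootstrap 95% CI over e.g. training seeds."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), float(lo), float(hi)
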