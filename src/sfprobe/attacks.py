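"""Bounded white-box adversarial attacks: PGD (l-inf / l2) and FGSM.

An adversarial perturbation tau maximizes the classification loss subject
to a norm budget ``||tau||_p <= eps`` on the [0, 1] pixel scale, e.g.
eps = 4/255.  PGD starts from uniform random noise in the ball and ascends
the input gradient with projection back onto the ball (and the pixel range)
after every step; FGSM is the single-step sign-of-gradient special case.

Only perturbations that flip an originally *correct* prediction count as
successful: these are the ones retained for spectral analysis, so the
perturbation spectra reflect decision-relevant feature sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AttackConfig",
    "Perturbation",
    "pgd_attack",
    "fgsm_attack",
    "filter_successful",
    "save_perturbations",
    "load_perturbations",
]


@dataclass(frozen=True)
class AttackConfig:
    """Attack hyperparameters on the [0, 1] pixel scale.

    ``step_size=None`` uses eps/4 for l-inf and 2.5*eps/steps for l2
    (standard PGD practice; the source recipe leaves these open).
    """

    norm: str = "linf"
    epsilon: float = 4 / 255
    steps: int = 10
    step_size: float | None = None
    random_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.norm not in ("linf", "l2"):
            raise ValueError(f"norm must be 'linf' or 'l2', got {self.norm!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")

    @property
    def effective_step_size(self) -> float:
        if self.step_size is not None:
            return self.step_size
        if self.norm == "linf":
            return self.epsilon / 4.0
        return 2.5 * self.epsilon / self.steps


@dataclass(frozen=True)
class Perturbation:
    """A bounded additive image delta plus its attack bookkeeping."""

    delta: np.ndarray = field(repr=False)
    true_label: int
    clean_label: int  # model's prediction on the clean image
    adv_label: int  # model's prediction on the perturbed image
    epsilon: float
    norm: str
    success: bool  # clean prediction correct AND adversarial prediction wrong
    aborted: bool = False  # non-finite gradients encountered


def _project(delta: np.ndarray, norm: str, eps: float) -> np.ndarray:
    if norm == "linf":
        return np.clip(delta, -eps, eps)
    flat = delta.reshape(len(delta), -1)
    norms = np.linalg.norm(flat, axis=1)
    factor = np.minimum(1.0, eps / np.maximum(norms, 1e-30))
    return delta * factor[:, None, None, None]


def _ascent_direction(grad: np.ndarray, norm: str) -> np.ndarray:
    if norm == "linf":
        return np.sign(grad)  # sign(0) = 0
    flat = grad.reshape(len(grad), -1)
    norms = np.linalg.norm(flat, axis=1)
    return grad / np.maximum(norms, 1e-30)[:, None, None, None]


def _wrap_results(
    images: np.ndarray,
    x_adv: np.ndarray,
    labels: np.ndarray,
    clean_pred: np.ndarray,
    adv_pred: np.ndarray,
    config_eps: float,
    norm: str,
    aborted: np.ndarray,
) -> list[Perturbation]:
    out = []
    for i in range(len(images)):
        out.append(
            Perturbation(
                delta=x_adv[i] - images[i],
                true_label=int(labels[i]),
                clean_label=int(clean_pred[i]),
                adv_label=int(adv_pred[i]),
                epsilon=config_eps,
                norm=norm,
                success=bool(
                    clean_pred[i] == labels[i]
                    and adv_pred[i] != labels[i]
                    and not aborted[i]
                ),
                aborted=bool(aborted[i]),
            )
        )
    return out


def _as_batch(images: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, bool]:
    images = np.asarray(images, dtype=np.float64)
    single = images.ndim == 3
    if single:
        images = images[None]
    labels = np.atleast_1d(np.asarray(labels, dtype=int))
    return images, labels, single


def pgd_attack(model, images: np.ndarray, labels, config: AttackConfig):
    """Projected gradient descent on a batch (or a single HWC image).

    After every step the perturbation is projected onto the eps-ball and
    the perturbed image clipped to [0, 1], so the final delta respects
    both constraints.  Images whose gradient turns non-finite are aborted
    (their delta stays at the last valid iterate) and logged.

    Returns a list of :class:`Perturbation` (or a single one for a single
    input image).
    """
    images, labels, single = _as_batch(images, labels)
    eps = config.epsilon
    rng = np.random.default_rng(config.seed)
    clean_pred = model.predict(images)

    if config.random_init:
        delta = rng.uniform(-eps, eps, size=images.shape)
        if config.norm == "l2":
            delta = _project(delta, "l2", eps)
    else:
        delta = np.zeros_like(images)
    x_adv = np.clip(images + delta, 0.0, 1.0)
    aborted = np.zeros(len(images), dtype=bool)
    step = config.effective_step_size

    for _ in range(config.steps):
        _, grad = model.loss_and_input_grad(x_adv, labels)
        bad = ~np.isfinite(grad.reshape(len(grad), -1)).all(axis=1)
        if bad.any():
            newly = bad & ~aborted
            if newly.any():
                logger.warning(
                    "PGD aborted %d image(s) with non-finite gradients", int(newly.sum())
                )
            aborted |= bad
            grad = np.where(np.isfinite(grad), grad, 0.0)
        direction = _ascent_direction(grad, config.norm)
        live = (~aborted)[:, None, None, None]
        x_adv = x_adv + step * direction * live
        delta = _project(x_adv - images, config.norm, eps)
        x_adv = np.clip(images + delta, 0.0, 1.0)

    adv_pred = model.predict(x_adv)
    results = _wrap_results(
        images, x_adv, labels, clean_pred, adv_pred, eps, config.norm, aborted
    )
    return results[0] if single else results


def fgsm_attack(model, images: np.ndarray, labels, epsilon: float):
    """Fast gradient sign method: ``delta = eps * sign(dL/dx)``, then clip.

    Identical to one l-inf PGD step from a zero initialization with
    step size eps.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    images, labels, single = _as_batch(images, labels)
    clean_pred = model.predict(images)
    _, grad = model.loss_and_input_grad(images, labels)
    aborted = ~np.isfinite(grad.reshape(len(grad), -1)).all(axis=1)
    if aborted.any():
        logger.warning(
            "FGSM aborted %d image(s) with non-finite gradients", int(aborted.sum())
        )
        grad = np.where(np.isfinite(grad), grad, 0.0)
    x_adv = np.clip(images + epsilon * np.sign(grad), 0.0, 1.0)
    adv_pred = model.predict(x_adv)
    results = _wrap_results(
        images, x_adv, labels, clean_pred, adv_pred, epsilon, "linf", aborted
    )
    return results[0] if single else results


def filter_successful(perturbations: list[Perturbation]) -> list[Perturbation]:
    """Keep perturbations that changed an originally correct prediction."""
    return [p for p in perturbations if p.success]


def save_perturbations(perturbations: list[Perturbation], path) -> None:
    """NPZ archive: stacked delta arrays plus JSON-encoded metadata."""
    import json

    meta = [
        {
            "true_label": p.true_label,
            "clean_label": p.clean_label,
            "adv_label": p.adv_label,
            "epsilon": p.epsilon,
            "norm": p.norm,
            "success": p.success,
            "aborted": p.aborted,
        }
        for p in perturbations
    ]
    np.savez(
        path,
        deltas=np.stack([p.delta for p in perturbations]),
        metadata=np.array(json.dumps(meta)),
    )


def load_perturbations(path) -> list[Perturbation]:
    import json

    with np.load(path, allow_pickle=False) as npz:
        deltas = npz["deltas"]
        meta = json.loads(str(npz["metadata"]))
    return [Perturbation(delta=d, **m) for d, m in zip(deltas, meta)]
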