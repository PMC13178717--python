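"""Experiment orchestration: conditions, seeds, training, and reports.

Ties the pieces together: a named augmentation *condition* (which band is
spared from phase scrambling) plus a *strength* (the probability p that a
training image is replaced by its scrambled version: 0.3 weak, 0.5 strong)
defines the training-time policy; models are trained with SGD, attacked,
and summarized into robustness curves and SF reliance statistics.

Seed policy: one integer seed spawns independent named substreams for
model init, data order + augmentation draws, and attack init, so two
conditions run with the same seed share their weight initialization —
matched comparisons differ only in augmentation.

Frequency parameters are stated on the reference 224 x 224 geometry
(nyquist 112 cpi) and rescaled to the working grid: log-frequency centres
shift by log2(nyquist/112), blur kernel widths scale with image size so the
mask's response in cpi is preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .attacks import AttackConfig, filter_successful, pgd_attack
from .frequency import (
    FrequencyGrid,
    OctaveBands,
    SFMask,
    blur_magnitude_mask,
    extreme_lsf_mask,
    human_channel_mask,
    invert_mask,
    mixed_sigma_policy,
)
from .nn import Classifier, TrainingLog, sgd_train
from .reliance import (
    BandStats,
    SFProfile,
    band_delta_auc,
    mean_profile_with_ci,
    profiles_from_perturbations,
)
from .robustness import DEFAULT_EPS_GRID, RobustnessCurve, evaluate_robustness
from .scramble import AugmentationPolicy, apply_policy
from .synthetic import (
    BandCodedDatasetSpec,
    generate_band_coded_dataset,
    make_fixture_classifier,
)

__all__ = [
    "TrainingParams",
    "DESK_SCALE",
    "PAPER_SCALE",
    "ExperimentConfig",
    "CONDITIONS",
    "condition_policy",
    "seed_streams",
    "train_model",
    "run_experiment",
]

#: Reference geometry on which all frequency parameters are stated.
REFERENCE_NYQUIST = 112.0

CONDITIONS = (
    "baseline",
    "human_channel",
    "extreme_lsf",
    "fixed_sigma_lsf",
    "mixed_sigma_lsf",
    "combined_channel",
    "inverse_human",
    "inverse_extreme_lsf",
)

#: Replacement probability per bias strength.
STRENGTH_P = {"weak": 0.3, "strong": 0.5}


@dataclass(frozen=True)
class TrainingParams:
    """SGD recipe.  ``PAPER_SCALE`` is the full ImageNet-50/ResNet recipe
    (60 epochs, lr 0.1 decayed x0.1 at epoch 45, batch 1024, momentum 0.9,
    weight decay 1e-4, label smoothing 0.1); ``DESK_SCALE`` (the default)
    is a short schedule sized for the synthetic fixture task on one CPU."""

    epochs: int = 5
    lr: float = 0.02
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    label_smoothing: float = 0.1
    lr_decay_epochs: tuple[int, ...] = (4,)
    lr_decay_factor: float = 0.1


DESK_SCALE = TrainingParams()
PAPER_SCALE = TrainingParams(
    epochs=60,
    lr=0.1,
    momentum=0.9,
    weight_decay=1e-4,
    batch_size=1024,
    label_smoothing=0.1,
    lr_decay_epochs=(45,),
    lr_decay_factor=0.1,
)


def condition_policy(
    condition: str,
    grid: FrequencyGrid,
    strength: str = "weak",
    use_filter: bool = False,
) -> AugmentationPolicy | None:
    """Build the augmentation policy for a named condition on a grid.

    Returns None for the baseline (no augmentation).  For the mixed-sigma
    mixture, the per-mask probabilities from the printed tables *are* the
    replacement probabilities (residual mass leaves the image unmodified),
    and kernel widths are rescaled to the working resolution.
    """
    if condition == "baseline":
        return None
    if strength not in STRENGTH_P:
        raise ValueError(f"strength must be one of {sorted(STRENGTH_P)}")
    p = STRENGTH_P[strength]
    scale = grid.nyquist_cpi / REFERENCE_NYQUIST
    mu_shift = float(np.log2(scale))
    px_scale = min(grid.height, grid.width) / 224.0

    def human() -> SFMask:
        return human_channel_mask(grid, mu_octaves=4.5 + mu_shift)

    def extreme() -> SFMask:
        from .frequency import EXTREME_LSF_MU

        return extreme_lsf_mask(grid, mu_octaves=EXTREME_LSF_MU + mu_shift)

    if condition == "human_channel":
        masks: tuple[SFMask, ...] = (human(),)
    elif condition == "extreme_lsf":
        masks = (extreme(),)
    elif condition == "fixed_sigma_lsf":
        masks = (blur_magnitude_mask(grid, 1.5 * px_scale),)
    elif condition == "mixed_sigma_lsf":
        mixture = mixed_sigma_policy(strength)
        sigmas = tuple(s * px_scale for s in mixture.sigmas)
        masks = tuple(
            blur_magnitude_mask(grid, s, condition="mixed_sigma_lsf") for s in sigmas
        )
        return AugmentationPolicy(
            masks=masks,
            mask_probs=mixture.probabilities,
            mixture_mode=True,
            use_filter=use_filter,
        )
    elif condition == "combined_channel":
        return AugmentationPolicy(
            masks=(human(), extreme()),
            replace_prob=p,
            mask_probs=(0.5, 0.5),
            use_filter=use_filter,
        )
    elif condition == "inverse_human":
        masks = (invert_mask(human()),)
    elif condition == "inverse_extreme_lsf":
        masks = (invert_mask(extreme()),)
    else:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return AugmentationPolicy(masks=masks, replace_prob=p, use_filter=use_filter)


def seed_streams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent substreams: init, data (order + augmentation), attack."""
    root = np.random.SeedSequence(seed)
    init_ss, data_ss, attack_ss = root.spawn(3)
    return {
        "init": np.random.default_rng(init_ss),
        "data": np.random.default_rng(data_ss),
        "attack": np.random.default_rng(attack_ss),
    }


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a run needs; serializable to/from YAML."""

    conditions: tuple[str, ...] = ("baseline", "human_channel")
    strength: str = "weak"
    use_filter: bool = False
    n_seeds: int = 1
    dataset: BandCodedDatasetSpec = field(default_factory=BandCodedDatasetSpec)
    n_train_per_class: int = 150
    training: TrainingParams = field(default_factory=TrainingParams)
    attack: AttackConfig = field(default_factory=AttackConfig)
    eps_grid: tuple[float, ...] = DEFAULT_EPS_GRID
    n_boot: int = 10_000
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        raw["dataset"] = BandCodedDatasetSpec(
            **{
                **raw.get("dataset", {}),
                "informative_band": tuple(raw["dataset"]["informative_band"]),
            }
        )
        raw["training"] = TrainingParams(
            **{
                **raw.get("training", {}),
                "lr_decay_epochs": tuple(raw["training"]["lr_decay_epochs"]),
            }
        )
        raw["attack"] = AttackConfig(**raw["attack"])
        for key in ("conditions", "eps_grid"):
            raw[key] = tuple(raw[key])
        return cls(**raw)


def train_model(
    clf: Classifier,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    params: TrainingParams,
    seed: int = 0,
    policy: AugmentationPolicy | None = None,
    val_images: np.ndarray | None = None,
    val_labels: np.ndarray | None = None,
) -> TrainingLog:
    """Train a classifier with an (optional) scrambling policy on the
    training stream only; evaluation data is never augmented.

    With ``policy=None`` the augmentation path is a strict no-op, so a
    p = 0 policy and the baseline recipe yield identical weights for the
    same seed.
    """
    streams = seed_streams(seed)
    augment_fn = None
    if policy is not None:
        def augment_fn(batch, rng):  # noqa: E306
            return apply_policy(batch, policy, rng)

    clf.label_smoothing = params.label_smoothing
    return sgd_train(
        clf,
        train_images,
        train_labels,
        epochs=params.epochs,
        lr=params.lr,
        momentum=params.momentum,
        weight_decay=params.weight_decay,
        batch_size=params.batch_size,
        lr_decay_epochs=params.lr_decay_epochs,
        lr_decay_factor=params.lr_decay_factor,
        rng=streams["data"],
        augment_fn=augment_fn,
        val_images=val_images,
        val_labels=val_labels,
    )


@dataclass
class ConditionResult:
    condition: str
    seed: int
    clean_accuracy: float
    curve: RobustnessCurve
    n_successful: int
    mean_profile: SFProfile | None
    log: TrainingLog


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    results: list[ConditionResult]
    band_stats: list[BandStats]
    config_hash: str


def _train_one(
    config: ExperimentConfig, condition: str, seed: int, data_split
) -> tuple[Classifier, TrainingLog]:
    tr_x, tr_y, te_x, te_y = data_split
    size = config.dataset.image_size
    grid = _grid_for(config)
    streams = seed_streams(seed)
    # init stream is shared across conditions at equal seed
    init_seed = int(streams["init"].integers(2**31))
    clf = make_fixture_classifier(
        image_size=size, n_classes=config.dataset.n_classes, seed=init_seed
    )
    policy = condition_policy(
        condition, grid, strength=config.strength, use_filter=config.use_filter
    )
    log = train_model(
        clf, tr_x, tr_y, config.training, seed=seed, policy=policy,
        val_images=te_x, val_labels=te_y,
    )
    return clf, log


def _grid_for(config: ExperimentConfig) -> FrequencyGrid:
    from .frequency import build_frequency_grid

    size = config.dataset.image_size
    return build_frequency_grid(size, size)


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Train -> attack -> robustness curve -> SF profile for every
    (condition, seed); band delta-AUC is computed against the baseline
    profile at the same seed (the baseline condition is added if absent).

    With ``config.out_dir`` set, per-model CSV/JSON artifacts tagged with
    the config hash are written and reused on reruns (stage-level resume);
    differing results under the same hash are never silently overwritten.
    """
    conditions = config.conditions
    if "baseline" not in conditions:
        conditions = ("baseline",) + conditions
    dataset = generate_band_coded_dataset(config.dataset)
    split = dataset.split(config.n_train_per_class)
    _, _, te_x, te_y = split
    grid = _grid_for(config)
    bands = OctaveBands.default(grid.nyquist_cpi)
    cfg_hash = config.hash()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / f"config-{cfg_hash}.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=str)
        )

    results: list[ConditionResult] = []
    profiles: dict[tuple[str, int], SFProfile] = {}
    for condition in conditions:
        for seed in range(config.n_seeds):
            cached = _load_stage(out_dir, cfg_hash, condition, seed)
            if cached is not None:
                results.append(cached)
                if cached.mean_profile is not None:
                    profiles[(condition, seed)] = cached.mean_profile
                continue
            clf, log = _train_one(config, condition, seed, split)
            streams = seed_streams(seed)
            attack_seed = int(streams["attack"].integers(2**31))
            atk = replace(config.attack, seed=attack_seed)
            curve = evaluate_robustness(
                clf, te_x, te_y, eps_grid=config.eps_grid, attack_config=atk,
                model_id=f"{condition}-s{seed}",
            )
            perts = filter_successful(pgd_attack(clf, te_x, te_y, atk))
            mean_prof = None
            if len(perts) >= 2:
                mean_prof = mean_profile_with_ci(
                    profiles_from_perturbations(perts, grid),
                    n_boot=config.n_boot,
                    seed=streams["attack"],
                )
                profiles[(condition, seed)] = mean_prof
            res = ConditionResult(
                condition=condition,
                seed=seed,
                clean_accuracy=curve.clean_accuracy,
                curve=curve,
                n_successful=len(perts),
                mean_profile=mean_prof,
                log=log,
            )
            results.append(res)
            _save_stage(out_dir, cfg_hash, res)

    band_stats = []
    for (condition, seed), prof in profiles.items():
        if condition == "baseline":
            continue
        base = profiles.get(("baseline", seed))
        if base is None:
            continue
        band_stats.append(
            band_delta_auc(prof, base, bands, model_id=f"{condition}-s{seed}")
        )
    report = ExperimentReport(
        config=config, results=results, band_stats=band_stats, config_hash=cfg_hash
    )
    if out_dir:
        _write_report_tables(out_dir, report)
    return report


# ---------------------------------------------------------------------------
# on-disk artifacts


def _stage_path(out_dir: Path | None, cfg_hash: str, condition: str, seed: int):
    if out_dir is None:
        return None
    return out_dir / f"{cfg_hash}-{condition}-s{seed}.json"


def _save_stage(out_dir: Path | None, cfg_hash: str, res: ConditionResult) -> None:
    path = _stage_path(out_dir, cfg_hash, res.condition, res.seed)
    if path is None:
        return
    payload = {
        "config_hash": cfg_hash,
        "condition": res.condition,
        "seed": res.seed,
        "clean_accuracy": res.clean_accuracy,
        "epsilons": res.curve.epsilons.tolist(),
        "accuracies": res.curve.accuracies.tolist(),
        "n_successful": res.n_successful,
        "profile": None
        if res.mean_profile is None
        else {
            "bin_centers_cpi": res.mean_profile.bin_centers_cpi.tolist(),
            "proportions": res.mean_profile.proportions.tolist(),
            "ci_low": res.mean_profile.ci_low.tolist(),
            "ci_high": res.mean_profile.ci_high.tolist(),
            "n_perturbations": res.mean_profile.n_perturbations,
        },
        "val_acc": res.log.val_acc,
    }
    path.write_text(json.dumps(payload))


def _load_stage(
    out_dir: Path | None, cfg_hash: str, condition: str, seed: int
) -> ConditionResult | None:
    path = _stage_path(out_dir, cfg_hash, condition, seed)
    if path is None or not path.exists():
        return None
    raw = json.loads(path.read_text())
    if raw.get("config_hash") != cfg_hash:
        raise RuntimeError(
            f"artifact {path} carries a different config hash; refusing to reuse"
        )
    prof = None
    if raw["profile"] is not None:
        p = raw["profile"]
        prof = SFProfile(
            bin_centers_cpi=np.asarray(p["bin_centers_cpi"]),
            proportions=np.asarray(p["proportions"]),
            n_perturbations=p["n_perturbations"],
            ci_low=np.asarray(p["ci_low"]),
            ci_high=np.asarray(p["ci_high"]),
        )
    curve = RobustnessCurve(
        epsilons=np.asarray(raw["epsilons"]),
        accuracies=np.asarray(raw["accuracies"]),
        clean_accuracy=raw["clean_accuracy"],
        model_id=f"{condition}-s{seed}",
    )
    log = TrainingLog(val_acc=raw.get("val_acc", []))
    return ConditionResult(
        condition=condition,
        seed=seed,
        clean_accuracy=raw["clean_accuracy"],
        curve=curve,
        n_successful=raw["n_successful"],
        mean_profile=prof,
        log=log,
    )


def _write_report_tables(out_dir: Path, report: ExperimentReport) -> None:
    import pandas as pd

    rows = [
        {
            "condition": r.condition,
            "seed": r.seed,
            "epsilon": float(e),
            "accuracy": float(a),
        }
        for r in report.results
        for e, a in zip(r.curve.epsilons, r.curve.accuracies)
    ]
    pd.DataFrame(rows).to_csv(
        out_dir / f"robustness-{report.config_hash}.csv", index=False
    )
    band_rows = [
        {
            "model_id": b.model_id,
            "band": b.bands.labels[i],
            "delta_auc_pct_power": float(b.delta_auc_pct_power[i]),
        }
        for b in report.band_stats
        for i in range(b.bands.n_bands)
    ]
    pd.DataFrame(band_rows).to_csv(
        out_dir / f"band-stats-{report.config_hash}.csv", index=False
    )
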