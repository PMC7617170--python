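"""Training orchestration: simulation-as-augmentation batches, the
validation metric, and early stopping.

The eight ablation variants (Baseline, Phys-Base, Aug, Strat, Phys-Strat,
Phys-Aug, Strat-Aug, Phys-Strat-Aug) are pure flag combinations of
``TrainConfig``: ``physics`` (conditioning branch on/off), ``strat``
(stratification loss on/off), and ``pregenerated`` (a fixed fan of
contrasts prepared in advance versus on-demand parameter sampling).

The validation metric combines segmentation quality (Dice against the
PGS) and acquisition invariance (volumetric coefficient of variation
across a fan of contrasts): mean over the three tissues of (Dice - CoV),
maximised.  Training stops after ``patience`` epochs without improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentationConfig, apply_spatial_augs, build_batch
from .labels import SoftLabelMap, hard_labels
from .losses import heteroscedastic_loss, total_loss
from .metrics import cov, dice
from .nn.unet import NetworkConfig, PhysicsUNet3D, build_network, softmax_probs
from .phantom import MPMVolume, TISSUE_CLASSES
from .simulate import ParamRanges, physics_vector, sample_params, simulate

__all__ = ["TrainConfig", "validation_metric", "train"]


@dataclass
class TrainConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    ranges: ParamRanges = field(default_factory=ParamRanges.mprage_training)
    batch_size: int = 4
    patch_size: int = 128
    physics: bool = True
    strat: bool = True
    strat_weight: float = 1.0
    heteroscedastic: bool = False
    het_T: int = 10
    #: on-demand simulation ("augmentation") vs a pre-generated contrast fan
    pregenerated: bool = False
    n_pregenerated: int = 121
    augmentation: AugmentationConfig | None = None
    lr: float = 1e-3
    iterations_per_epoch: int = 150
    max_epochs: int = 100
    max_iterations: int | None = None
    patience: int = 7
    #: contrasts per validation subject for the CoV part of the metric
    validation_fan: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.patch_size % 2**self.network.n_levels:
            raise ValueError(
                "patch size must be divisible by 2**n_levels "
                f"({2**self.network.n_levels})"
            )
        self.network.physics_len = (
            (4 if self.ranges.sequence == "mprage" else 6) if self.physics else None
        )
        self.network.heteroscedastic = self.heteroscedastic

    @classmethod
    def smoke(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: 24-cube patches, 2-level, 8-channel network."""
        kw = dict(
            network=NetworkConfig.smoke(),
            patch_size=24,
            iterations_per_epoch=50,
            max_epochs=6,
            validation_fan=5,
        )
        kw.update(overrides)
        return cls(**kw)


def validation_metric(dice_per_tissue: dict, cov_per_tissue: dict) -> float:
    """Mean over CSF/GM/WM of (Dice - CoV); larger is better."""
    vals = [
        dice_per_tissue[c] - cov_per_tissue[c] for c in TISSUE_CLASSES
    ]
    return float(np.mean(vals))


def _pregenerate_params(ranges: ParamRanges, n: int, rng: np.random.Generator):
    """The fixed contrast fan used by pre-generated-data training.

    MPRAGE: equally spaced TIs over the range (pTD mid-range); SPGR:
    random draws over the box.
    """
    if ranges.sequence == "mprage":
        tis = np.linspace(*ranges.ti_ms, n)
        ptd_mid = float(np.mean(ranges.ptd_ms))
        from .simulate import MPRAGEParams

        return [
            MPRAGEParams(ti=ti / 1000.0, ptd=ptd_mid / 1000.0, gs=ranges.gs)
            for ti in tis
        ]
    return [sample_params(ranges, rng) for _ in range(n)]


def evaluate_fan(
    net: PhysicsUNet3D,
    mpm: MPMVolume,
    labels: SoftLabelMap,
    params_fan,
    patch_size: int | None = None,
) -> tuple[dict, dict, dict]:
    """Dice (mean over the fan, vs PGS hard labels) and volume CoV per
    tissue for one subject across a fan of contrasts.

    Returns ``(dice_per_tissue, cov_per_tissue, volumes)`` where
    ``volumes[tissue]`` lists the soft class volume per contrast.
    """
    truth_hard = hard_labels(labels)
    dices = {c: [] for c in TISSUE_CLASSES}
    vols = {c: [] for c in TISSUE_CLASSES}
    for p in params_fan:
        img = simulate(mpm, p)
        pv = physics_vector(p).as_array()[None] if net.config.physics_len else None
        out = net.forward(img.intensities[None, None], pv, mode="eval")
        probs = softmax_probs(out.logits)[0]  # (4, D, H, W)
        pred_hard = np.argmax(probs, axis=0)
        d = dice(pred_hard, truth_hard, n_classes=4)
        for i, c in enumerate(TISSUE_CLASSES):
            dices[c].append(d[i])
            vols[c].append(float(probs[i].sum()))
    dice_t = {c: float(np.mean(dices[c])) for c in TISSUE_CLASSES}
    cov_t = {c: cov(vols[c]) for c in TISSUE_CLASSES}
    return dice_t, cov_t, vols


def train(train_subjects, val_subjects, config: TrainConfig):
    """Train a network on (MPMVolume, SoftLabelMap) subject pairs.

    Returns ``(network, history)``; ``history`` is a list of per-epoch
    dicts with losses and the validation metric.  Fully deterministic for
    a fixed config seed (single-threaded numpy).
    """
    if not train_subjects or not val_subjects:
        raise ValueError("need at least one training and one validation subject")
    rng = np.random.default_rng(config.seed)
    net = build_network(config.network)
    opt = net.optimizer(lr=config.lr)

    params_list = (
        _pregenerate_params(config.ranges, config.n_pregenerated, rng)
        if config.pregenerated
        else None
    )
    val_fans = [
        _pregenerate_params(config.ranges, config.validation_fan, rng)
        for _ in val_subjects
    ]

    history = []
    best_metric, best_state, since_best = -np.inf, None, 0
    total_iters = 0
    for epoch in range(config.max_epochs):
        losses = []
        for _ in range(config.iterations_per_epoch):
            if config.max_iterations and total_iters >= config.max_iterations:
                break
            mpm, labels = train_subjects[int(rng.integers(len(train_subjects)))]
            batch = build_batch(
                mpm, labels, config.ranges, config.batch_size,
                config.patch_size, rng, params_list=params_list,
            )
            if config.augmentation is not None:
                batch = apply_spatial_augs(batch, rng, config.augmentation)
            phys = batch.physics if config.physics else None
            out = net.forward(
                batch.images[:, None], phys, mode="train", rng=rng
            )
            lab = np.broadcast_to(
                batch.labels.responsibilities[None],
                out.logits.shape,
            )
            if config.heteroscedastic:
                loss = heteroscedastic_loss(
                    out.logits, out.sigma, lab, T=config.het_T, rng=rng
                )
                parts = {"total": float(loss.data)}
                if config.strat:
                    from .losses import stratification_loss

                    strat = stratification_loss(out.penultimate_features)
                    parts["stratification"] = float(strat.data)
                    loss = loss + strat * config.strat_weight
                    parts["total"] = float(loss.data)
            else:
                feats = out.penultimate_features if config.strat else None
                loss, parts = total_loss(
                    out.logits, lab, features=feats,
                    strat_weight=config.strat_weight,
                )
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {parts}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(parts)
            total_iters += 1

        # validation
        metrics = []
        for (mpm, labels), fan in zip(val_subjects, val_fans):
            d, c, _ = evaluate_fan(net, mpm, labels, fan)
            metrics.append(validation_metric(d, c))
        vm = float(np.mean(metrics))
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean([p["total"] for p in losses])) if losses else None,
                "val_metric": vm,
                "iterations": total_iters,
            }
        )
        if vm > best_metric:
            best_metric, since_best = vm, 0
            best_state = [a.copy() for a in net.state_arrays()]
        else:
            since_best += 1
            if since_best >= config.patience:
                break
        if config.max_iterations and total_iters >= config.max_iterations:
            break

    if best_state is not None:
        net.load_state_arrays(best_state)
    return net, history
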