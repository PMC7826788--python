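"""Training loop and cross-validated evaluation.

The optimization regimen: stochastic gradient descent (momentum 0.9) on
a mean-squared-error loss between the sigmoid probability map and the
binary mask, mini-batches of 4, initial learning rate 0.01 divided by
10 whenever the validation Dice stops improving, early stopping, an
iteration budget of 10,000 optimizer steps, reduction ratio 0.5 in the
channel-attention MLPs, and no data augmentation. Evaluation applies
the full pipeline per image — preprocess, predict, binarize, keep the
two largest components, confusion counts — and reports per-image and
macro-averaged Dice/sensitivity/PPV; the ablation runner repeats this
over placement configurations and folds and tabulates mean ± std.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, DimensionError, TrainingDivergenceError, ValidationError
from .imageops import binarize, keep_largest_components, preprocess, read_gray_png, read_mask_png, resize_mask
from .layers import SGD
from .metrics import MetricsResult, aggregate, confusion, eq_metrics, format_mean_std
from .network import AttentionUNet, NetworkSpec, build_network, load_checkpoint, parse_placement, predict
from .phantom import SplitPlan, make_splits

__all__ = [
    "TrainConfig",
    "TrainState",
    "TrainResult",
    "EvalResult",
    "mse_loss",
    "plateau_schedule",
    "train",
    "evaluate",
    "run_ablation",
]


@dataclass
class TrainConfig:
    """Hyperparameters; the defaults are the regimen stated above."""

    batch_size: int = 4
    initial_lr: float = 0.01
    lr_decay_factor: float = 10.0
    plateau_patience: int = 5       # evaluations without improvement before decay
    early_stop_patience: int = 15   # evaluations without improvement before stopping
    max_iterations: int = 10_000
    eval_interval: int = 50         # iterations between validation evaluations
    seed: int = 0
    reduction_ratio: float = 0.5
    augmentation: bool = False      # deliberately off; kept explicit
    momentum: float = 0.9
    weight_decay: float = 0.0
    input_size: tuple[int, int] = (64, 64)
    threshold: float = 0.5
    keep_components: int = 2

    def __post_init__(self):
        for name in ("batch_size", "initial_lr", "lr_decay_factor", "plateau_patience",
                     "early_stop_patience", "max_iterations", "eval_interval"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.augmentation:
            raise ConfigError("data augmentation is not part of the training regimen")


@dataclass
class TrainState:
    iteration: int = 0
    lr: float = 0.01
    best_val_dice: float = -np.inf
    evals_since_improve: int = 0
    checkpoint_path: str | None = None


@dataclass
class TrainResult:
    state: TrainState
    best_weights: dict
    history: list
    log: list
    spec: NetworkSpec


@dataclass
class EvalResult:
    per_image: dict            # id -> MetricsResult
    macro: MetricsResult       # equal-weight mean over images
    pooled: MetricsResult      # metrics of the summed confusion counts


def mse_loss(prob: np.ndarray, truth: np.ndarray) -> float:
    """Mean over pixels of (prob - truth)^2."""
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prob.shape != truth.shape:
        raise DimensionError(f"shape mismatch: {prob.shape} vs {truth.shape}")
    d = prob - truth
    return float((d * d).mean())


def plateau_schedule(
    history,
    state: TrainState | None = None,
    patience: int = 5,
    decay_factor: float = 10.0,
    initial_lr: float = 0.01,
) -> float:
    """Learning rate implied by a validation-Dice history.

    The rate is divided by ``decay_factor`` whenever ``patience``
    consecutive evaluations pass without a strict improvement of the
    best Dice; the decay counter resets after each decay. The function is
    a pure recomputation from the history, so it can be called at any
    point of training; if a ``state`` is given its ``lr`` and counters
    are updated in place.  ``state.evals_since_improve`` counts
    evaluations since the last strict improvement and is *not* reset by
    decays — it is the early-stopping counter.
    """
    if len(history) == 0:
        raise ValidationError("history must be non-empty")
    lr = initial_lr
    best = -np.inf
    since_decay = 0
    since_best = 0
    for v in history:
        if v > best:
            best, since_decay, since_best = v, 0, 0
        else:
            since_best += 1
            since_decay += 1
            if since_decay >= patience:
                lr /= decay_factor
                since_decay = 0
    if state is not None:
        state.lr = lr
        state.best_val_dice = best
        state.evals_since_improve = since_best
    return lr


def _load_pair(manifest: pd.DataFrame, image_id, size) -> tuple[np.ndarray, np.ndarray]:
    row = manifest.loc[manifest["id"] == image_id]
    if row.empty:
        raise ValidationError(f"id {image_id!r} not present in manifest")
    row = row.iloc[0]
    img = preprocess(read_gray_png(row["image_path"]), size).astype(np.float64) / 255.0
    mask = resize_mask(read_mask_png(row["mask_path"]), size)
    return img, mask


def _validation_dice(net: AttentionUNet, images, masks, threshold: float) -> float:
    """Mean per-image Dice of thresholded predictions (no component filtering)."""
    dices = []
    for img, mask in zip(images, masks):
        pred = binarize(predict(net, img), threshold)
        dices.append(eq_metrics(confusion(pred, mask)).dice)
    return float(np.mean(dices))


def train(
    net: AttentionUNet,
    manifest: pd.DataFrame,
    split: SplitPlan,
    cfg: TrainConfig,
    checkpoint_path=None,
) -> TrainResult:
    """Run the SGD regimen on one split; keeps the best-validation weights.

    With an empty validation list the full iteration budget is spent and
    the final weights are kept (useful for overfitting smoke runs).
    Raises :class:`TrainingDivergenceError` on a non-finite loss.
    """
    size = tuple(net.spec.input_size)
    rng = np.random.default_rng(cfg.seed)
    train_imgs, train_masks = [], []
    for i in split.train:
        img, mask = _load_pair(manifest, i, size)
        train_imgs.append(img)
        train_masks.append(mask)
    val_imgs, val_masks = [], []
    for i in split.val:
        img, mask = _load_pair(manifest, i, size)
        val_imgs.append(img)
        val_masks.append(mask)

    opt = SGD(net.parameters(), lr=cfg.initial_lr, momentum=cfg.momentum,
              weight_decay=cfg.weight_decay)
    state = TrainState(lr=cfg.initial_lr)
    history: list[float] = []
    log: list[str] = []
    best_weights = copy.deepcopy(net.state_dict())
    pool: list[int] = []
    n_train = len(train_imgs)
    stop = False

    while state.iteration < cfg.max_iterations and not stop:
        if len(pool) < cfg.batch_size:
            pool.extend(rng.permutation(n_train).tolist())
        idx = [pool.pop(0) for _ in range(cfg.batch_size)]
        xb = np.stack([train_imgs[j] for j in idx])[:, None]
        yb = np.stack([train_masks[j] for j in idx])[:, None].astype(np.float64)
        net.train()
        out = net(Tensor(xb))
        loss = ad.mse(out, yb)
        if not np.isfinite(loss.data):
            raise TrainingDivergenceError(state.iteration)
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.iteration += 1

        if val_imgs and state.iteration % cfg.eval_interval == 0:
            vd = _validation_dice(net, val_imgs, val_masks, cfg.threshold)
            history.append(vd)
            if vd > state.best_val_dice:
                best_weights = copy.deepcopy(net.state_dict())
            new_lr = plateau_schedule(
                history, state, patience=cfg.plateau_patience,
                decay_factor=cfg.lr_decay_factor, initial_lr=cfg.initial_lr,
            )
            opt.lr = new_lr
            log.append(
                f"iter={state.iteration} loss={float(loss.data):.5f} "
                f"lr={new_lr:g} val_dice={vd:.4f}"
            )
            if state.evals_since_improve >= cfg.early_stop_patience:
                log.append(f"iter={state.iteration} early_stop")
                stop = True
        elif state.iteration % cfg.eval_interval == 0:
            log.append(f"iter={state.iteration} loss={float(loss.data):.5f} lr={opt.lr:g}")

    if not val_imgs:
        best_weights = copy.deepcopy(net.state_dict())
    net.load_state_dict(best_weights)
    if checkpoint_path is not None:
        from .network import save_checkpoint

        save_checkpoint(checkpoint_path, net)
        state.checkpoint_path = str(checkpoint_path)
    return TrainResult(state=state, best_weights=best_weights, history=history,
                       log=log, spec=net.spec)


def evaluate(
    net_or_checkpoint,
    manifest: pd.DataFrame,
    ids,
    threshold: float = 0.5,
    keep_components: int = 2,
    connectivity: int = 2,
) -> EvalResult:
    """Full per-image pipeline: preprocess, predict, binarize, keep the
    largest components, count, score."""
    if isinstance(net_or_checkpoint, AttentionUNet):
        net = net_or_checkpoint
    else:
        net = load_checkpoint(net_or_checkpoint)
    size = tuple(net.spec.input_size)
    per_image: dict = {}
    total = None
    for i in ids:
        img, mask = _load_pair(manifest, i, size)
        pred = binarize(predict(net, img), threshold)
        if keep_components:
            pred = keep_largest_components(pred, keep_components, connectivity)
        c = confusion(pred, mask)
        per_image[i] = eq_metrics(c)
        total = c if total is None else type(c)(
            total.tp + c.tp, total.fp + c.fp, total.fn + c.fn, total.tn + c.tn
        )
    if total is None:
        raise ValidationError("no ids to evaluate")
    vals = list(per_image.values())
    macro = MetricsResult(
        dice=float(np.mean([v.dice for v in vals])),
        sensitivity=float(np.mean([v.sensitivity for v in vals])),
        ppv=float(np.mean([v.ppv for v in vals])),
    )
    return EvalResult(per_image=per_image, macro=macro, pooled=eq_metrics(total))


def run_ablation(
    manifest: pd.DataFrame,
    labels,
    cfg: TrainConfig,
    encoder_spec: NetworkSpec | None = None,
    n_folds: int = 5,
    split_seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated comparison of attention placements.

    For each placement label: parse, then for each of ``n_folds`` split
    plans build a freshly seeded network, train it and evaluate on the
    fold's test ids; aggregate mean ± std per metric. Returns one row
    per configuration with raw and Table-style formatted columns.
    """
    if not labels:
        raise ValidationError("at least one configuration label is required")
    base = encoder_spec if encoder_spec is not None else NetworkSpec(input_size=cfg.input_size)
    plans = make_splits(list(manifest["id"]), seed=split_seed)[:n_folds]
    rows = []
    for label in labels:
        placement = parse_placement(label)
        fold_results: list[MetricsResult] = []
        for plan in plans:
            spec = replace(base, placement=placement)
            net = build_network(spec, seed=cfg.seed + plan.fold)
            fold_cfg = replace(cfg, seed=cfg.seed + plan.fold)
            train(net, manifest, plan, fold_cfg)
            res = evaluate(net, manifest, plan.test, threshold=cfg.threshold,
                           keep_components=cfg.keep_components)
            fold_results.append(res.macro)
        agg = aggregate(fold_results)
        row = {"configuration": placement.label()}
        for metric in ("dice", "sensitivity", "ppv"):
            mean, std = agg[metric]
            row[f"{metric}_mean"] = mean
            row[f"{metric}_std"] = std
            row[metric] = format_mean_std(mean, std)
        rows.append(row)
    return pd.DataFrame(rows)
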