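"""Per-plane 2D segmentation model: training protocol, subject-level
cross-validation splitting, paired augmentation, inference and fine-tuning.

The training protocol follows the standard recipe for this problem: Adam,
50 epochs, learning rate 1e-4, batch size 16, augmentation with random
horizontal/vertical flips, rotations up to 10 degrees and shifts up to 10% of
the image extent, and subject-level 5-fold cross-validation with 3:1:1
train/validation/test splits so that no subject's slices leak across sets.
Model selection keeps the epoch with the highest validation DSC.

A reduced "desk" configuration (:func:`desk_config`) trains the same network
from scratch at 64x64 resolution in minutes on one CPU; see docs/methods.md
for the rationale behind its settings.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import Adam, UNet2D, bce_dice_loss_and_grad, dice_loss_and_grad
from .errors import ConsistencyError
from .preprocess import SliceStack

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "FoldSplit",
    "PlaneModel",
    "desk_config",
    "make_folds",
    "sample_augment_params",
    "augment_pair",
    "train",
    "predict_slices",
    "fine_tune",
    "save_model",
    "load_model",
]


@dataclass
class AugmentConfig:
    hflip: bool = True
    vflip: bool = True
    max_rotation_deg: float = 10.0
    max_shift_frac: float = 0.10

    @property
    def enabled(self) -> bool:
        return self.hflip or self.vflip or self.max_rotation_deg > 0 or self.max_shift_frac > 0


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the full protocol."""

    epochs: int = 50
    learning_rate: float = 1e-4
    batch_size: int = 16
    augmentation: AugmentConfig = field(default_factory=AugmentConfig)
    encoder_depth: int = 3
    base_channels: int = 8
    pretrained_encoder: bool = False
    loss_name: str = "dice"  # "dice" | "bce_dice"
    seed: int = 0
    binarization_threshold: float = 0.5
    resolution: int = 256

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.encoder_depth < 1:
            raise ValueError("counts must be >= 1 (epochs >= 0)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 <= self.augmentation.max_shift_frac <= 0.5:
            raise ValueError("max_shift_frac must lie in [0, 0.5]")
        if not 0 < self.binarization_threshold < 1:
            raise ValueError("binarization threshold must lie in (0, 1)")
        if self.loss_name not in ("dice", "bce_dice"):
            raise ValueError(f"unknown loss {self.loss_name!r}")
        if self.pretrained_encoder:
            raise ValueError(
                "no pretrained encoder weights are bundled; train from scratch "
                "(pretrained_encoder=False) or warm-start via fine_tune()"
            )


def desk_config(seed: int = 0, epochs: int = 10) -> TrainConfig:
    """CPU-scale configuration: 64x64 slices, depth-2 net, lr 1e-3."""
    return TrainConfig(
        epochs=epochs,
        learning_rate=1e-3,
        encoder_depth=2,
        base_channels=8,
        resolution=64,
        seed=seed,
    )


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ConsistencyError(
                f"fold {self.fold_id}: train/val/test sets overlap"
            )


@dataclass
class PlaneModel:
    """A trained per-plane segmenter: plane name, network state, config, history."""

    plane: str
    net: UNet2D
    config: TrainConfig
    history: list[dict] = field(default_factory=list)


def make_folds(subject_ids, k: int, seed: int = 0) -> list[FoldSplit]:
    """Subject-level k-fold splits with a 3:1:1 train/val/test ratio.

    The k test sets partition the cohort, so every subject is held out for
    testing exactly once; within each fold the validation set is the next
    fold's test group and the remaining subjects train.  Deterministic from
    ``seed``.
    """
    ids = sorted(set(subject_ids))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} folds but only {len(ids)} subjects")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    groups = [perm[i::k] for i in range(k)]
    folds = []
    for f in range(k):
        test = tuple(sorted(groups[f]))
        val = tuple(sorted(groups[(f + 1) % k]))
        train_ids = tuple(
            sorted(x for g in range(k) if g not in (f, (f + 1) % k) for x in groups[g])
        )
        folds.append(FoldSplit(fold_id=f, train_ids=train_ids, val_ids=val, test_ids=test))
    return folds


def sample_augment_params(aug: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw one augmentation parameter set (shared by image and mask)."""
    return {
        "hflip": bool(aug.hflip and rng.random() < 0.5),
        "vflip": bool(aug.vflip and rng.random() < 0.5),
        "angle_deg": float(rng.uniform(-aug.max_rotation_deg, aug.max_rotation_deg))
        if aug.max_rotation_deg > 0
        else 0.0,
        "shift_frac": tuple(
            float(rng.uniform(-aug.max_shift_frac, aug.max_shift_frac))
            if aug.max_shift_frac > 0
            else 0.0
            for _ in range(2)
        ),
    }


def _apply_augment(arr: np.ndarray, params: dict, order: int) -> np.ndarray:
    out = arr
    if params["hflip"]:
        out = out[:, ::-1]
    if params["vflip"]:
        out = out[::-1, :]
    angle = params["angle_deg"]
    sh = params["shift_frac"]
    if angle != 0.0 or any(s != 0.0 for s in sh):
        theta = math.radians(angle)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        center = (np.array(out.shape, dtype=float) - 1) / 2
        shift_px = np.array([sh[0] * out.shape[0], sh[1] * out.shape[1]])
        offset = center - rot @ center - rot @ shift_px
        out = ndimage.affine_transform(
            out, rot, offset=offset, order=order, mode="constant", cval=0.0,
            prefilter=False,
        )
    return np.ascontiguousarray(out, dtype=np.float32)


def augment_pair(
    image_slice: np.ndarray,
    mask_slice: np.ndarray,
    config: TrainConfig | AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric transform identically to image and mask.

    Linear interpolation for the image, nearest for the mask (stays binary);
    out-of-bounds regions are filled with 0.
    """
    if image_slice.shape != mask_slice.shape:
        raise ConsistencyError(
            f"image {image_slice.shape} and mask {mask_slice.shape} differ"
        )
    aug = config.augmentation if isinstance(config, TrainConfig) else config
    if not aug.enabled:
        return image_slice, mask_slice
    params = sample_augment_params(aug, rng)
    return (
        _apply_augment(image_slice, params, order=1),
        _apply_augment(mask_slice, params, order=0),
    )


StackPair = tuple[SliceStack, SliceStack]  # (image stack, mask stack)


def _collect(stacks: list[StackPair], plane: str | None):
    xs, ys, subjects = [], [], set()
    for img, msk in stacks:
        if plane is None:
            plane = img.plane
        if img.plane != plane or msk.plane != plane:
            raise ConsistencyError(
                f"stack planes {img.plane}/{msk.plane} do not match {plane}"
            )
        if img.slices.shape != msk.slices.shape:
            raise ConsistencyError("image and mask stacks have different shapes")
        xs.append(img.slices)
        ys.append(msk.slices)
        subjects.add(img.subject_id)
    return np.concatenate(xs), np.concatenate(ys), subjects, plane


def _global_dice(pred_bin: np.ndarray, truth: np.ndarray) -> float:
    inter = float(np.logical_and(pred_bin, truth > 0.5).sum())
    total = float(pred_bin.sum()) + float((truth > 0.5).sum())
    if total == 0:
        return 1.0
    return 2.0 * inter / total


def _loss_fn(name: str):
    return dice_loss_and_grad if name == "dice" else bce_dice_loss_and_grad


def _run_training(
    net: UNet2D,
    train_stacks: list[StackPair],
    val_stacks: list[StackPair],
    config: TrainConfig,
    plane: str | None = None,
) -> PlaneModel:
    if not train_stacks:
        raise ValueError("empty training set")
    x_tr, y_tr, subj_tr, plane = _collect(train_stacks, plane)
    x_va, y_va, subj_va, _ = _collect(val_stacks, plane) if val_stacks else (
        np.empty((0,) + x_tr.shape[1:]), np.empty((0,) + x_tr.shape[1:]), set(), plane
    )
    leaked = subj_tr & subj_va
    assert not leaked, f"subject-level leakage between train and val: {leaked}"

    rng = np.random.default_rng(config.seed + 1)
    adam = Adam(net.params, lr=config.learning_rate)
    loss_grad = _loss_fn(config.loss_name)
    n = x_tr.shape[0]
    history: list[dict] = []
    best_state = net.state_dict()
    best_val = -np.inf

    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = perm[start : start + config.batch_size]
            if config.augmentation.enabled:
                xb = np.empty((len(idx),) + x_tr.shape[1:], dtype=np.float32)
                yb = np.empty_like(xb)
                for j, i in enumerate(idx):
                    xb[j], yb[j] = augment_pair(x_tr[i], y_tr[i], config, rng)
            else:
                xb = x_tr[idx].astype(np.float32)
                yb = y_tr[idx].astype(np.float32)
            logits = net.forward(xb[..., None], train=True)
            loss, dz = loss_grad(logits, yb[..., None])
            grads = net.backward(dz)
            adam.step(grads)
            losses.append(loss)
        record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if x_va.shape[0]:
            proba = net.predict_proba(
                x_va[..., None].astype(np.float32), batch_size=config.batch_size
            )
            pred = proba >= config.binarization_threshold
            record["val_dsc"] = _global_dice(pred, y_va)
            val_logits = np.log(
                np.clip(proba, 1e-6, 1 - 1e-6) / np.clip(1 - proba, 1e-6, 1)
            ).astype(np.float32)
            record["val_loss"] = float(
                loss_grad(val_logits[..., None], y_va[..., None].astype(np.float32))[0]
            )
        else:
            record["val_dsc"] = float("nan")
        history.append(record)
        val_score = record["val_dsc"]
        if np.isnan(val_score):
            val_score = -record["train_loss"]  # no val set: keep lowest train loss
        if val_score >= best_val:
            best_val = val_score
            best_state = net.state_dict()

    net.load_state_dict(best_state)
    return PlaneModel(plane=plane, net=net, config=config, history=history)


def train(
    train_stacks: list[StackPair],
    val_stacks: list[StackPair],
    config: TrainConfig,
) -> PlaneModel:
    """Train a per-plane model from scratch.

    ``train_stacks``/``val_stacks`` are lists of (image stack, mask stack)
    pairs from disjoint subject sets, all on one plane.  The returned model
    carries the parameter state of the epoch maximizing validation DSC, plus
    the full per-epoch history.  Deterministic given ``config.seed``.
    """
    net = UNet2D(
        in_ch=1, base=config.base_channels, depth=config.encoder_depth,
        seed=config.seed,
    )
    return _run_training(net, train_stacks, val_stacks, config)


def predict_slices(model: PlaneModel, stack: SliceStack) -> np.ndarray:
    """Per-slice probability grids (n, res, res) in [0, 1]; pure function."""
    if stack.plane != model.plane:
        raise ConsistencyError(
            f"stack plane {stack.plane!r} != model plane {model.plane!r}"
        )
    x = stack.slices[..., None].astype(np.float32)
    return model.net.predict_proba(x, batch_size=model.config.batch_size)


def fine_tune(
    model: PlaneModel,
    new_train_stacks: list[StackPair],
    new_val_stacks: list[StackPair],
    config: TrainConfig,
) -> PlaneModel:
    """Continue optimizing an existing model on new data (no re-initialization).

    With ``config.epochs == 0`` the parameters are returned unchanged.
    """
    net = model.net.copy()
    if config.epochs == 0:
        return PlaneModel(plane=model.plane, net=net, config=config,
                          history=list(model.history))
    return _run_training(net, new_train_stacks, new_val_stacks, config,
                         plane=model.plane)


def save_model(model: PlaneModel, path: str | Path) -> None:
    """Persist a model (parameters + config + history) to a single .npz file."""
    meta = {
        "plane": model.plane,
        "config": dataclasses.asdict(model.config),
        "history": model.history,
        "arch": {"in_ch": model.net.in_ch, "base": model.net.base,
                 "depth": model.net.depth},
    }
    arrays = {f"param/{k}": v for k, v in model.net.params.items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> PlaneModel:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        params = {
            k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")
        }
    cfg_raw = dict(meta["config"])
    cfg_raw["augmentation"] = AugmentConfig(**cfg_raw["augmentation"])
    config = TrainConfig(**cfg_raw)
    net = UNet2D(**meta["arch"], seed=0)
    net.load_state_dict(params)
    return PlaneModel(plane=meta["plane"], net=net, config=config,
                      history=list(meta["history"]))
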