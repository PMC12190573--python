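"""Training and prediction orchestration.

Defaults mirror the published training recipe: Adam at learning rate 1e-4,
batch size 2, 100 epochs, combined Dice+Focal objective, softmax output.
Runs are fully seeded (weight init and data order) and CPU-deterministic;
the best-validation checkpoint (by mean foreground region soft Dice) is
retained. Checkpoints are ``.npz`` archives of the flat weight arrays plus
the architecture config, so save -> load -> predict is bit-identical.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_brats import SubjectRecord, read_subject, remap_labels
from .model import ArchitectureConfig, LIUNet, build_liunet, count_parameters
from .nn import Adam
from .objectives import CombinedLossConfig, FocalLossConfig, get_loss
from .preprocess import DEFAULT_TARGET_SHAPE, preprocess_subject
from .volumes import LabelVolume


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 100
    optimizer: str = "adam"
    loss: str = "combined"
    seed: int = 0
    checkpoint_dir: Path | None = None
    device: str = "cpu"
    max_steps: int | None = None      # cap on total optimizer steps
    augment_flips: bool = False
    # objective parameters
    alpha: float = 0.25
    gamma: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    eps: float = 1e-6

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.device not in ("cpu", "gpu"):
            raise ValueError(f"device must be cpu or gpu, got {self.device!r}")
        if self.device == "gpu":
            warnings.warn("no GPU backend is available; falling back to cpu")
            self.device = "cpu"
        if self.checkpoint_dir is not None:
            self.checkpoint_dir = Path(self.checkpoint_dir)


def load_dataset(records, target_shape=DEFAULT_TARGET_SHAPE,
                 normalization: str = "minmax"):
    """Read + preprocess subjects into (x, y, subject_id) training triples."""
    out = []
    for rec in records:
        volumes, mask = read_subject(rec)
        x, y = preprocess_subject(volumes, mask, target_shape=target_shape,
                                  normalization=normalization)
        out.append((x.voxels, None if y is None else y.voxels, rec.subject_id))
    return out


def region_soft_dice(p: np.ndarray, g: np.ndarray, labels, eps: float = 1e-6) -> float:
    """Soft Dice of a label-union region on probability maps (channels last)."""
    pr = p[..., list(labels)].sum(axis=-1)
    gr = g[..., list(labels)].sum(axis=-1)
    num = 2.0 * (pr * gr).sum() + eps
    den = (pr * pr).sum() + (gr * gr).sum() + eps
    return float(num / den)


_REGION_LABELS = {"ET": (3,), "TC": (1, 3), "WT": (1, 2, 3)}


def _evaluate_soft(model: LIUNet, data) -> dict:
    scores = {name: [] for name in _REGION_LABELS}
    for x, y, _sid in data:
        p = model.forward(x[None], training=False)[0]
        for name, labels in _REGION_LABELS.items():
            scores[name].append(region_soft_dice(p, y, labels))
    return {name: float(np.mean(v)) for name, v in scores.items()}


def train(train_data, val_data, arch_cfg: ArchitectureConfig | None,
          cfg: TrainConfig):
    """Optimize the network on preprocessed (x, y, id) triples.

    Returns ``(model, log)`` where the model carries the best-validation
    weights (final weights if there is no validation set) and ``log`` is a
    per-epoch DataFrame. A checkpoint and CSV log are written when
    ``cfg.checkpoint_dir`` is set.
    """
    if not train_data:
        raise ValueError("training partition is empty")
    if any(y is None for _x, y, _s in train_data):
        raise ValueError("every training subject needs a label mask")

    model = build_liunet(arch_cfg, seed=cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    focal_cfg = FocalLossConfig(alpha=cfg.alpha, gamma=cfg.gamma)
    combined_cfg = CombinedLossConfig(lambda1=cfg.lambda1, lambda2=cfg.lambda2)
    loss_fn = get_loss(cfg.loss, combined_cfg, focal_cfg, eps=cfg.eps)
    rng = np.random.default_rng(cfg.seed)

    rows = []
    best_score = -np.inf
    best_state = None
    steps = 0
    done = False
    for epoch in range(1, cfg.epochs + 1):
        t0 = time.perf_counter()
        order = rng.permutation(len(train_data))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = np.stack([train_data[i][0] for i in idx])
            yb = np.stack([train_data[i][1] for i in idx])
            if cfg.augment_flips:
                for axis in (1, 2, 3):
                    if rng.random() < 0.5:
                        xb = np.flip(xb, axis=axis)
                        yb = np.flip(yb, axis=axis)
                xb = np.ascontiguousarray(xb)
                yb = np.ascontiguousarray(yb)
            p = model.forward(xb, training=True)
            value, grad = loss_fn(p, yb)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value!r} at epoch {epoch} step {steps}; "
                    "reduce the learning rate or check the inputs")
            optimizer.zero_grad()
            model.backward(grad.astype(np.float32))
            optimizer.step()
            losses.append(float(value))
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break

        row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_loss": np.nan, "dice_ET": np.nan, "dice_TC": np.nan,
               "dice_WT": np.nan}
        if val_data:
            vlosses = [float(loss_fn(model.forward(x[None], training=False),
                                     y[None])[0]) for x, y, _ in val_data]
            row["val_loss"] = float(np.mean(vlosses))
            soft = _evaluate_soft(model, val_data)
            row.update({f"dice_{k}": v for k, v in soft.items()})
            score = float(np.mean(list(soft.values())))
        else:
            score = -row["train_loss"]
        row["seconds"] = time.perf_counter() - t0
        rows.append(row)
        if score > best_score:
            best_score = score
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if done:
            break

    if best_state is not None:
        model.load_state_arrays(best_state)
    log = pd.DataFrame(rows)
    if cfg.checkpoint_dir is not None:
        cfg.checkpoint_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, cfg.checkpoint_dir / "best.npz")
        log.to_csv(cfg.checkpoint_dir / "train_log.csv", index=False)
    return model, log


def save_checkpoint(model: LIUNet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_arrays()
    state["__arch_json"] = np.frombuffer(
        json.dumps(model.cfg.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)
    return path


def load_checkpoint(path) -> LIUNet:
    with np.load(Path(path)) as npz:
        arch = ArchitectureConfig.from_dict(
            json.loads(bytes(npz["__arch_json"]).decode()))
        model = build_liunet(arch, seed=0)
        model.load_state_arrays({k: npz[k] for k in npz.files if k != "__arch_json"})
    return model


def predict_tensor(model: LIUNet, x: np.ndarray) -> LabelVolume:
    """Argmax labels for one preprocessed (D,H,W,4) tensor."""
    p = model.forward(np.asarray(x, dtype=np.float32)[None], training=False)[0]
    return LabelVolume(np.argmax(p, axis=-1).astype(np.int16))


def predict_subject(model: LIUNet, record: SubjectRecord,
                    target_shape=DEFAULT_TARGET_SHAPE,
                    normalization: str = "minmax"):
    """Preprocess a subject and predict its segmentation mask.

    Returns ``(prediction, ground_truth)``; ground truth is the remapped,
    resized mask when the record has one, else ``None``.
    """
    volumes, mask = read_subject(record)
    x, y = preprocess_subject(volumes, mask, target_shape=target_shape,
                              normalization=normalization)
    pred = predict_tensor(model, x.voxels)
    truth = None
    if y is not None:
        truth = LabelVolume(np.argmax(y.voxels, axis=-1).astype(np.int16))
    return pred, truth


def model_size_report(arch_cfg: ArchitectureConfig | None = None) -> dict:
    """Parameter count of an instantiated network, as both count and millions."""
    model = build_liunet(arch_cfg, seed=0)
    n = count_parameters(model)
    return {"param_count": n, "param_millions": n / 1e6}
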