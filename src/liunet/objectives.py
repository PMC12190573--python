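"""Training objectives: soft Dice, focal loss and their weighted combination.

The soft Dice coefficient uses the squared-denominator form

    dice = (2 * sum(p*g) + eps) / (sum(p^2) + sum(g^2) + eps)

computed per class over all voxels and averaged over the three foreground
classes (background is excluded by default, since it dominates voxel counts).
Dice loss is ``1 - dice``. Focal loss down-weights easy voxels,

    FL(p_t) = -alpha_t * (1 - p_t)^gamma * ln(p_t),

averaged over voxels, where ``p_t`` is the predicted probability of each
voxel's true class, clipped at 1e-7 before the logarithm. The combined
objective is ``lambda1 * focal + lambda2 * dice_loss``.

Every loss comes with an analytic gradient with respect to the predicted
probabilities (``*_and_grad``), which the training loop feeds into the
network's softmax backward pass; the test suite checks these gradients
against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_EPS = 1e-6
PROB_CLIP = 1e-7


@dataclass
class FocalLossConfig:
    """alpha: class-balance factor; gamma: focusing exponent; alpha_t:
    optional per-class weights overriding the scalar alpha."""

    alpha: float = 0.25
    gamma: float = 2.0
    alpha_t: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")
        if self.alpha_t is not None:
            self.alpha_t = np.asarray(self.alpha_t, dtype=np.float64)


@dataclass
class CombinedLossConfig:
    """lambda1 weights the focal term, lambda2 the Dice term."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.lambda1 == 0 and self.lambda2 == 0:
            raise ValueError("at least one loss weight must be positive")


def _check_shapes(p: np.ndarray, g: np.ndarray) -> None:
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != ground truth shape {g.shape}")


def _foreground_channels(n_channels: int, foreground_only: bool) -> range:
    return range(1, n_channels) if (foreground_only and n_channels > 1) else range(n_channels)


def soft_dice_and_grad(p: np.ndarray, g: np.ndarray, eps: float = DEFAULT_EPS,
                       foreground_only: bool = True):
    """Soft Dice coefficient and its gradient w.r.t. ``p``.

    Multi-channel inputs (ndim >= 4, channels last) score each class over all
    voxels and average over foreground classes; lower-rank inputs are treated
    as a single region.
    """
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _check_shapes(p, g)
    grad = np.zeros_like(p)
    if p.ndim >= 4:
        channels = list(_foreground_channels(p.shape[-1], foreground_only))
        total = 0.0
        for c in channels:
            pc, gc = p[..., c], g[..., c]
            num = 2.0 * (pc * gc).sum() + eps
            den = (pc * pc).sum() + (gc * gc).sum() + eps
            total += num / den
            grad[..., c] = (2.0 * gc * den - num * 2.0 * pc) / (den * den)
        k = len(channels)
        return total / k, grad / k
    num = 2.0 * (p * g).sum() + eps
    den = (p * p).sum() + (g * g).sum() + eps
    grad[...] = (2.0 * g * den - num * 2.0 * p) / (den * den)
    return num / den, grad


def soft_dice_coefficient(p, g, eps: float = DEFAULT_EPS,
                          foreground_only: bool = True) -> float:
    return float(soft_dice_and_grad(p, g, eps, foreground_only)[0])


def dice_loss_and_grad(p, g, eps: float = DEFAULT_EPS, foreground_only: bool = True):
    value, grad = soft_dice_and_grad(p, g, eps, foreground_only)
    return 1.0 - value, -grad


def dice_loss(p, g, eps: float = DEFAULT_EPS, foreground_only: bool = True) -> float:
    return float(dice_loss_and_grad(p, g, eps, foreground_only)[0])


def focal_loss_and_grad(p_t: np.ndarray, cfg: FocalLossConfig | None = None,
                        alpha_t_map: np.ndarray | None = None):
    """Focal loss over per-voxel true-class probabilities, and d(loss)/d(p_t).

    ``alpha_t_map`` optionally gives each voxel its own class weight
    (already gathered for the voxel's true class); otherwise the scalar
    ``cfg.alpha`` applies uniformly.
    """
    cfg = cfg or FocalLossConfig()
    p_t = np.asarray(p_t, dtype=np.float64)
    clipped = (p_t < PROB_CLIP) | (p_t > 1.0)
    pt = np.clip(p_t, PROB_CLIP, 1.0)
    a = cfg.alpha if alpha_t_map is None else np.asarray(alpha_t_map, dtype=np.float64)
    gamma = cfg.gamma
    one_minus = 1.0 - pt
    log_pt = np.log(pt)
    per_voxel = -a * one_minus ** gamma * log_pt
    n = p_t.size
    # d/dpt[-a (1-pt)^g ln pt] = -a [ -g (1-pt)^(g-1) ln pt + (1-pt)^g / pt ]
    if gamma == 0.0:
        dpt = -a / pt
    else:
        dpt = -a * (-gamma * one_minus ** (gamma - 1.0) * log_pt
                    + one_minus ** gamma / pt)
    dpt = np.where(clipped, 0.0, dpt) / n
    return float(per_voxel.mean()), dpt


def focal_loss(p_t, cfg: FocalLossConfig | None = None) -> float:
    return focal_loss_and_grad(p_t, cfg)[0]


def focal_loss_binary(y: np.ndarray, p: np.ndarray,
                      cfg: FocalLossConfig | None = None) -> float:
    """Binary (tumor vs. background) expansion:
    ``-alpha*y*(1-p)^g*ln(p) - (1-alpha)*(1-y)*p^g*ln(1-p)``."""
    cfg = cfg or FocalLossConfig()
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p, dtype=np.float64), PROB_CLIP, 1.0 - PROB_CLIP)
    a, gamma = cfg.alpha, cfg.gamma
    pos = -a * y * (1.0 - p) ** gamma * np.log(p)
    neg = -(1.0 - a) * (1.0 - y) * p ** gamma * np.log(1.0 - p)
    return float((pos + neg).mean())


def multiclass_focal_and_grad(p: np.ndarray, g: np.ndarray,
                              cfg: FocalLossConfig | None = None):
    """Multi-class focal loss from class probabilities ``p`` and one-hot
    ``g`` (channels last), with gradient w.r.t. ``p``."""
    cfg = cfg or FocalLossConfig()
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    _check_shapes(p, g)
    p_t = (p * g).sum(axis=-1)
    alpha_map = None
    if cfg.alpha_t is not None:
        if cfg.alpha_t.shape[-1] != p.shape[-1]:
            raise ValueError("alpha_t length must equal the class count")
        alpha_map = (g * cfg.alpha_t).sum(axis=-1)
    value, dpt = focal_loss_and_grad(p_t, cfg, alpha_t_map=alpha_map)
    return value, g * dpt[..., None]


def multiclass_focal_loss(p, g, cfg: FocalLossConfig | None = None) -> float:
    return multiclass_focal_and_grad(p, g, cfg)[0]


def combined_loss_and_grad(p: np.ndarray, g: np.ndarray,
                           cfg: CombinedLossConfig | None = None,
                           focal_cfg: FocalLossConfig | None = None,
                           eps: float = DEFAULT_EPS):
    """``lambda1 * focal + lambda2 * dice_loss`` with gradient w.r.t. ``p``."""
    cfg = cfg or CombinedLossConfig()
    fl, fg = multiclass_focal_and_grad(p, g, focal_cfg)
    dl, dg = dice_loss_and_grad(p, g, eps=eps)
    return cfg.lambda1 * fl + cfg.lambda2 * dl, cfg.lambda1 * fg + cfg.lambda2 * dg


def combined_loss(p, g, cfg: CombinedLossConfig | None = None,
                  focal_cfg: FocalLossConfig | None = None,
                  eps: float = DEFAULT_EPS) -> float:
    return float(combined_loss_and_grad(p, g, cfg, focal_cfg, eps)[0])


#: Losses selectable from the training config, each (p, g) -> (value, grad).
def get_loss(name: str, combined_cfg: CombinedLossConfig | None = None,
             focal_cfg: FocalLossConfig | None = None, eps: float = DEFAULT_EPS):
    if name == "dice":
        return lambda p, g: dice_loss_and_grad(p, g, eps=eps)
    if name == "focal":
        return lambda p, g: multiclass_focal_and_grad(p, g, focal_cfg)
    if name == "combined":
        return lambda p, g: combined_loss_and_grad(p, g, combined_cfg, focal_cfg, eps)
    raise ValueError(f"unknown loss {name!r}; expected dice, focal or combined")
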