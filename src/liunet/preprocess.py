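"""Intensity normalization, spatial resizing, stacking and one-hot encoding.

Normalization operates per modality, per subject. Two modes are provided:
min–max scaling ``(X - X_min) / (X_max - X_min)`` (the pipeline default) and
z-scoring with the population standard deviation. The canonical pipeline
order is resize first, then normalize, so the output range is guaranteed
regardless of interpolation overshoot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import IntensityVolume, LabelVolume, MultimodalTensor, OneHotMask, MODALITIES

#: BraTS native resolution and the working resolution used for training.
BRATS_SHAPE = (240, 240, 155)
DEFAULT_TARGET_SHAPE = (128, 128, 128)


@dataclass
class NormalizationParams:
    """Fit statistics of one normalization so it can be reported/inverted."""

    mode: str
    x_min: float = 0.0
    x_max: float = 0.0
    mean: float = 0.0
    sd: float = 0.0


def minmax_normalize(vol: IntensityVolume):
    """Rescale a volume to [0, 1] by its own min and max.

    A constant volume has no dynamic range; it maps to all zeros with a
    warning rather than dividing by zero.
    """
    x = np.asarray(vol.voxels, dtype=np.float32)
    x_min = float(x.min())
    x_max = float(x.max())
    params = NormalizationParams(mode="minmax", x_min=x_min, x_max=x_max)
    if x_max == x_min:
        warnings.warn(
            f"constant {vol.modality} volume (value {x_min}); returning zeros",
            stacklevel=2)
        out = np.zeros_like(x)
    else:
        out = (x - x_min) / (x_max - x_min)
    return IntensityVolume(out, modality=vol.modality, affine=vol.affine.copy()), params


def zscore_normalize(vol: IntensityVolume):
    """Center to zero mean and scale to unit population standard deviation."""
    x = np.asarray(vol.voxels, dtype=np.float64)
    mean = float(x.mean())
    sd = float(x.std())  # population sd (ddof=0)
    params = NormalizationParams(mode="zscore", mean=mean, sd=sd)
    if sd == 0.0:
        warnings.warn(
            f"constant {vol.modality} volume (value {mean}); returning zeros",
            stacklevel=2)
        out = np.zeros_like(x, dtype=np.float32)
    else:
        out = ((x - mean) / sd).astype(np.float32)
    return IntensityVolume(out, modality=vol.modality, affine=vol.affine.copy()), params


def normalize(vol: IntensityVolume, mode: str = "minmax"):
    if mode == "minmax":
        return minmax_normalize(vol)
    if mode == "zscore":
        return zscore_normalize(vol)
    raise ValueError(f"unknown normalization mode {mode!r}")


def resize_volume(voxels: np.ndarray, target_shape, kind: str = "intensity") -> np.ndarray:
    """Resample a 3D volume to ``target_shape``.

    Intensities use trilinear interpolation; label masks use nearest-neighbor
    so no new label values are invented.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {voxels.ndim}D")
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t <= 0 for t in target_shape):
        raise ValueError(f"target shape must be three positive ints, got {target_shape}")
    if voxels.shape == target_shape:
        return voxels.copy()
    zoom = [t / s for t, s in zip(target_shape, voxels.shape)]
    if kind == "intensity":
        out = ndimage.zoom(voxels.astype(np.float32), zoom, order=1,
                           mode="nearest", grid_mode=True)
    elif kind == "label":
        out = ndimage.zoom(voxels, zoom, order=0, mode="nearest", grid_mode=True)
    else:
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    # scipy.ndimage.zoom can be off by one voxel on awkward ratios; crop/assert
    if out.shape != target_shape:
        out = out[tuple(slice(0, t) for t in target_shape)]
    return out


def stack_modalities(volumes: dict) -> MultimodalTensor:
    """Stack the four modalities channels-last in the fixed order
    (t1, t1ce, t2, flair)."""
    missing = set(MODALITIES) - set(volumes)
    if missing:
        raise ValueError(f"missing modalities: {sorted(missing)}")
    shapes = {m: tuple(volumes[m].voxels.shape) for m in MODALITIES}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"modality shapes differ: {shapes}")
    stacked = np.stack([np.asarray(volumes[m].voxels, dtype=np.float32)
                        for m in MODALITIES], axis=-1)
    return MultimodalTensor(stacked)


def one_hot_encode(mask: LabelVolume, n_classes: int = 4) -> OneHotMask:
    """Expand integer labels to a (D,H,W,n_classes) binary tensor."""
    v = mask.voxels
    if v.min() < 0 or v.max() >= n_classes:
        raise ValueError(
            f"labels must lie in [0, {n_classes}), got range [{v.min()}, {v.max()}]")
    out = np.zeros(v.shape + (n_classes,), dtype=np.float32)
    np.put_along_axis(out, v[..., None].astype(np.int64), 1.0, axis=-1)
    return OneHotMask(out)


def preprocess_subject(volumes: dict, mask: LabelVolume | None,
                       target_shape=DEFAULT_TARGET_SHAPE,
                       normalization: str = "minmax"):
    """Full per-subject pipeline: resize -> normalize -> stack (+ mask path).

    The raw mask is remapped (4 -> 3) eagerly, resized nearest-neighbor and
    one-hot encoded. Returns ``(MultimodalTensor, OneHotMask | None)``.
    """
    from .io_brats import remap_labels

    resized = {}
    for m, vol in volumes.items():
        r = resize_volume(vol.voxels, target_shape, kind="intensity")
        rv = IntensityVolume(r, modality=m, affine=vol.affine.copy())
        resized[m], _ = normalize(rv, mode=normalization)
    tensor = stack_modalities(resized)
    onehot = None
    if mask is not None:
        remapped = remap_labels(mask)
        rm = resize_volume(remapped.voxels, target_shape, kind="label")
        onehot = one_hot_encode(LabelVolume(rm, affine=mask.affine.copy()))
    return tensor, onehot
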