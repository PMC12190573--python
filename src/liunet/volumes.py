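"""Shared in-memory containers for volumes and masks.

Arrays are kept in on-disk voxel order; affines pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Fixed channel order for stacked multimodal tensors.
MODALITIES = ("t1", "t1ce", "t2", "flair")

#: Raw BraTS label for enhancing tumor, remapped to 3 before modelling.
RAW_ET_LABEL = 4

_EYE4 = np.eye(4)


def _default_affine() -> np.ndarray:
    return _EYE4.copy()


@dataclass
class IntensityVolume:
    """One modality's 3D scalar field in scanner units (or normalized)."""

    voxels: np.ndarray
    modality: str
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"intensity volume must be 3D, got shape {self.voxels.shape}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}, expected one of {MODALITIES}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("intensity volume contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """Integer segmentation mask; {0,1,2,3} once remapped (raw may hold 4)."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label volume must be 3D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"label volume must be integer-typed, got {self.voxels.dtype}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def label_set(self) -> set:
        return set(np.unique(self.voxels).tolist())


@dataclass
class MultimodalTensor:
    """Stacked 4-channel volume ``(D, H, W, 4)`` in MODALITIES order."""

    voxels: np.ndarray
    channel_order: tuple = MODALITIES

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4 or self.voxels.shape[-1] != len(self.channel_order):
            raise ValueError(
                f"multimodal tensor must be (D,H,W,{len(self.channel_order)}), "
                f"got shape {self.voxels.shape}")

    @property
    def spatial_shape(self) -> tuple:
        return self.voxels.shape[:3]


@dataclass
class OneHotMask:
    """One-hot encoded labels ``(D, H, W, C)``; channels sum to 1 per voxel."""

    voxels: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError(f"one-hot mask must be 4D, got shape {self.voxels.shape}")

    @property
    def n_classes(self) -> int:
        return self.voxels.shape[-1]
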