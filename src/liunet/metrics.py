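"""Hard per-region Dice evaluation over the BraTS tumor regions.

Regions are nested unions of the remapped labels: enhancing tumor
ET = {3}, tumor core TC = {1, 3} (tumor excluding edema) and whole tumor
WT = {1, 2, 3}. The score is 2|X n Y| / (|X| + |Y|); when ground truth and
prediction are both empty for a region the score is 1.0 (nothing to find,
nothing found), and 0.0 when exactly one is empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import LabelVolume


@dataclass(frozen=True)
class RegionSpec:
    name: str
    labels: frozenset

    def __post_init__(self):
        if not self.labels:
            raise ValueError("region needs at least one label")


ET = RegionSpec("ET", frozenset({3}))
TC = RegionSpec("TC", frozenset({1, 3}))
WT = RegionSpec("WT", frozenset({1, 2, 3}))
DEFAULT_REGIONS = (ET, TC, WT)


def region_mask(mask: LabelVolume, region: RegionSpec) -> np.ndarray:
    """Binary volume that is true where the voxel label belongs to the region."""
    v = mask.voxels
    if (v == 4).any():
        raise ValueError("mask contains raw label 4; remap labels first")
    return np.isin(v, list(region.labels))


def hard_dice(x: np.ndarray, y: np.ndarray) -> float:
    """Overlap 2|X n Y| / (|X| + |Y|) between two binary volumes."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    nx = int(x.sum())
    ny = int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    inter = int(np.logical_and(x, y).sum())
    return 2.0 * inter / (nx + ny)


def subject_dice(prediction: LabelVolume, ground_truth: LabelVolume,
                 regions=DEFAULT_REGIONS) -> dict:
    """Per-region hard Dice for one subject."""
    if prediction.shape != ground_truth.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} != ground truth {ground_truth.shape}")
    return {r.name: hard_dice(region_mask(prediction, r), region_mask(ground_truth, r))
            for r in regions}


@dataclass
class DiceReport:
    per_subject: pd.DataFrame  # index subject_id, one column per region
    means: dict

    def to_csv(self, path) -> None:
        """Per-subject scores plus a cohort-mean summary row."""
        table = self.per_subject.copy()
        table.loc["mean"] = [self.means[c] for c in table.columns]
        table.to_csv(path, index_label="subject_id")


def evaluate_cohort(predictions: dict, ground_truth: dict,
                    regions=DEFAULT_REGIONS) -> DiceReport:
    """Subject-wise Dice per region plus unweighted cohort means.

    Both arguments map subject_id to a (remapped) :class:`LabelVolume`;
    every ground-truth subject must have a prediction.
    """
    missing = set(ground_truth) - set(predictions)
    if missing:
        raise ValueError(f"missing predictions for subjects: {sorted(missing)}")
    rows = {}
    for sid in sorted(ground_truth):
        rows[sid] = subject_dice(predictions[sid], ground_truth[sid], regions)
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[r.name for r in regions])
    means = {c: float(table[c].mean()) if len(table) else float("nan")
             for c in table.columns}
    return DiceReport(per_subject=table, means=means)
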