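"""BraTS-layout NIfTI I/O, label remapping and deterministic cohort splits.

A cohort lives as ``<root>/<ID>/<ID>_{flair,t1,t1ce,t2,seg}.nii.gz``. Raw
masks use labels {0: background, 1: necrotic/non-enhancing core, 2: edema,
4: enhancing tumor}; :func:`remap_labels` moves 4 to 3 so classes are the
contiguous set {0,1,2,3}. Readers preserve the raw values — remapping is an
explicit, observable step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .volumes import MODALITIES, IntensityVolume, LabelVolume

VALID_RAW_LABELS = frozenset({0, 1, 2, 3, 4})


@dataclass
class SubjectRecord:
    """Paths to one patient's four modality volumes and optional mask."""

    subject_id: str
    modality_paths: dict
    mask_path: Path | None = None

    def __post_init__(self):
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        missing = set(MODALITIES) - set(self.modality_paths)
        if missing:
            raise ValueError(
                f"subject {self.subject_id}: missing modality paths {sorted(missing)}")
        extra = set(self.modality_paths) - set(MODALITIES)
        if extra:
            raise ValueError(
                f"subject {self.subject_id}: unknown modalities {sorted(extra)}")
        self.modality_paths = {m: Path(p) for m, p in self.modality_paths.items()}
        if self.mask_path is not None:
            self.mask_path = Path(self.mask_path)

    @classmethod
    def from_directory(cls, subject_dir, require_mask: bool = False) -> "SubjectRecord":
        """Build a record from a ``<ID>/<ID>_<modality>.nii.gz`` directory."""
        subject_dir = Path(subject_dir)
        sid = subject_dir.name
        paths = {m: subject_dir / f"{sid}_{m}.nii.gz" for m in MODALITIES}
        seg = subject_dir / f"{sid}_seg.nii.gz"
        mask_path = seg if (seg.exists() or require_mask) else None
        return cls(subject_id=sid, modality_paths=paths, mask_path=mask_path)


@dataclass
class DatasetSplit:
    train_ids: list
    val_ids: list
    test_ids: list
    fractions: tuple
    seed: int

    def sizes(self) -> tuple:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))

    def partition_of(self, subject_id: str) -> str:
        for name, ids in (("train", self.train_ids), ("val", self.val_ids),
                          ("test", self.test_ids)):
            if subject_id in ids:
                return name
        raise KeyError(subject_id)


def _load_nifti(path: Path, what: str):
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} volume not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{what} volume at {path} is {data.ndim}D, expected 3D")
    return data, img.affine


def read_subject(record: SubjectRecord):
    """Load the four modality volumes and, if present, the raw mask.

    Returns ``(volumes, mask)`` where ``volumes`` maps modality name to
    :class:`IntensityVolume` and ``mask`` is a raw (un-remapped)
    :class:`LabelVolume` or ``None``. All five arrays must share one shape.
    """
    volumes = {}
    ref_shape = None
    for m in MODALITIES:
        data, affine = _load_nifti(record.modality_paths[m], f"{record.subject_id}/{m}")
        if ref_shape is None:
            ref_shape = data.shape
        elif data.shape != ref_shape:
            raise ValueError(
                f"subject {record.subject_id}: modality {m} shape {data.shape} "
                f"differs from {ref_shape}")
        volumes[m] = IntensityVolume(data.astype(np.float32), modality=m, affine=affine)
    mask = None
    if record.mask_path is not None:
        data, affine = _load_nifti(record.mask_path, f"{record.subject_id}/seg")
        if data.shape != ref_shape:
            raise ValueError(
                f"subject {record.subject_id}: mask shape {data.shape} "
                f"differs from modalities {ref_shape}")
        mask = LabelVolume(np.rint(data).astype(np.int16), affine=affine)
    return volumes, mask


def remap_labels(mask: LabelVolume) -> LabelVolume:
    """Map raw enhancing-tumor label 4 to 3; idempotent on {0,1,2,3}."""
    values = set(np.unique(mask.voxels).tolist())
    bad = values - VALID_RAW_LABELS
    if bad:
        raise ValueError(f"mask contains invalid label values: {sorted(bad)}")
    out = mask.voxels.copy()
    out[out == 4] = 3
    return LabelVolume(out, affine=mask.affine.copy())


def make_split(subject_ids, fractions=(0.7, 0.1, 0.2), seed: int = 0,
               groups: dict | None = None) -> DatasetSplit:
    """Deterministically partition a cohort into train/val/test.

    Sizes follow the floor rule: ``n_train = floor(f_train * n)``,
    ``n_val = floor(f_val * n)``, and the remainder goes to test (so a
    1250-subject cohort at 70/10/20 gives exactly 875/125/250). When
    ``groups`` maps subject_id to a stratum tag, the rule is applied within
    each stratum independently (seeded per cohort, so the overall split is
    still reproducible).
    """
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject_ids in cohort")
    f = tuple(float(x) for x in fractions)
    if len(f) != 3 or any(x < 0 for x in f):
        raise ValueError(f"fractions must be three non-negative numbers, got {fractions}")
    if abs(sum(f) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(f)!r}")

    rng = np.random.default_rng(seed)

    def _split_ids(ids):
        ids = list(ids)
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n = len(ids)
        n_train = int(np.floor(f[0] * n))
        n_val = int(np.floor(f[1] * n))
        return (shuffled[:n_train],
                shuffled[n_train:n_train + n_val],
                shuffled[n_train + n_val:])

    if groups:
        strata: dict = {}
        for sid in subject_ids:
            strata.setdefault(groups.get(sid), []).append(sid)
        train, val, test = [], [], []
        for tag in sorted(strata, key=str):
            tr, va, te = _split_ids(strata[tag])
            train += tr
            val += va
            test += te
    else:
        train, val, test = _split_ids(subject_ids)
    return DatasetSplit(train, val, test, fractions=f, seed=seed)


def write_nifti(volume: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a 3D/4D array as NIfTI-1, preserving the array dtype."""
    volume = np.asarray(volume)
    if volume.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D array, got {volume.ndim}D")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(volume, np.asarray(affine, dtype=np.float64))
    img.set_data_dtype(volume.dtype)
    nib.save(img, str(path))
    return path


def write_manifest(split: DatasetSplit, path) -> Path:
    """Emit the cohort index as a two-column CSV (subject_id, partition)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "partition"])
        for name, ids in (("train", split.train_ids), ("val", split.val_ids),
                          ("test", split.test_ids)):
            for sid in ids:
                writer.writerow([sid, name])
    return path


def read_manifest(path) -> dict:
    """Read a split manifest back as {partition: [subject_id, ...]}."""
    parts: dict = {"train": [], "val": [], "test": []}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            name = row["partition"]
            if name not in parts:
                raise ValueError(f"unknown partition {name!r} in manifest {path}")
            parts[name].append(row["subject_id"])
    return parts
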