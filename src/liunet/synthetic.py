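"""Synthetic BraTS-like phantoms: four modalities plus a nested label mask.

Each phantom is a brain-sized ellipsoid containing a nested tumor: a whole-
tumor ellipsoid whose outer shell is edema (label 2), a tumor-core ellipsoid
whose rim enhances (label 3) and whose interior is necrotic/non-enhancing
core (label 1). Channel intensities follow the qualitative contrast of real
MRI: FLAIR is brightest in edema, T1ce in the enhancing rim, T2 bright across
the tumor, T1 near-uniform. Gaussian noise is added per channel.

Geometry is deliberately simple — the generator exists to give every
pipeline stage controllable inputs with exactly known labels, not to imitate
MRI texture. All randomness derives from ``(seed, subject_index)`` so a
cohort is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_brats import SubjectRecord, write_nifti
from .volumes import MODALITIES, IntensityVolume, LabelVolume

TISSUES = ("background", "brain", "core", "edema", "enhancing")

#: Mean intensity per (modality, tissue), loosely mimicking clinical contrast.
DEFAULT_INTENSITY_TABLE = {
    ("t1", "background"): 0.0, ("t1", "brain"): 100.0, ("t1", "edema"): 90.0,
    ("t1", "core"): 80.0, ("t1", "enhancing"): 95.0,
    ("t1ce", "background"): 0.0, ("t1ce", "brain"): 100.0, ("t1ce", "edema"): 110.0,
    ("t1ce", "core"): 90.0, ("t1ce", "enhancing"): 200.0,
    ("t2", "background"): 0.0, ("t2", "brain"): 100.0, ("t2", "edema"): 160.0,
    ("t2", "core"): 150.0, ("t2", "enhancing"): 140.0,
    ("flair", "background"): 0.0, ("flair", "brain"): 100.0, ("flair", "edema"): 200.0,
    ("flair", "core"): 130.0, ("flair", "enhancing"): 120.0,
}


def _default_radii(shape) -> dict:
    """Semi-axis ranges (voxels) scaled to the volume's smallest dimension."""
    s = min(shape) / 64.0
    return {"wt": (10.0 * s, 14.0 * s),
            "tc": (6.0 * s, 8.0 * s),
            "et": (3.0 * s, 4.5 * s)}


@dataclass
class PhantomConfig:
    shape: tuple = (64, 64, 64)
    n_subjects: int = 4
    radii: dict | None = None
    intensity_table: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_TABLE))
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape must be three dims >= 8, got {self.shape}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if self.radii is None:
            self.radii = _default_radii(self.shape)
        for key in ("wt", "tc", "et"):
            lo, hi = self.radii[key]
            if not 0 < lo <= hi:
                raise ValueError(f"radii[{key!r}] must be an increasing positive range")
        # strict nesting: enhancing-rim inner boundary < core < whole tumor
        if not (self.radii["et"][1] < self.radii["tc"][0]
                and self.radii["tc"][1] < self.radii["wt"][0]):
            raise ValueError(
                f"radius ranges must nest strictly (et < tc < wt), got {self.radii}")
        brain = 0.42 * min(self.shape)
        if self.radii["wt"][1] >= brain:
            raise ValueError(
                f"whole-tumor radius {self.radii['wt'][1]} must stay inside the "
                f"brain ellipsoid (semi-axis {brain:.1f})")


@dataclass
class PhantomSubject:
    subject_id: str
    volumes: dict  # modality -> IntensityVolume
    mask: LabelVolume
    provenance: dict


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_phantom(cfg: PhantomConfig, subject_index: int = 0) -> PhantomSubject:
    """Deterministically synthesize one multimodal subject."""
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, int(subject_index)])
    shape = cfg.shape
    center = np.array(shape) / 2.0
    brain_axes = [0.42 * s for s in shape]

    wt_r = rng.uniform(*cfg.radii["wt"])
    tc_r = rng.uniform(*cfg.radii["tc"])
    et_r = rng.uniform(*cfg.radii["et"])
    # tumor center offset, kept inside the brain ellipsoid
    max_off = [max(0.0, 0.9 * b - wt_r) for b in brain_axes]
    offset = rng.uniform(-1.0, 1.0, size=3) * [min(m, 0.15 * s)
                                               for m, s in zip(max_off, shape)]
    t_center = center + offset
    # mild anisotropy per axis so the ellipsoids are not spheres
    squash = rng.uniform(0.85, 1.15, size=3)

    brain = _ellipsoid(shape, center, brain_axes)
    wt = _ellipsoid(shape, t_center, wt_r * squash) & brain
    tc = _ellipsoid(shape, t_center, tc_r * squash) & brain
    core = _ellipsoid(shape, t_center, et_r * squash) & brain

    mask = np.zeros(shape, dtype=np.int16)
    mask[wt] = 2            # edema shell
    mask[tc] = 3            # enhancing rim of the core
    mask[core] = 1          # necrotic / non-enhancing center

    tissue = np.zeros(shape, dtype=np.int8)  # indexes into TISSUES
    tissue[brain] = 1
    tissue[mask == 2] = 3
    tissue[mask == 1] = 2
    tissue[mask == 3] = 4

    volumes = {}
    for m in MODALITIES:
        means = np.array([cfg.intensity_table[(m, t)] for t in TISSUES],
                         dtype=np.float32)
        img = means[tissue]
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, size=shape).astype(np.float32)
        volumes[m] = IntensityVolume(img.astype(np.float32), modality=m)

    return PhantomSubject(
        subject_id=f"phantom_{subject_index:04d}",
        volumes=volumes,
        mask=LabelVolume(mask),
        provenance={"seed": cfg.seed, "subject_index": int(subject_index),
                    "shape": shape, "radii": {k: (wt_r, tc_r, et_r)[i]
                                              for i, k in enumerate(("wt", "tc", "et"))}},
    )


def generate_cohort(cfg: PhantomConfig, out_dir,
                    emit_raw_label4: bool = False) -> list:
    """Write ``cfg.n_subjects`` phantoms as a BraTS-layout directory tree.

    With ``emit_raw_label4`` the segmentation files carry the raw BraTS
    convention (enhancing tumor stored as 4) so the label-remapping path is
    exercised on read-back.
    """
    out_dir = Path(out_dir)
    records = []
    for i in range(cfg.n_subjects):
        subj = generate_phantom(cfg, i)
        sdir = out_dir / subj.subject_id
        affine = np.eye(4)
        for m in MODALITIES:
            write_nifti(subj.volumes[m].voxels, affine,
                        sdir / f"{subj.subject_id}_{m}.nii.gz")
        seg = subj.mask.voxels
        if emit_raw_label4:
            seg = seg.copy()
            seg[seg == 3] = 4
        write_nifti(seg, affine, sdir / f"{subj.subject_id}_seg.nii.gz")
        records.append(SubjectRecord.from_directory(sdir))
    return records
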