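"""Reading/writing of volumes and phenotypes, and cross-file reconciliation.

All stages share one reference grid: volumes are modulated grey-matter maps
already in a common (study/template) space, so no resampling is performed and
any grid mismatch is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    PairingError,
    ReconciliationError,
    ShapeError,
    VolumeValidationError,
)

PHENOTYPE_COLUMNS = ("subject_id", "group", "timepoint", "sex", "age", "CDR", "MMSE", "MoCA")


@dataclass
class VolumeImage:
    """A 3D scalar grid of grey-matter volume values.

    ``data`` holds non-negative, finite values (modulated GM maps preserve
    local tissue volume and cannot be negative). ``affine`` is carried
    opaquely for round-tripping; analysis only uses ``voxel_size_mm``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise VolumeValidationError("volume contains non-finite values")
        if np.any(self.data < 0):
            raise VolumeValidationError("volume contains negative values")
        vs = tuple(float(v) for v in np.atleast_1d(self.voxel_size_mm).ravel())
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeValidationError(f"invalid voxel size {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag(list(vs) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class ScanVolume:
    """A volume plus the identifiers that link it to a phenotype row."""

    subject_id: str
    timepoint: str
    group: str
    image: VolumeImage


def read_volume(path: str | Path) -> VolumeImage:
    """Read a NIfTI-1 volume; validates shape and value invariants."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D image, got {data.ndim}D")
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, voxel_size_mm=vs, affine=np.asarray(img.affine))


def write_volume(img: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (.nii or .nii.gz by extension)."""
    path = Path(path)
    nifti = nib.Nifti1Image(img.data, img.affine)
    nifti.header.set_zooms(img.voxel_size_mm)
    nib.save(nifti, str(path))
    return path


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV (missing MoCA encoded as empty field)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ReconciliationError(f"phenotype CSV missing columns: {missing}", missing)
    return df


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    phenotypes.to_csv(path, index=False)
    return path


def volume_filename(subject_id: str, timepoint: str, ext: str = ".nii.gz") -> str:
    return f"{subject_id}_{timepoint}{ext}"


def check_grids(images: Iterable[VolumeImage]) -> tuple[int, int, int]:
    """Assert all images share one grid; returns the common shape."""
    shapes = {im.shape for im in images}
    if len(shapes) > 1:
        raise ShapeError(f"volumes on mismatched grids: {sorted(shapes)}")
    if not shapes:
        raise ShapeError("no volumes given")
    return shapes.pop()


def load_cohort(volume_dir: str | Path, phenotype_csv: str | Path) -> tuple[list[ScanVolume], pd.DataFrame]:
    """Load and reconcile a cohort directory against its phenotype table.

    Every phenotype row must have exactly one matching volume file
    ``<subject_id>_<timepoint>.nii[.gz]`` and vice versa; offenders are
    listed in the raised error. Scans are returned in a stable order
    (sorted by subject_id, then timepoint) regardless of file ordering.
    """
    volume_dir = Path(volume_dir)
    phen = read_phenotypes(phenotype_csv)

    keys = list(zip(phen["subject_id"].astype(str), phen["timepoint"].astype(str)))
    dup = pd.Series(keys).duplicated(keep=False)
    if dup.any():
        offenders = sorted({keys[i] for i in np.flatnonzero(dup.to_numpy())})
        raise ReconciliationError(
            f"duplicate (subject, timepoint) phenotype rows: {offenders}", offenders
        )

    files: dict[tuple[str, str], Path] = {}
    for path in sorted(volume_dir.glob("*.nii*")):
        stem = path.name
        for suffix in (".nii.gz", ".nii"):
            if stem.endswith(suffix):
                stem = stem[: -len(suffix)]
                break
        if "_" not in stem:
            continue
        sid, tp = stem.rsplit("_", 1)
        files[(sid, tp)] = path

    orphan_rows = sorted(set(keys) - set(files))
    orphan_files = sorted(set(files) - set(keys))
    if orphan_rows or orphan_files:
        parts = []
        if orphan_rows:
            parts.append(f"phenotype rows with no volume file: {orphan_rows}")
        if orphan_files:
            parts.append(f"volume files with no phenotype row: {orphan_files}")
        raise ReconciliationError("; ".join(parts), orphan_rows + orphan_files)

    phen = phen.sort_values(["subject_id", "timepoint"], kind="mergesort").reset_index(drop=True)
    scans = []
    for row in phen.itertuples(index=False):
        key = (str(row.subject_id), str(row.timepoint))
        scans.append(
            ScanVolume(
                subject_id=key[0],
                timepoint=key[1],
                group=str(row.group),
                image=read_volume(files[key]),
            )
        )
    check_grids([s.image for s in scans])
    return scans, phen
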