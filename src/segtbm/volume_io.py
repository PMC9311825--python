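"""NIfTI volume / cohort-table I/O and the masked subjects x voxels matrix.

Voxel ordering convention
-------------------------
Matrix columns follow ascending *Fortran-order* linear indices of the mask
grid, i.e. ``linear = i + nx * (j + ny * k)`` with the first (x) axis varying
fastest.  Every voxel-index set elsewhere in the package (segments, label
maps, planted blocks) refers to *column positions* in this fixed ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, DegenerateVoxelError, GeometryError

__all__ = [
    "VoxelMask",
    "JacobianCohort",
    "REQUIRED_COHORT_COLUMNS",
    "load_cohort_table",
    "load_jacobian_cohort",
    "save_cohort_volumes",
    "export_label_map",
    "sample_homogeneity",
]

AFFINE_TOL = 1e-4

REQUIRED_COHORT_COLUMNS = (
    "subject_id",
    "mutation",
    "status",
    "phenotype",
    "age",
    "sex",
    "site",
    "family",
)


@dataclass(frozen=True)
class VoxelMask:
    """Geometry container: which grid voxels are inside the analysis mask.

    Parameters
    ----------
    grid_shape : tuple of int
        3D shape of the template grid.
    voxel_size : tuple of float
        Voxel dimensions in mm.
    affine : ndarray, shape (4, 4)
        Grid-to-world transform.
    indices : ndarray of int
        Strictly increasing Fortran-order linear indices of masked voxels.
    """

    grid_shape: tuple
    voxel_size: tuple
    affine: np.ndarray
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.intp)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if idx.size < 2:
            raise ValueError("mask must contain at least 2 voxels")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("mask indices must be strictly increasing and unique")
        n_grid = int(np.prod(self.grid_shape))
        if idx[0] < 0 or idx[-1] >= n_grid:
            raise ValueError("mask indices out of grid bounds")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    @classmethod
    def from_array(cls, mask: np.ndarray, affine: np.ndarray | None = None) -> "VoxelMask":
        mask = np.asarray(mask)
        if affine is None:
            affine = np.eye(4)
        affine = np.asarray(affine, dtype=float)
        indices = np.flatnonzero(mask.reshape(-1, order="F") != 0)
        voxel_size = tuple(np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
        return cls(mask.shape, voxel_size, affine, indices)

    @classmethod
    def from_nifti(cls, path) -> "VoxelMask":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        return cls.from_array(data > 0, img.affine)

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Masked voxel values of one 3D volume, in column order."""
        volume = np.asarray(volume)
        if volume.shape != self.grid_shape:
            raise GeometryError(
                f"volume shape {volume.shape} != grid {self.grid_shape}"
            )
        return volume.reshape(-1, order="F")[self.indices]

    def insert(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back onto the 3D grid."""
        values = np.asarray(values)
        if values.shape != (self.n_voxels,):
            raise ValueError("values length must equal number of masked voxels")
        flat = np.full(int(np.prod(self.grid_shape)), fill, dtype=values.dtype)
        flat[self.indices] = values
        return flat.reshape(self.grid_shape, order="F")

    def coordinates(self) -> np.ndarray:
        """(n_voxels, 3) integer grid coordinates of the masked voxels."""
        return np.column_stack(
            np.unravel_index(self.indices, self.grid_shape, order="F")
        )

    def to_nifti(self) -> nib.Nifti1Image:
        vol = self.insert(np.ones(self.n_voxels, dtype=np.int16))
        return nib.Nifti1Image(vol, self.affine)


@dataclass
class JacobianCohort:
    """Subjects x masked-voxels matrix of Jacobian determinants."""

    data: np.ndarray
    mask: VoxelMask
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (subjects x voxels)")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("row count must equal number of subject ids")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError("column count must equal number of masked voxels")
        if not np.all(np.isfinite(self.data)):
            raise DataError("non-finite values in cohort matrix")
        if np.any(self.data <= 0):
            warnings.warn(
                "Jacobian values <= 0 inside the mask; expected for smoothed "
                "edge voxels but worth checking",
                stacklevel=2,
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _check_geometry(img, mask: VoxelMask, path) -> None:
    if tuple(img.shape[:3]) != mask.grid_shape:
        raise GeometryError(
            f"{path}: grid shape {tuple(img.shape[:3])} != mask grid {mask.grid_shape}"
        )
    if not np.allclose(img.affine, mask.affine, atol=AFFINE_TOL):
        raise GeometryError(f"{path}: affine differs from mask affine beyond tolerance")


def load_jacobian_cohort(
    volume_paths: Sequence,
    mask_path,
    subject_ids: Sequence[str] | None = None,
) -> JacobianCohort:
    """Load per-subject Jacobian volumes into a cohort matrix.

    All volumes must share grid shape and affine with the mask (affine entries
    within 1e-4).  Row ``s`` contains volume ``s`` sampled at the masked voxels
    in mask index order.
    """
    mask = VoxelMask.from_nifti(mask_path)
    if subject_ids is None:
        subject_ids = [Path(str(p)).name.split(".")[0] for p in volume_paths]
    rows = []
    for path, sid in zip(volume_paths, subject_ids):
        img = nib.load(str(path))
        _check_geometry(img, mask, path)
        values = mask.extract(np.asarray(img.dataobj, dtype=float))
        if not np.all(np.isfinite(values)):
            raise DataError(f"{path}: non-finite voxel inside mask")
        rows.append(values)
    return JacobianCohort(np.array(rows), mask, list(subject_ids))


def save_cohort_volumes(cohort: JacobianCohort, out_dir) -> list:
    """Write one NIfTI volume per subject (``<subject_id>.nii.gz``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for row, sid in zip(cohort.data, cohort.subject_ids):
        vol = cohort.mask.insert(row)
        img = nib.Nifti1Image(vol.astype(np.float64), cohort.mask.affine)
        path = out_dir / f"{sid}.nii.gz"
        nib.save(img, str(path))
        paths.append(path)
    return paths


def load_cohort_table(path) -> pd.DataFrame:
    """Read the cohort CSV and validate required columns."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"cohort table missing columns: {missing}")
    for col in ("age", "sex", "site", "family"):
        if table[col].isna().any():
            raise DataError(f"cohort table has missing values in '{col}'")
    if table["subject_id"].duplicated().any():
        raise DataError("duplicate subject ids in cohort table")
    return table


def export_label_map(tree, level: int, mask: VoxelMask) -> nib.Nifti1Image:
    """Label volume for one hierarchy level: segment node id per masked voxel.

    Voxels outside the mask are 0; masked voxels in segments that stopped
    early above this level carry their last ancestor's id.
    """
    if not 1 <= level <= tree.depth:
        raise ValueError(f"level {level} out of range 1..{tree.depth}")
    labels = tree.labels_at_level(level, mask.n_voxels)
    vol = mask.insert(labels.astype(np.int32), fill=0)
    return nib.Nifti1Image(vol, mask.affine)


def sample_homogeneity(cohort: JacobianCohort) -> np.ndarray:
    """Per-subject QC score: mean Pearson correlation to every other map."""
    data = cohort.data
    n = data.shape[0]
    if n < 3:
        raise ValueError("sample_homogeneity requires at least 3 subjects")
    sd = data.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateVoxelError(
            f"zero-variance map for subject(s): {[cohort.subject_ids[i] for i in bad]}"
        )
    corr = np.corrcoef(data)
    np.fill_diagonal(corr, 0.0)
    return corr.sum(axis=1) / (n - 1)
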