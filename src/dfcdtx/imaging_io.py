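"""Readers/writers for the imaging-side formats and their consistency checks.

Volumes are NIfTI-1 (optionally gzipped); tables are TSV with a header row.
Loaders are pure functions of the file bytes: identical bytes yield identical
in-memory structures. No resampling is performed anywhere — a BOLD series and
the parcellation used with it must already share grid and affine (checked to
``AFFINE_TOL`` mm).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

AFFINE_TOL = 1e-4
ATLAS_INT_TOL = 1e-6

REQUIRED_SUBJECT_COLUMNS = ("subject_id", "group", "age", "sex")
VALID_GROUPS = ("patient", "control")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclasses.dataclass
class BoldSeries:
    """A single subject's 4D BOLD series.

    data : float array, shape (X, Y, Z, T)
    affine : 4x4 voxel-to-world (MNI mm) transform
    tr : repetition time in seconds
    """

    data: np.ndarray
    affine: np.ndarray
    tr: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise FormatError(
                f"BOLD series must be 4D, got shape {self.data.shape}"
            )
        if self.data.shape[3] < 2:
            raise FormatError("BOLD series needs at least 2 timepoints")
        if self.tr <= 0:
            raise FormatError(f"nonpositive TR: {self.tr}")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise FormatError("affine is singular")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclasses.dataclass
class AtlasParcellation:
    """Integer-labelled parcellation volume; 0 is background."""

    labels: np.ndarray
    affine: np.ndarray
    region_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            rounded = np.rint(labels)
            if np.max(np.abs(labels - rounded)) > ATLAS_INT_TOL:
                raise FormatError(
                    "atlas contains non-integer labels beyond tolerance "
                    f"{ATLAS_INT_TOL}"
                )
            labels = rounded.astype(np.int32)
        self.labels = labels
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels.ndim != 3:
            raise FormatError("atlas volume must be 3D")
        if len(self.region_ids) == 0:
            raise FormatError("atlas has no nonzero labels")

    @property
    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def name_of(self, region_id: int) -> str:
        if self.region_names and region_id in self.region_names:
            return self.region_names[region_id]
        return f"region_{int(region_id)}"


@dataclasses.dataclass
class SubjectTable:
    """Cohort table: one row per subject with group and covariates."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_SUBJECT_COLUMNS if c not in self.table]
        if missing:
            raise FormatError(f"subject table missing columns: {missing}")
        if self.table["subject_id"].duplicated().any():
            raise FormatError("duplicate subject_id values")
        groups = set(self.table["group"])
        if not groups <= set(VALID_GROUPS):
            raise FormatError(
                f"group values must be in {VALID_GROUPS}, got {sorted(groups)}"
            )
        if len(groups) < 2:
            raise FormatError("both groups must be present")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def group_indicator(self) -> np.ndarray:
        """1 for patients, 0 for controls (contrast patient − control)."""
        return (self.table["group"].to_numpy() == "patient").astype(float)

    @property
    def sex_indicator(self) -> np.ndarray:
        return (self.table["sex"].to_numpy() == "M").astype(float)

    def covariate_matrix(self, covariates: tuple[str, ...]) -> np.ndarray:
        cols = []
        for name in covariates:
            if name == "sex":
                cols.append(self.sex_indicator)
            else:
                if name not in self.table:
                    raise FormatError(f"unknown covariate column: {name}")
                cols.append(self.table[name].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(self), 0))


def check_alignment(bold: BoldSeries, atlas: AtlasParcellation) -> None:
    """Reject BOLD/atlas pairs that do not share grid and affine."""
    if bold.grid_shape != atlas.labels.shape:
        raise FormatError(
            f"grid mismatch: BOLD {bold.grid_shape} vs atlas {atlas.labels.shape}"
        )
    if np.max(np.abs(bold.affine - atlas.affine)) > AFFINE_TOL:
        raise FormatError("affine mismatch beyond tolerance; no resampling is done")


def load_bold(path: str | Path, tr: float | None = None,
              subject_id: str | None = None) -> BoldSeries:
    """Load a 4D NIfTI. TR comes from pixdim[4] unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got {data.ndim}D")
    if np.isnan(data).any():
        data = np.nan_to_num(data, nan=0.0)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return BoldSeries(data=data, affine=img.affine, tr=tr, subject_id=subject_id)


def save_bold(bold: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(bold.data.astype(np.float64), bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_atlas(path: str | Path,
               region_names: dict[int, str] | None = None) -> AtlasParcellation:
    img = nib.load(str(path))
    return AtlasParcellation(labels=np.asarray(img.get_fdata()),
                             affine=img.affine, region_names=region_names)


def save_atlas(atlas: AtlasParcellation, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine),
             str(path))


def load_subjects(path: str | Path) -> SubjectTable:
    return SubjectTable(pd.read_csv(path, sep="\t"))


def save_subjects(subjects: SubjectTable, path: str | Path) -> None:
    subjects.table.to_csv(path, sep="\t", index=False)


def write_map(values: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a 3D statistic map as NIfTI."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise FormatError("statistic map must be 3D")
    nib.save(nib.Nifti1Image(values, np.asarray(affine, dtype=np.float64)),
             str(path))


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=np.float64), img.affine
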