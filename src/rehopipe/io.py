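"""Readers and writers for the volume, motion and cohort formats the pipeline touches.

Volumes are NIfTI-1 only (``.nii`` / ``.nii.gz``), read through nibabel.  Voxel
indices are 0-based throughout; world (mm) coordinates are produced only via the
image affine.  Motion traces come as whitespace-delimited 6-column text files in
either the SPM (``rp_*.txt``: translations mm then rotations rad) or FSL
(``.par``: rotations rad then translations mm) column order and are normalised
into a single in-memory representation.  The cohort table is a CSV read into a
pandas DataFrame with light validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("patient", "control")

#: clinical columns that may be absent or partially missing in a cohort CSV
CLINICAL_COLUMNS = (
    "ybocs_total",
    "obsessions",
    "compulsions",
    "hamd",
    "hama",
    "duration_years",
)


@dataclass
class BoldSeries:
    """One subject's 4D BOLD run: ``data[x, y, z, t]`` plus geometry and TR."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        # C-contiguity matters: stage code scatters results through
        # data.reshape(-1, T) views, which silently copy on F-ordered arrays
        # (as returned by nibabel's get_fdata)
        self.data = np.ascontiguousarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D BOLD array, got {self.data.ndim}D")
        if self.data.shape[3] < 3:
            raise ValueError("BOLD series needs at least 3 time points")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if not (self.tr_seconds > 0):
            raise ValueError("tr_seconds must be positive")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Boolean 3D mask on the same grid as the volumes it is applied to."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask has no true voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_geometry(self, other) -> None:
        """Raise if *other* (BoldSeries or 3D map holder) lives on another grid."""
        shape = other.data.shape[:3]
        if shape != self.data.shape:
            raise ValueError(
                f"grid shape mismatch: mask {self.data.shape} vs data {shape}"
            )
        if not np.allclose(self.affine, other.affine, atol=1e-4):
            raise ValueError("affine mismatch between mask and data")


@dataclass
class MotionTrace:
    """Rigid-body motion parameters per frame: T x 3 translations (mm) and rotations (rad)."""

    translations_mm: np.ndarray
    rotations_rad: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_rad = np.atleast_2d(np.asarray(self.rotations_rad, dtype=float))
        if self.translations_mm.shape != self.rotations_rad.shape:
            raise ValueError("translations and rotations must have the same shape")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("motion trace needs 3 translation and 3 rotation axes")
        if not (np.isfinite(self.translations_mm).all() and np.isfinite(self.rotations_rad).all()):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """T x 6 matrix in SPM order (translations then rotations)."""
        return np.hstack([self.translations_mm, self.rotations_rad])


def read_bold(path, tr_fallback_seconds: float | None = None, subject_id: str = "") -> BoldSeries:
    """Load a 4D NIfTI-1 BOLD image.

    TR is taken from header ``pixdim[4]``; if that is not positive,
    ``tr_fallback_seconds`` is used (error if neither is available).  A config
    TR that disagrees with a valid header TR by more than 1 ms wins, with a
    warning (config takes precedence over the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    data = np.asarray(img.get_fdata())
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_fallback_seconds is not None and tr_fallback_seconds > 0:
        if header_tr > 0 and abs(header_tr - tr_fallback_seconds) > 1e-3:
            logger.warning(
                "TR mismatch for %s: header %.4fs vs config %.4fs; using config",
                path, header_tr, tr_fallback_seconds,
            )
        tr = float(tr_fallback_seconds)
    elif header_tr > 0:
        tr = header_tr
    else:
        raise ValueError(f"no TR in header of {path} and no fallback TR configured")
    bad = ~np.isfinite(data)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"non-finite voxel value at index {idx} in {path}")
    return BoldSeries(data=data, affine=img.affine, tr_seconds=tr,
                      subject_id=subject_id or path.name.split(".")[0])


def read_mask(path) -> BrainMask:
    """Load a 3D NIfTI-1 mask (any nonzero voxel counts as inside)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D: {path}")
    return BrainMask(data=data > 0, affine=img.affine)


def write_map(map_data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D map (or boolean mask) as NIfTI-1, float32 for real maps, uint8 for bool."""
    map_data = np.asarray(map_data)
    if map_data.ndim != 3:
        raise ValueError("write_map expects a 3D array")
    if map_data.dtype == bool:
        out = map_data.astype(np.uint8)
    else:
        out = map_data.astype(np.float32)
        if not np.isfinite(out).all():
            raise ValueError("map contains non-finite values")
    img = nib.Nifti1Image(out, np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def write_bold(bold: BoldSeries, path) -> None:
    """Write a BoldSeries as 4D NIfTI-1 with TR recorded in pixdim[4]."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = bold.tr_seconds
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D map; returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"expected 3D map, got {data.ndim}D: {path}")
    return data, img.affine


def read_motion(path, dialect: str = "spm", subject_id: str = "") -> MotionTrace:
    """Read a 6-column rigid-body motion file.

    dialect ``"spm"``: columns 1-3 translations (mm), 4-6 rotations (rad);
    dialect ``"fsl"``: columns 1-3 rotations (rad), 4-6 translations (mm).
    """
    if dialect not in ("spm", "fsl"):
        raise ValueError(f"unknown motion dialect {dialect!r}; expected 'spm' or 'fsl'")
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tokens = line.split()
            if len(tokens) != 6:
                raise ValueError(
                    f"{path}: row {lineno} has {len(tokens)} columns, expected 6"
                )
            try:
                rows.append([float(tok) for tok in tokens])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token in row {lineno}") from exc
    arr = np.array(rows, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{path}: empty motion file")
    if dialect == "spm":
        trans, rot = arr[:, :3], arr[:, 3:]
    else:
        rot, trans = arr[:, :3], arr[:, 3:]
    return MotionTrace(translations_mm=trans, rotations_rad=rot,
                       subject_id=subject_id or path.stem)


def write_motion(motion: MotionTrace, path, dialect: str = "spm") -> None:
    """Write a motion trace in the requested column dialect."""
    if dialect == "spm":
        arr = np.hstack([motion.translations_mm, motion.rotations_rad])
    elif dialect == "fsl":
        arr = np.hstack([motion.rotations_rad, motion.translations_mm])
    else:
        raise ValueError(f"unknown motion dialect {dialect!r}")
    np.savetxt(str(path), arr, fmt="%.10f")


def read_cohort(path) -> pd.DataFrame:
    """Read the cohort CSV (required columns ``id`` and ``group``).

    Clinical columns are optional and missing values are allowed (controls
    typically carry no symptom scores).  Returns a DataFrame with ``id`` as
    plain strings, validated group labels, and a ``qc_pass`` boolean column
    (defaulting to True when absent).
    """
    table = pd.read_csv(path)
    return validate_cohort(table)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    for col in ("id", "group"):
        if col not in table.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    table["id"] = table["id"].astype(str)
    dupes = table["id"][table["id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate subject id(s): {sorted(set(dupes))}")
    bad = set(table["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group label(s) {sorted(bad)}; expected {GROUP_LABELS}")
    if "qc_pass" not in table.columns:
        table["qc_pass"] = True
    table["qc_pass"] = table["qc_pass"].astype(bool)
    for col in CLINICAL_COLUMNS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce")
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
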