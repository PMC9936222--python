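"""Volume/mask loading, background statistics, TBR normalization and the
minimum-voxel eligibility filter.

A case is a PET volume in SUV units together with a lesion mask and a
contralateral background mask on the same voxel grid. TBR (tumor-to-
background ratio) values are SUVs divided by the mean SUV of the
background region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "PETVolume",
    "ROIMask",
    "PatientRecord",
    "Case",
    "load_case",
    "background_stats",
    "tbr_normalize",
    "filter_eligible",
]

DEFAULT_MIN_VOXELS = 64


@dataclass
class PETVolume:
    """3D scalar grid in SUV units with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    def scaled(self, factor: float) -> "PETVolume":
        """Return a copy with all intensities multiplied by ``factor``."""
        return replace(self, data=self.data * factor)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class ROIMask:
    """Binary voxel mask aligned to a PETVolume."""

    data: np.ndarray
    role: Literal["lesion", "background"]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0  # binarize any nonzero coding
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.data.shape}")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self, path: str | Path, affine: np.ndarray | None = None) -> None:
        img = nib.Nifti1Image(
            self.data.astype(np.uint8), np.eye(4) if affine is None else affine
        )
        nib.save(img, str(path))


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: Literal["F", "M"]
    idh: Literal["+", "-"]
    grade: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.idh not in ("+", "-"):
            raise ValueError(f"idh must be '+' or '-', got {self.idh!r}")


@dataclass
class Case:
    """One patient's volume, masks and metadata."""

    record: PatientRecord
    volume: PETVolume
    lesion: ROIMask
    background: ROIMask


def _read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), np.asarray(img.affine)


def load_case(
    volume_path: str | Path,
    lesion_mask_path: str | Path,
    background_mask_path: str | Path,
) -> tuple[PETVolume, ROIMask, ROIMask]:
    """Load and validate a volume/lesion-mask/background-mask triplet.

    Masks are binarized (any nonzero voxel is a member) and must share
    the volume's grid shape; empty masks are rejected.
    """
    vol_data, spacing, affine = _read_nifti(volume_path)
    volume = PETVolume(vol_data, spacing, affine)
    masks = []
    for path, role in ((lesion_mask_path, "lesion"), (background_mask_path, "background")):
        mask_data, _, _ = _read_nifti(path)
        if mask_data.shape != vol_data.shape:
            raise ValueError(
                f"{role} mask shape {mask_data.shape} does not match "
                f"volume shape {vol_data.shape} ({path})"
            )
        mask = ROIMask(mask_data, role)
        if mask.n_voxels == 0:
            raise ValueError(f"{role} mask is empty ({path})")
        masks.append(mask)
    return volume, masks[0], masks[1]


def background_stats(volume: PETVolume, background: ROIMask) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of background SUVs.

    A single-voxel background yields sd 0 with a warning.
    """
    vals = volume.data[background.data]
    if vals.size == 0:
        raise ValueError("background mask is empty")
    if vals.size == 1:
        warnings.warn("single-voxel background region: sd reported as 0", stacklevel=2)
        return float(vals[0]), 0.0
    return float(vals.mean()), float(vals.std(ddof=1))


def tbr_normalize(lesion_values: np.ndarray, background_mean: float) -> np.ndarray:
    """Divide lesion SUVs by the background mean, preserving order."""
    if background_mean <= 0:
        raise ValueError(f"background mean must be > 0, got {background_mean}")
    return np.asarray(lesion_values, dtype=float) / background_mean


def filter_eligible(
    cases: Iterable[Case], min_voxels: int = DEFAULT_MIN_VOXELS
) -> tuple[list[Case], pd.DataFrame]:
    """Keep cases whose lesion has at least ``min_voxels`` voxels.

    Returns the retained cases and an exclusion log (patient_id, reason).
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    retained, excluded = [], []
    for case in cases:
        n = case.lesion.n_voxels
        if n >= min_voxels:
            retained.append(case)
        else:
            excluded.append(
                {
                    "patient_id": case.record.patient_id,
                    "reason": f"lesion has {n} voxels, below minimum {min_voxels}",
                }
            )
    return retained, pd.DataFrame(excluded, columns=["patient_id", "reason"])
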