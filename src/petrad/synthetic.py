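"""Synthetic MET-PET cohort generation.

Generates per-patient SUV volumes with one spherical lesion inside an
ellipsoidal "brain" of background uptake, plus a mirrored contralateral
background reference sphere. Subgroup intensity distributions are
moment-targeted: each sex x IDH cell has a between-patient distribution
of per-lesion mean SUV and a within-lesion coefficient of variation and
skewness target, so that downstream histogram and texture analyses see
group differences of the kind observed in real amino-acid PET cohorts.

Within-lesion voxel values are drawn from a shifted gamma family whose
closed-form moments hit the mean/CV/skewness targets exactly in
population (gamma shape k = 4/skew^2; reflected for negative skewness;
a normal is used when the skewness target is 0).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .io import Case, PatientRecord, PETVolume, ROIMask

__all__ = [
    "SubgroupProfile",
    "CohortSpec",
    "build_default_cohort_spec",
    "sample_lesion_intensities",
    "generate_cohort",
]

_MIN_SUV = 1e-6


@dataclass(frozen=True)
class SubgroupProfile:
    """Intensity targets for one sex x IDH cell.

    ``lesion_suv_mean``/``lesion_suv_sd`` describe the between-patient
    distribution of per-lesion mean SUV; ``lesion_cv`` and
    ``lesion_skew`` are within-lesion voxel-distribution targets;
    the background pair describes the contralateral reference region.
    """

    sex: str
    idh: str
    n_patients: int
    lesion_suv_mean: float
    lesion_suv_sd: float
    lesion_cv: float
    lesion_skew: float
    background_suv_mean: float
    background_suv_sd: float

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.lesion_suv_mean <= 0 or self.background_suv_mean <= 0:
            raise ValueError("mean SUVs must be positive")
        if self.lesion_cv < 0:
            raise ValueError("lesion_cv must be >= 0")


@dataclass
class CohortSpec:
    """Full recipe for one synthetic cohort."""

    profiles: list[SubgroupProfile]
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_radius_range: tuple[int, int] = (4, 7)
    smoothing_sigma: float = 1.0
    background_within_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        cells = {(p.sex, p.idh) for p in self.profiles}
        expected = {("F", "+"), ("F", "-"), ("M", "+"), ("M", "-")}
        if cells != expected:
            raise ValueError(f"profiles must cover all four sex x IDH cells, got {cells}")
        rmin, rmax = self.lesion_radius_range
        if rmin < 2 or rmax < rmin:
            raise ValueError("invalid lesion_radius_range")
        if 2 * rmax + 2 >= min(self.grid_shape):
            raise ValueError("largest lesion does not fit in the grid")

    @property
    def n_patients(self) -> int:
        return sum(p.n_patients for p in self.profiles)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["profiles"] = [asdict(p) for p in self.profiles]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text())
        profiles = [SubgroupProfile(**p) for p in doc.pop("profiles")]
        for key in ("grid_shape", "voxel_spacing", "lesion_radius_range"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(profiles=profiles, **doc)


def build_default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default 35-patient cohort: 13 F (6 IDH+), 22 M (8 IDH+).

    Cell-level targets: per-lesion mean SUV 1.20/1.78/1.40/1.38 and
    background SUV 1.19/1.11/1.15/1.03 for F+/F-/M+/M- respectively,
    with within-lesion CV 0.264/0.440/0.308/0.385 and skewness
    -0.327/0.483/-0.123/0.519.
    """
    profiles = [
        SubgroupProfile("F", "+", 6, 1.20, 0.26, 0.264, -0.327, 1.19, 0.31),
        SubgroupProfile("F", "-", 7, 1.78, 0.64, 0.440, 0.483, 1.11, 0.16),
        SubgroupProfile("M", "+", 8, 1.40, 0.25, 0.308, -0.123, 1.15, 0.16),
        SubgroupProfile("M", "-", 14, 1.38, 0.31, 0.385, 0.519, 1.03, 0.16),
    ]
    return CohortSpec(profiles=profiles, seed=seed, **overrides)


def sample_lesion_intensities(
    n_voxels: int,
    mean: float,
    cv: float,
    skew: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Draw voxel SUVs with target mean, coefficient of variation and skewness.

    Uses a standardized gamma deviate (shape k = 4/skew^2, skewness
    2/sqrt(k) = |skew|), reflected for negative skewness, scaled to
    sd = mean*cv and shifted to the mean; a normal replaces the gamma
    when skew == 0. Values are clipped to stay positive.

    Returns
    -------
    (values, clip_rate)
        The sampled values and the fraction of voxels that hit the
        positivity clip.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cv == 0:
        return np.full(n_voxels, float(mean)), 0.0
    if skew == 0:
        z = rng.standard_normal(n_voxels)
    else:
        k = 4.0 / skew**2
        z = (rng.gamma(k, 1.0, size=n_voxels) - k) / np.sqrt(k)
        if skew < 0:
            z = -z
    x = mean + mean * cv * z
    clipped = x < _MIN_SUV
    x[clipped] = _MIN_SUV
    return x, float(clipped.mean())


def _sphere_mask(shape: Sequence[int], center: Sequence[int], radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius**2


def _ellipsoid_mask(shape: Sequence[int]) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    semi = [0.46 * s for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    # redraw rather than clip so the between-patient spread is preserved
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return max(float(mean), lo)


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[list[Case], pd.DataFrame]:
    """Generate the synthetic cohort described by ``spec``.

    Returns the cases and a cohort table (patient_id, sex, idh, grade,
    and file paths when ``out_dir`` is given). Fixed ``spec.seed``
    yields bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    brain = _ellipsoid_mask(shape)
    cx = shape[0] // 2
    cases: list[Case] = []
    rows: list[dict] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    pid = 0
    rmin, rmax = spec.lesion_radius_range
    for profile in spec.profiles:
        for _ in range(profile.n_patients):
            pid += 1
            patient_id = f"P{pid:03d}"
            radius = int(rng.integers(rmin, rmax + 1))
            bg_radius = max(radius, 4)
            jitter = rng.integers(-2, 3, size=3)
            # lesion in one hemisphere, background mirrored contralaterally;
            # clamp the lesion centre so the mirrored spheres cannot touch
            lx = cx // 2 + 1 + int(jitter[0])
            lx = max(radius + 2, min(lx, (shape[0] - 3 - radius - bg_radius) // 2))
            lesion_center = np.array(
                [lx, shape[1] // 2 + int(jitter[1]), shape[2] // 2 + int(jitter[2])]
            )
            bg_center = lesion_center.copy()
            bg_center[0] = shape[0] - 1 - lesion_center[0]

            lesion_mask = _sphere_mask(shape, lesion_center, radius) & brain
            bg_mask = _sphere_mask(shape, bg_center, bg_radius) & brain

            bg_mean = _truncated_normal(
                rng, profile.background_suv_mean, profile.background_suv_sd, 0.05
            )
            lesion_mean = _truncated_normal(
                rng, profile.lesion_suv_mean, profile.lesion_suv_sd, 0.05
            )

            vol = np.zeros(shape)
            n_brain = int(brain.sum())
            vol[brain] = np.maximum(
                rng.normal(bg_mean, spec.background_within_cv * bg_mean, size=n_brain),
                _MIN_SUV,
            )
            lesion_vals, _ = sample_lesion_intensities(
                int(lesion_mask.sum()), lesion_mean, profile.lesion_cv,
                profile.lesion_skew, rng,
            )
            vol[lesion_mask] = lesion_vals
            if spec.smoothing_sigma > 0:
                vol = gaussian_filter(vol, spec.smoothing_sigma)

            volume = PETVolume(vol, spec.voxel_spacing)
            record = PatientRecord(patient_id, profile.sex, profile.idh)
            case = Case(
                record,
                volume,
                ROIMask(lesion_mask, "lesion"),
                ROIMask(bg_mask, "background"),
            )
            if case.lesion.n_voxels == 0 or case.background.n_voxels == 0:
                raise RuntimeError(f"empty mask generated for {patient_id}")
            if (lesion_mask & bg_mask).any():
                raise RuntimeError(f"overlapping masks for {patient_id}")
            cases.append(case)

            row = {"patient_id": patient_id, "sex": profile.sex, "idh": profile.idh,
                   "grade": ""}
            if out_path is not None:
                vp = out_path / f"{patient_id}_suv.nii.gz"
                lp = out_path / f"{patient_id}_lesion.nii.gz"
                bp = out_path / f"{patient_id}_background.nii.gz"
                volume.to_nifti(vp)
                case.lesion.to_nifti(lp, volume.affine)
                case.background.to_nifti(bp, volume.affine)
                row.update(
                    volume_path=vp.name, lesion_mask_path=lp.name,
                    background_mask_path=bp.name,
                )
            rows.append(row)

    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path / "cohort.csv", index=False)
        spec.to_yaml(out_path / "cohort_spec.yaml")
    return cases, table
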