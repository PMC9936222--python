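from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from petrad.io import Case, PatientRecord, PETVolume, ROIMask
from petrad.synthetic import build_default_cohort_spec, generate_cohort


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230203)


@pytest.fixture(scope="session")
def default_cohort():
    """The default 35-patient synthetic cohort, shared across tests."""
    spec = build_default_cohort_spec(seed=7)
    cases, table = generate_cohort(spec)
    return cases, table


def make_case(
    intensities: np.ndarray,
    patient_id: str = "P001",
    sex: str = "F",
    idh: str = "+",
    spacing=(2.0, 2.0, 2.0),
) -> Case:
    """Wrap a 3D array as a case whose lesion covers every voxel and
    whose background is a constant-1 border slab."""
    vol = np.asarray(intensities, dtype=float)
    padded = np.pad(vol, ((0, 0), (0, 0), (0, 2)), constant_values=1.0)
    lesion = np.zeros(padded.shape, dtype=bool)
    lesion[:, :, : vol.shape[2]] = True
    background = np.zeros(padded.shape, dtype=bool)
    background[:, :, vol.shape[2] :] = True
    return Case(
        PatientRecord(patient_id, sex, idh),
        PETVolume(padded, spacing),
        ROIMask(lesion, "lesion"),
        ROIMask(background, "background"),
    )
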