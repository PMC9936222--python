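"""Synthetic cohort generator: defaults, moment targeting, determinism."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from petrad.features import statistical_features
from petrad.synthetic import (
    CohortSpec,
    SubgroupProfile,
    build_default_cohort_spec,
    generate_cohort,
    sample_lesion_intensities,
)


class TestDefaultSpec:
    def test_cohort_composition(self):
        spec = build_default_cohort_spec()
        assert spec.n_patients == 35
        by_cell = {(p.sex, p.idh): p for p in spec.profiles}
        assert sum(p.n_patients for p in spec.profiles if p.sex == "F") == 13
        assert sum(p.n_patients for p in spec.profiles if p.sex == "M") == 22
        assert sum(p.n_patients for p in spec.profiles if p.idh == "+") == 14
        assert by_cell[("F", "+")].n_patients == 6
        assert by_cell[("M", "+")].n_patients == 8

    def test_cell_intensity_targets(self):
        by_cell = {(p.sex, p.idh): p for p in build_default_cohort_spec().profiles}
        assert by_cell[("F", "+")].lesion_suv_mean == 1.20
        assert by_cell[("F", "-")].lesion_suv_mean == 1.78
        assert by_cell[("M", "+")].lesion_suv_mean == 1.40
        assert by_cell[("M", "-")].lesion_suv_mean == 1.38
        assert by_cell[("F", "+")].background_suv_sd == 0.31
        assert by_cell[("F", "+")].lesion_skew == -0.327
        assert by_cell[("M", "+")].lesion_skew == -0.123
        assert by_cell[("F", "-")].lesion_skew == 0.483
        assert by_cell[("M", "-")].lesion_skew == 0.519

    def test_yaml_roundtrip(self, tmp_path):
        spec = build_default_cohort_spec(seed=5)
        spec.to_yaml(tmp_path / "spec.yaml")
        back = CohortSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec

    def test_all_cells_required(self):
        with pytest.raises(ValueError, match="four"):
            CohortSpec(profiles=build_default_cohort_spec().profiles[:3])


class TestIntensitySampler:
    def test_symmetric_targets_recovered(self):
        x, clip = sample_lesion_intensities(10**5, 1.20, 0.26, 0.0, seed=3)
        assert x.mean() == pytest.approx(1.20, rel=0.01)
        assert abs(stats.skew(x)) < 0.05
        assert clip < 0.01

    def test_gamma_skew_target(self):
        # skew 2 -> gamma shape k = 1 (exponential-like tail)
        x, _ = sample_lesion_intensities(10**5, 1.0, 0.5, 2.0, seed=4)
        assert stats.skew(x) == pytest.approx(2.0, abs=0.1)
        assert x.std() / x.mean() == pytest.approx(0.5, rel=0.03)

    def test_negative_skew_by_reflection(self):
        x, _ = sample_lesion_intensities(10**5, 2.0, 0.2, -1.0, seed=5)
        assert stats.skew(x) == pytest.approx(-1.0, abs=0.1)

    def test_zero_variance_is_constant(self):
        x, clip = sample_lesion_intensities(10, 1.0, 0.0, 0.0, seed=6)
        np.testing.assert_array_equal(x, np.ones(10))
        assert clip == 0.0

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            sample_lesion_intensities(0, 1.0, 0.1, 0.0, seed=0)
        with pytest.raises(ValueError):
            sample_lesion_intensities(10, -1.0, 0.1, 0.0, seed=0)


class TestGenerateCohort:
    def test_default_cohort_shape(self, default_cohort):
        cases, table = default_cohort
        assert len(cases) == 35
        ids = [c.record.patient_id for c in cases]
        assert len(set(ids)) == 35
        for case in cases:
            assert case.lesion.n_voxels > 0
            assert case.background.n_voxels > 0
        assert set(table.columns) >= {"patient_id", "sex", "idh"}

    def test_masks_disjoint(self, default_cohort):
        cases, _ = default_cohort
        for case in cases:
            assert not (case.lesion.data & case.background.data).any()

    def test_fixed_seed_bit_identical(self):
        spec = build_default_cohort_spec(seed=123)
        c1, t1 = generate_cohort(spec)
        c2, t2 = generate_cohort(build_default_cohort_spec(seed=123))
        assert t1.equals(t2)
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.volume.data, b.volume.data)
            np.testing.assert_array_equal(a.lesion.data, b.lesion.data)

    def test_nifti_export(self, tmp_path):
        spec = build_default_cohort_spec(seed=1)
        spec.profiles = [
            SubgroupProfile(p.sex, p.idh, 1, p.lesion_suv_mean, p.lesion_suv_sd,
                            p.lesion_cv, p.lesion_skew, p.background_suv_mean,
                            p.background_suv_sd)
            for p in spec.profiles
        ]
        _, table = generate_cohort(spec, out_dir=tmp_path)
        assert (tmp_path / "cohort.csv").exists()
        assert (tmp_path / "cohort_spec.yaml").exists()
        assert all((tmp_path / p).exists() for p in table["volume_path"])

    def test_moment_recovery_unsmoothed(self):
        """With smoothing off and large lesions, per-lesion sample skewness
        averages to the subgroup target."""
        spec = build_default_cohort_spec(seed=9, smoothing_sigma=0.0,
                                         lesion_radius_range=(7, 7))
        target = {(p.sex, p.idh): p.lesion_skew for p in spec.profiles}
        reps = 6  # 6 x 35 patients pooled by cell
        skews: dict[tuple, list] = {k: [] for k in target}
        for rep in range(reps):
            spec_r = build_default_cohort_spec(seed=9 + rep, smoothing_sigma=0.0,
                                               lesion_radius_range=(7, 7))
            cases, _ = generate_cohort(spec_r)
            for case in cases:
                vals = case.volume.data[case.lesion.data]
                skews[(case.record.sex, case.record.idh)].append(
                    statistical_features(vals)["stat.skew"]
                )
        for cell, observed in skews.items():
            assert np.mean(observed) == pytest.approx(target[cell], abs=0.1), cell
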