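"""R^2 ranking, occurrence rules, Mann-Whitney and Bonferroni logic."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrad.io import PatientRecord
from petrad.ranking import (
    bonferroni_threshold,
    high_ranking,
    mwu_test,
    occurrence_rates,
    r2_scores,
    select_top_k,
    subgroup_summary,
)

from .oracles import mwu_enumerate


class TestR2:
    def test_feature_equal_to_label(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 0.0, 1.0]})
        assert r2_scores(X, ["a", "b", "a", "b"])["f"] == pytest.approx(1.0)

    def test_worked_example(self):
        X = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]})
        # r = 0.25 / sqrt(1.25 * 0.25) -> R^2 = 0.2
        assert r2_scores(X, [0, 1, 0, 1])["f"] == pytest.approx(0.2)

    def test_constant_feature_zero(self):
        X = pd.DataFrame({"f": [2.0, 2.0, 2.0, 2.0]})
        assert r2_scores(X, [0, 1, 0, 1])["f"] == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            r2_scores(pd.DataFrame({"f": [1.0, 2.0]}), ["a", "a"])

    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 50),
    )
    @settings(max_examples=40, deadline=None)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(20)
        y = rng.integers(0, 2, size=20)
        y[:2] = [0, 1]
        a = r2_scores(pd.DataFrame({"f": x}), y)["f"]
        b = r2_scores(pd.DataFrame({"f": x * scale + shift}), y)["f"]
        assert b == pytest.approx(a, rel=1e-6, abs=1e-9)


class TestSelection:
    def test_top_k_largest(self):
        scores = pd.Series({f"f{i}": i / 10 for i in range(10)})
        assert set(select_top_k(scores, 6)) == {f"f{i}" for i in range(4, 10)}

    def test_tie_broken_by_manifest_order(self):
        scores = pd.Series({"ih.cov": 0.5, "stat.skew": 0.5, "szm.lze": 0.9})
        top = select_top_k(scores, 2)
        # stat.skew precedes ih.cov in the manifest
        assert top == ["szm.lze", "stat.skew"]

    def test_k_equals_feature_count(self):
        scores = pd.Series({"a": 0.1, "b": 0.9})
        assert select_top_k(scores, 2) == ["b", "a"]

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            select_top_k(pd.Series({"a": 0.1}), 6)


class TestOccurrence:
    def test_rates_and_strict_threshold(self):
        sels = [["a", "b"]] * 90 + [["a", "c"]] * 10
        rates = occurrence_rates(sels)
        assert rates["a"] == 1.0
        assert rates["b"] == 0.90
        assert rates["c"] == 0.10
        hr = high_ranking(rates, 0.90)
        assert hr == ["a"]  # 0.90 is NOT higher than 90%
        assert set(high_ranking(rates, 0.90, strict=False)) == {"a", "b"}

    def test_empty_selection_set(self):
        with pytest.raises(ValueError):
            occurrence_rates([])

    def test_no_feature_above_threshold(self):
        rates = occurrence_rates([["a"], ["b"]])
        assert high_ranking(rates, 0.90) == []


class TestMWU:
    def test_disjoint_groups_exact(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of 20 assignments as extreme

    def test_identical_groups(self):
        u, p = mwu_test([1, 2], [1, 2])
        assert u == 2.0
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mwu_test([], [1.0])

    def test_exact_path_matches_enumeration(self, rng):
        """All group-size combinations with n_a + n_b <= 10, random
        tie-free data, against full enumeration."""
        for na in range(1, 6):
            for nb in range(na, 11 - na):
                for _ in range(3):
                    pooled = rng.permutation(np.arange(na + nb, dtype=float) * 1.37)
                    a, b = pooled[:na], pooled[na:]
                    u_impl, p_impl = mwu_test(a, b)
                    u_ref, p_ref = mwu_enumerate(a, b)
                    assert u_impl == u_ref, (na, nb)
                    assert p_impl == pytest.approx(p_ref, rel=1e-12), (na, nb)


class TestBonferroni:
    def test_factor_31(self):
        t, displayed = bonferroni_threshold(0.05, 31)
        assert t == pytest.approx(0.05 / 31)
        assert displayed == 0.0016

    def test_identity_correction(self):
        assert bonferroni_threshold(0.05, 1) == (0.05, 0.05)

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 3)


class TestSubgroupSummary:
    def _records(self):
        return [
            PatientRecord("P1", "F", "+"), PatientRecord("P2", "F", "+"),
            PatientRecord("P3", "F", "-"),
            PatientRecord("P4", "M", "+"), PatientRecord("P5", "M", "-"),
            PatientRecord("P6", "M", "-"),
        ]

    def test_cell_means_and_single_patient_sd(self, rng):
        recs = self._records()
        ids = [r.patient_id for r in recs]
        X = pd.DataFrame({"stat.skew": rng.standard_normal(6)}, index=ids)
        out = subgroup_summary({"SUV": X}, recs, ["stat.skew"])
        cell = out[(out.sex == "F") & (out.idh == "+")].iloc[0]
        assert cell["n"] == 2
        assert cell["mean"] == pytest.approx(X.loc[["P1", "P2"], "stat.skew"].mean())
        lone = out[(out.sex == "F") & (out.idh == "-")].iloc[0]
        assert lone["n"] == 1 and np.isnan(lone["sd"])

    def test_skew_identical_across_datasets(self, rng):
        recs = self._records()
        ids = [r.patient_id for r in recs]
        skew = rng.standard_normal(6)
        tables = {
            "SUV": pd.DataFrame({"stat.skew": skew}, index=ids),
            "TBR": pd.DataFrame({"stat.skew": skew}, index=ids),
        }
        out = subgroup_summary(tables, recs, ["stat.skew"])
        suv = out[out.dataset == "SUV"].set_index(["sex", "idh"])["mean"]
        tbr = out[out.dataset == "TBR"].set_index(["sex", "idh"])["mean"]
        pd.testing.assert_series_equal(suv, tbr, check_names=False)
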