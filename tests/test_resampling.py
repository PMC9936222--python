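"""Monte-Carlo split plans, Tomek borderline and isolation-forest scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from petrad.io import PatientRecord
from petrad.resampling import (
    iforest_outlier,
    make_mc_splits,
    score_folds,
    tomek_borderline,
)

from .oracles import tomek_score_brute


def _records(n_f=13, n_m=22, idh_f=6, idh_m=8):
    recs = []
    for i in range(n_f):
        recs.append(PatientRecord(f"F{i:02d}", "F", "+" if i < idh_f else "-"))
    for i in range(n_m):
        recs.append(PatientRecord(f"M{i:02d}", "M", "+" if i < idh_m else "-"))
    return recs


class TestSplitPlan:
    def test_100_fold_contract(self):
        plan = make_mc_splits(_records(), "sex", n_folds=100, seed=3)
        assert plan.n_folds == 100
        holdouts = set()
        for train, holdout in plan.folds:
            assert len(holdout) == 2
            sexes = {h[0] for h in holdout}  # ids encode class here
            assert sexes == {"F", "M"}
            assert len(train) == 33
            assert set(train) | set(holdout) == {r.patient_id for r in _records()}
            assert not set(train) & set(holdout)
            holdouts.add(tuple(sorted(holdout)))
        assert len(holdouts) == 100  # no repeated configuration

    def test_exhaustive_enumeration_when_saturated(self):
        recs = [
            PatientRecord("A1", "F", "+"), PatientRecord("A2", "F", "-"),
            PatientRecord("B1", "M", "+"), PatientRecord("B2", "M", "-"),
        ]
        plan = make_mc_splits(recs, "sex", n_folds=4, seed=0)
        assert {tuple(sorted(h)) for _, h in plan.folds} == {
            ("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2")
        }

    def test_pigeonhole_error(self):
        recs = [PatientRecord("A", "F", "+"), PatientRecord("B", "M", "-")]
        with pytest.raises(ValueError, match="distinct"):
            make_mc_splits(recs, "sex", n_folds=2, seed=0)

    def test_idh_labeling(self):
        plan = make_mc_splits(_records(), "idh", n_folds=50, seed=1)
        idh = {r.patient_id: r.idh for r in _records()}
        for _, holdout in plan.folds:
            assert {idh[h] for h in holdout} == {"+", "-"}


class TestTomekBorderline:
    def test_single_link_half(self):
        X = np.array([[0.0], [3.0], [1.0], [10.0]])
        y = np.array(["a", "a", "b", "b"])
        # only (0, 1) are mutual nearest neighbours with opposite labels
        assert tomek_borderline(X, y, standardize=False) == 0.5

    def test_separated_classes_score_zero(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array(["a", "a", "b", "b"])
        assert tomek_borderline(X, y) == 0.0

    def test_one_per_class_always_linked(self):
        X = np.array([[0.0], [5.0]])
        assert tomek_borderline(X, np.array(["a", "b"])) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tomek_borderline(np.zeros((3, 2)), np.array(["a", "a", "a"]))

    def test_matches_brute_force_oracle(self, rng):
        """50 random instances with n <= 20 against the O(n^2) oracle."""
        for _ in range(50):
            n = int(rng.integers(4, 21))
            X = rng.standard_normal((n, int(rng.integers(1, 6))))
            y = rng.integers(0, 2, size=n)
            if len(set(y.tolist())) < 2:
                y[0] = 1 - y[0]
            assert tomek_borderline(X, y) == tomek_score_brute(X, y)

    def test_scale_invariance_through_zscoring(self, rng):
        X = rng.standard_normal((12, 4))
        y = rng.integers(0, 2, size=12)
        y[:2] = [0, 1]
        assert tomek_borderline(X, y) == tomek_borderline(X * 37.5, y)


class TestIsolationForest:
    def test_identical_samples_equal_scores(self):
        scores, _ = iforest_outlier(np.ones((8, 3)), seed=0)
        assert np.allclose(scores, scores[0])

    def test_far_point_has_max_score(self, rng):
        """A clear outlier earns the maximum score in >= 95% of seeds."""
        hits = 0
        X = np.vstack([rng.standard_normal((20, 2)) * 0.1, [[8.0, 8.0]]])
        for seed in range(100):
            scores, _ = iforest_outlier(X, seed=seed, n_trees=50)
            hits += int(np.argmax(scores) == 20)
        assert hits >= 95

    def test_scores_strictly_in_unit_interval(self, rng):
        scores, mean = iforest_outlier(rng.standard_normal((30, 5)), seed=1)
        assert (scores > 0).all() and (scores < 1).all()
        assert 0 < mean < 1

    def test_reproducible_under_seed(self, rng):
        X = rng.standard_normal((15, 3))
        s1, m1 = iforest_outlier(X, seed=42)
        s2, m2 = iforest_outlier(X, seed=42)
        np.testing.assert_array_equal(s1, s2)
        assert m1 == m2

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            iforest_outlier(np.zeros((1, 2)), seed=0)


class TestScoreFolds:
    def test_aligned_scores_table(self, rng):
        recs = _records(4, 4, 2, 2)
        ids = [r.patient_id for r in recs]
        tables = {
            tag: pd.DataFrame(rng.standard_normal((8, 5)), index=ids)
            for tag in ("SUV", "TBR")
        }
        plan = make_mc_splits(recs, "sex", n_folds=6, seed=0)
        labels = {r.patient_id: r.sex for r in recs}
        scores = score_folds(tables, plan, labels, seed=5)
        assert len(scores) == 12  # 6 folds x 2 datasets
        assert set(scores["dataset"]) == {"SUV", "TBR"}
        assert scores["borderline"].between(0, 1).all()
        assert scores["outlier"].between(0, 1, inclusive="neither").all()
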