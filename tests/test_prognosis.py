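import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoprog.prognosis import (
    CaseRecord,
    EmptyCaseError,
    GroupAssignmentWarning,
    QUADRANT_TIMING,
    RecurrenceModel,
    UnlearnableError,
    assign_group,
    build_label_sets,
    combine_horizons,
    split_cohort,
    train_horizon_model,
)


class TestAssignGroup:
    @pytest.mark.parametrize(
        "recurrence,months,expected",
        [
            (True, 36, "A"),
            (True, 60, "A"),
            (True, 61, "B"),
            (True, 120, "B"),
            (False, 60, "C"),
            (False, 120, "C"),
            (False, 121, "D"),
            (False, 150, "D"),
            (False, 48, None),  # censored before 5 years: excluded
        ],
    )
    def test_group_boundaries(self, recurrence, months, expected):
        assert assign_group(recurrence, months) == expected

    def test_recurrence_after_ten_years_excluded_with_warning(self):
        with pytest.warns(GroupAssignmentWarning):
            assert assign_group(True, 145) is None

    def test_nonpositive_months_rejected(self):
        with pytest.raises(ValueError):
            assign_group(False, 0)


def _case(group, n_rois=2, n_feat=4, seed=0, offset=0.0):
    months = {"A": 30, "B": 90, "C": 90, "D": 150}[group]
    rec = group in ("A", "B")
    rng = np.random.default_rng(seed)
    return CaseRecord(
        case_id=f"{group}{seed}",
        recurrence=rec,
        months=months,
        roi_vectors=rng.standard_normal((n_rois, n_feat)) + offset,
    )


class TestLabelSets:
    def test_five_year_labels(self):
        cases = [_case(g) for g in "ABCD"]
        labels = {c.group: lab for c, lab in build_label_sets(cases, "5y")}
        assert labels == {"A": 1, "B": 0, "C": 0, "D": 0}

    def test_ten_year_labels_with_unlabeled_c(self):
        cases = [_case(g) for g in "ABCD"]
        labels = {c.group: lab for c, lab in build_label_sets(cases, "10y")}
        assert labels == {"A": 1, "B": 1, "C": None, "D": 0}


class TestSplit:
    def _cohort(self, sizes={"A": 40, "B": 22, "C": 37, "D": 32}):
        return [
            _case(g, seed=i) for g, n in sizes.items() for i in range(n)
        ]

    def test_partition_property(self):
        cases = self._cohort({"A": 1, "B": 1, "C": 1, "D": 1})
        train, test = split_cohort(cases, 0.25, seed=0)
        ids = sorted(c.case_id for c in train + test)
        assert ids == sorted(c.case_id for c in cases)

    def test_seed_reproducibility(self):
        cases = self._cohort()
        a = split_cohort(cases, 0.25, seed=42)
        b = split_cohort(cases, 0.25, seed=42)
        assert [c.case_id for c in a[0]] == [c.case_id for c in b[0]]
        assert [c.case_id for c in a[1]] == [c.case_id for c in b[1]]

    def test_study_counts_with_configured_composition(self):
        cases = self._cohort()
        train, test = split_cohort(
            cases, seed=1, test_counts={"A": 10, "B": 4, "C": 9, "D": 8}
        )
        assert len(test) == 31 and len(train) == 100
        # 5-year model: A positive (40 = 30 train + 10 test),
        # B/C/D negative (91 = 70 train + 21 test)
        assert sum(c.group == "A" for c in train) == 30
        assert sum(c.group == "A" for c in test) == 10
        assert sum(c.group != "A" for c in train) == 70
        assert sum(c.group != "A" for c in test) == 21

    def test_empty_group_warns_and_passes_through(self):
        cases = self._cohort({"A": 3, "B": 2, "C": 2, "D": 1})
        cases = [c for c in cases if c.group != "B"]
        with pytest.warns(UserWarning, match="group B"):
            train, test = split_cohort(cases, 0.25, seed=0)
        assert len(train) + len(test) == len(cases)


class TestHorizonModel:
    def _separable(self, n_per_class=20, gap=5.0, seed=0):
        rng = np.random.default_rng(seed)
        X0 = rng.standard_normal((n_per_class, 6))
        X1 = rng.standard_normal((n_per_class, 6)) + gap
        X = np.vstack([X0, X1])
        y = np.array([0] * n_per_class + [1] * n_per_class)
        return X, y

    def test_separable_training_accuracy_is_100(self):
        X, y = self._separable()
        res = train_horizon_model(X, y, "5y")
        assert res.train_roi_confusion.accuracy_pct == 100.0

    def test_single_class_unlearnable(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(UnlearnableError):
            train_horizon_model(X, np.ones(10), "5y")

    def test_decision_function_is_affine(self):
        X, y = self._separable()
        res = train_horizon_model(X, y, "5y")
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((2, 6))
        lhs = res.decision_function(((a + b) / 2)[None])[0]
        rhs = (res.decision_function(a[None])[0] + res.decision_function(b[None])[0]) / 2
        assert lhs == pytest.approx(rhs, abs=1e-8)

    def test_duplicating_rois_keeps_boundary(self):
        X, y = self._separable()
        res1 = train_horizon_model(X, y, "5y")
        res2 = train_horizon_model(np.vstack([X, X]), np.concatenate([y, y]), "5y")
        w1 = res1.coef_ / np.linalg.norm(res1.coef_)
        w2 = res2.coef_ / np.linalg.norm(res2.coef_)
        assert float(w1 @ w2) > 0.99

    def test_permuted_labels_near_majority_rate(self):
        # destroy the signal; held-out accuracy falls to the majority rate
        rng = np.random.default_rng(7)
        X, y = self._separable(n_per_class=60, gap=3.0, seed=7)
        y_perm = rng.permutation(y)
        train_idx = rng.permutation(120)[:80]
        test_idx = np.setdiff1d(np.arange(120), train_idx)
        res = train_horizon_model(X[train_idx], y_perm[train_idx], "5y")
        pred = res.predict_roi_proba(X[test_idx]) > 0.5
        acc = float((pred == y_perm[test_idx]).mean())
        majority = max(y_perm[test_idx].mean(), 1 - y_perm[test_idx].mean())
        assert abs(acc - majority) < 0.2

    def test_predict_case_is_mean_of_roi_probabilities(self):
        X, y = self._separable()
        res = train_horizon_model(X, y, "5y")
        case = _case("A", n_rois=3, n_feat=6, seed=5)
        p, call = res.predict_case(case)
        probs = res.predict_roi_proba(case.roi_vectors)
        assert p == pytest.approx(float(probs.mean()))
        assert min(probs) <= p <= max(probs)
        assert call == (p > 0.5)

    def test_empty_case_rejected(self):
        X, y = self._separable()
        res = train_horizon_model(X, y, "5y")
        case = CaseRecord(case_id="x", recurrence=True, months=30)
        with pytest.raises(EmptyCaseError):
            res.predict_case(case)

    def test_summary_mentions_horizon_and_accuracy(self):
        X, y = self._separable()
        res = train_horizon_model(X, y, "10y")
        text = res.summary()
        assert "10y" in text and "accuracy" in text


class TestCombineHorizons:
    @pytest.mark.parametrize(
        "p5,p10,quadrant,timing",
        [
            (0.8, 0.9, "Q1", "recur_within_5y"),
            (0.3, 0.7, "Q2", "recur_5_to_10y"),
            (0.2, 0.1, "Q3", "recurrence_free_10y"),
            (0.7, 0.2, "Q4", "contradictory"),
            (0.5, 0.5, "Q3", "recurrence_free_10y"),  # exactly 0.50: no recurrence
        ],
    )
    def test_quadrant_mapping(self, p5, p10, quadrant, timing):
        dual = combine_horizons("c", p5, p10)
        assert dual.quadrant == quadrant
        assert dual.predicted_timing == timing

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            combine_horizons("c", 1.2, 0.5)
        with pytest.raises(ValueError):
            combine_horizons("c", 0.5, -0.1)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.floats(0, 1), st.floats(0, 1))
def test_quadrants_partition_unit_square(p5, p10):
    """Every probability pair maps to exactly one quadrant category."""
    dual = combine_horizons("c", p5, p10)
    memberships = [
        p5 > 0.5 and p10 > 0.5,
        p5 <= 0.5 and p10 > 0.5,
        p5 <= 0.5 and p10 <= 0.5,
        p5 > 0.5 and p10 <= 0.5,
    ]
    assert sum(memberships) == 1
    assert dual.quadrant == ["Q1", "Q2", "Q3", "Q4"][memberships.index(True)]
    assert dual.predicted_timing == QUADRANT_TIMING[dual.quadrant]


class TestRoiLabelInheritance:
    def test_from_cases_stacks_labeled_rois(self):
        cases = [_case(g, n_rois=3) for g in "ABCD"]
        m5 = RecurrenceModel.from_cases(cases, "5y")
        assert m5.X.shape == (12, 4)
        assert m5.y.sum() == 3  # only A's ROIs positive
        m10 = RecurrenceModel.from_cases(cases, "10y")
        assert m10.X.shape == (9, 4)  # C dropped entirely
        assert m10.y.sum() == 6
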