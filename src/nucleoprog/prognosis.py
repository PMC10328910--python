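"""Recurrence prognosis models over ROI feature vectors.

The cohort design divides nephrectomy patients into four groups by
recurrence status and follow-up duration:

* **A** — recurrence within 5 years (months <= 60);
* **B** — recurrence between 5 and 10 years (60 < months <= 120);
* **C** — recurrence-free with 5–10 years of follow-up (censored);
* **D** — recurrence-free for more than 10 years.

Patients censored before 5 years fall outside the scheme and are excluded,
as is the rare recurrence after 10 years.

Two horizon-specific binary classifiers are trained on ROI feature vectors:
the 5-year model labels group A positive and B/C/D negative; the 10-year
model labels A/B positive and D negative, with group C carried through as
prediction-only (its 10-year status is unknown).  Each classifier is a
linear-kernel SVM with Platt sigmoid probability calibration, fitted on
z-scored features (training statistics only).  A case's probability is the
arithmetic mean of its ROI probabilities; "recurrence" means probability
strictly greater than 0.50.

Combining the two calibrated probabilities (p5, p10) against the 0.50
cutoff maps each case to a quadrant of the unit square, i.e. a predicted
time of recurrence: Q1 = recur within 5 years, Q2 = recur between 5 and
10 years, Q3 = recurrence-free within 10 years, Q4 = contradictory
(5-year model positive but 10-year model negative).

The module follows the Model/Results convention: build a
:class:`RecurrenceModel` (or :class:`DualHorizonModel`) from data, call
``fit()``, and read estimates and diagnostics off the returned Results
object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import ConfusionMatrix, confusion

logger = logging.getLogger(__name__)

__all__ = [
    "CaseRecord",
    "DualPrediction",
    "GroupAssignmentWarning",
    "UnlearnableError",
    "EmptyCaseError",
    "GROUPS",
    "QUADRANT_TIMING",
    "EXPECTED_QUADRANT",
    "assign_group",
    "build_label_sets",
    "split_cohort",
    "train_horizon_model",
    "predict_case",
    "combine_horizons",
    "RecurrenceModel",
    "RecurrenceResults",
    "DualHorizonModel",
    "DualHorizonResults",
]

GROUPS = ("A", "B", "C", "D")

QUADRANT_TIMING = {
    "Q1": "recur_within_5y",
    "Q2": "recur_5_to_10y",
    "Q3": "recurrence_free_10y",
    "Q4": "contradictory",
}

#: quadrant a case of each group should land in when both models are right
EXPECTED_QUADRANT = {"A": "Q1", "B": "Q2", "D": "Q3"}


class GroupAssignmentWarning(UserWarning):
    """A case falls outside the four-group scheme and is excluded."""


class UnlearnableError(ValueError):
    """Training set contains a single class."""


class EmptyCaseError(ValueError):
    """Case has no ROI vectors to predict from."""


@dataclass
class CaseRecord:
    """Patient-level record: outcome, group, and ROI feature vectors."""

    case_id: str
    recurrence: bool
    months: float
    group: str | None = None
    roi_vectors: np.ndarray | None = None  # (n_rois, n_features)
    roi_ids: list[str] = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.months <= 0:
            raise ValueError("months must be positive")
        if self.group is None:
            self.group = assign_group(self.recurrence, self.months)
        if self.roi_vectors is not None:
            self.roi_vectors = np.asarray(self.roi_vectors, dtype=float)
            if self.roi_vectors.ndim != 2:
                raise ValueError("roi_vectors must be (n_rois, n_features)")

    @property
    def n_rois(self) -> int:
        return 0 if self.roi_vectors is None else self.roi_vectors.shape[0]


@dataclass
class DualPrediction:
    case_id: str
    p5: float
    p10: float
    quadrant: str
    predicted_timing: str


def assign_group(recurrence: bool, months: float) -> str | None:
    """Map (recurrence flag, months) to group A–D, or None if excluded.

    Recurrence-free cases followed less than 5 years carry no usable label
    and are excluded; so is recurrence after 10 years, which the four-group
    scheme does not cover (excluded with a warning).
    """
    if months <= 0:
        raise ValueError("months must be positive")
    if recurrence:
        if months <= 60:
            return "A"
        if months <= 120:
            return "B"
        warnings.warn(
            f"recurrence at {months} months is outside the 10-year scheme; "
            "case excluded",
            GroupAssignmentWarning,
            stacklevel=2,
        )
        return None
    if months < 60:
        return None  # censored before 5 years
    if months <= 120:
        return "C"
    return "D"


def build_label_sets(
    cases: list[CaseRecord], horizon: str
) -> list[tuple[CaseRecord, int | None]]:
    """Horizon-specific binary labels; None marks prediction-only cases.

    5y: A positive, B/C/D negative.  10y: A/B positive, D negative, C
    unlabeled (cannot serve as training data).
    """
    if horizon not in ("5y", "10y"):
        raise ValueError("horizon must be '5y' or '10y'")
    out: list[tuple[CaseRecord, int | None]] = []
    for case in cases:
        if case.group not in GROUPS:
            raise ValueError(f"case {case.case_id} has no group assignment")
        if horizon == "5y":
            out.append((case, 1 if case.group == "A" else 0))
        else:
            if case.group in ("A", "B"):
                out.append((case, 1))
            elif case.group == "D":
                out.append((case, 0))
            else:
                out.append((case, None))
    return out


def split_cohort(
    cases: list[CaseRecord],
    test_fraction: float = 0.25,
    seed: int = 0,
    test_counts: dict[str, int] | None = None,
) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Group-stratified random train/test partition.

    Per group the test set takes ``floor(n * test_fraction)`` cases, or the
    explicit ``test_counts[group]`` when given (use
    ``{"A": 10, "B": 4, "C": 9, "D": 8}`` to mirror the study's 31-case
    composition).  Deterministic for a fixed seed; an empty group passes
    through whole with a warning.
    """
    rng = np.random.default_rng(seed)
    train: list[CaseRecord] = []
    test: list[CaseRecord] = []
    for g in GROUPS:
        members = [c for c in cases if c.group == g]
        if not members:
            warnings.warn(f"group {g} is empty; nothing to stratify", stacklevel=2)
            continue
        n_test = (
            test_counts[g] if test_counts is not None else int(len(members) * test_fraction)
        )
        order = rng.permutation(len(members))
        test.extend(members[i] for i in order[:n_test])
        train.extend(members[i] for i in order[n_test:])
    return train, test


def combine_horizons(case_id: str, p5: float, p10: float) -> DualPrediction:
    """Quadrant classification of the (p5, p10) probability pair.

    Recurrence requires probability strictly greater than 0.50, so a
    probability of exactly 0.50 falls on the non-recurrence side.
    """
    for name, p in (("p5", p5), ("p10", p10)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if p5 > 0.5:
        quadrant = "Q1" if p10 > 0.5 else "Q4"
    else:
        quadrant = "Q2" if p10 > 0.5 else "Q3"
    return DualPrediction(case_id, p5, p10, quadrant, QUADRANT_TIMING[quadrant])


# ---------------------------------------------------------------------------
# single-horizon model


class RecurrenceModel:
    """Linear-SVM recurrence classifier for one horizon, built from ROIs.

    Parameters
    ----------
    roi_features : (n_rois, n_features) training design matrix.
    roi_labels : binary label per ROI (each ROI inherits its case's label).
    horizon : "5y" or "10y", recorded for reporting.
    C : SVM regularization strength (library default 1.0).
    random_state : seed for the Platt-calibration CV inside the SVM.
    """

    def __init__(
        self,
        roi_features: np.ndarray,
        roi_labels: np.ndarray,
        horizon: str = "5y",
        C: float = 1.0,
        random_state: int = 0,
    ) -> None:
        self.X = np.asarray(roi_features, dtype=float)
        self.y = np.asarray(roi_labels, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("roi_features and roi_labels disagree in length")
        self.horizon = horizon
        self.C = C
        self.random_state = random_state

    @classmethod
    def from_cases(
        cls,
        cases: list[CaseRecord],
        horizon: str,
        C: float = 1.0,
        random_state: int = 0,
    ) -> "RecurrenceModel":
        """Stack the labeled cases' ROI vectors; unlabeled cases are dropped."""
        Xs, ys = [], []
        for case, lab in build_label_sets(cases, horizon):
            if lab is None:
                continue
            if case.roi_vectors is None or case.n_rois == 0:
                raise EmptyCaseError(f"case {case.case_id} has no ROI vectors")
            Xs.append(case.roi_vectors)
            ys.append(np.full(case.n_rois, lab))
        return cls(np.vstack(Xs), np.concatenate(ys), horizon, C, random_state)

    def fit(self) -> "RecurrenceResults":
        classes = np.unique(self.y)
        if classes.size < 2:
            raise UnlearnableError(
                f"{self.horizon} training set contains a single class {classes}"
            )
        pipeline = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svm",
                    SVC(
                        kernel="linear",
                        C=self.C,
                        probability=True,
                        random_state=self.random_state,
                    ),
                ),
            ]
        )
        with warnings.catch_warnings():
            # sklearn 1.9 deprecates SVC(probability=True) in favour of a
            # wrapper; the libsvm Platt-sigmoid path is exactly what we want
            warnings.simplefilter("ignore", FutureWarning)
            pipeline.fit(self.X, self.y)
        return RecurrenceResults(self, pipeline)


class RecurrenceResults:
    """Fitted single-horizon classifier with its training diagnostics."""

    def __init__(self, model: RecurrenceModel, pipeline: Pipeline) -> None:
        self.model = model
        self.pipeline = pipeline
        pred = pipeline.predict(model.X)
        self.train_roi_confusion: ConfusionMatrix = confusion(
            model.y.astype(bool),
            pred.astype(bool),
            level="ROI",
            split="training",
        )

    @property
    def horizon(self) -> str:
        return self.model.horizon

    @property
    def coef_(self) -> np.ndarray:
        return self.pipeline.named_steps["svm"].coef_.ravel()

    @property
    def intercept_(self) -> float:
        return float(self.pipeline.named_steps["svm"].intercept_[0])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Signed margin; affine in the input by the linear-kernel contract."""
        return self.pipeline.decision_function(np.asarray(X, float))

    def predict_roi_proba(self, X: np.ndarray) -> np.ndarray:
        """Calibrated recurrence probability per ROI."""
        proba = self.pipeline.predict_proba(np.asarray(X, float))
        pos = list(self.pipeline.named_steps["svm"].classes_).index(1)
        return proba[:, pos]

    def predict_case(self, case: CaseRecord) -> tuple[float, bool]:
        """Case probability = mean ROI probability; call = p > 0.50."""
        if case.roi_vectors is None or case.n_rois == 0:
            raise EmptyCaseError(f"case {case.case_id} has no ROI vectors")
        p = float(self.predict_roi_proba(case.roi_vectors).mean())
        return p, p > 0.5

    def summary(self) -> str:
        cm = self.train_roi_confusion
        lines = [
            f"Recurrence model ({self.horizon} horizon, linear SVM, C={self.model.C})",
            f"  training ROIs: {len(self.model.y)} "
            f"({int(self.model.y.sum())} positive)",
            f"  training ROI accuracy: {cm.accuracy_pct:.1f}%",
            f"  confusion (tp fn fp tn): {cm.tp} {cm.fn} {cm.fp} {cm.tn}",
        ]
        return "\n".join(lines)


def train_horizon_model(
    roi_features: np.ndarray,
    roi_labels: np.ndarray,
    horizon: str = "5y",
    C: float = 1.0,
    random_state: int = 0,
) -> RecurrenceResults:
    """Functional wrapper: build and fit a :class:`RecurrenceModel`."""
    return RecurrenceModel(roi_features, roi_labels, horizon, C, random_state).fit()


def predict_case(results: RecurrenceResults, case: CaseRecord) -> tuple[float, bool]:
    """Functional wrapper for :meth:`RecurrenceResults.predict_case`."""
    return results.predict_case(case)


# ---------------------------------------------------------------------------
# dual-horizon model


class DualHorizonModel:
    """Both horizon models plus the split and the quadrant combiner.

    Splits the cohort by case (stratified by group) so no case contributes
    ROIs to both sides, fits the 5- and 10-year classifiers on training
    ROIs, and evaluates on the held-out cases.
    """

    def __init__(
        self,
        cases: list[CaseRecord],
        test_fraction: float = 0.25,
        seed: int = 0,
        test_counts: dict[str, int] | None = None,
        C: float = 1.0,
    ) -> None:
        self.cases = list(cases)
        self.test_fraction = test_fraction
        self.seed = seed
        self.test_counts = test_counts
        self.C = C

    def fit(self) -> "DualHorizonResults":
        train, test = split_cohort(
            self.cases, self.test_fraction, self.seed, self.test_counts
        )
        res5 = RecurrenceModel.from_cases(
            train, "5y", C=self.C, random_state=self.seed
        ).fit()
        res10 = RecurrenceModel.from_cases(
            train, "10y", C=self.C, random_state=self.seed
        ).fit()
        return DualHorizonResults(self, train, test, res5, res10)


class DualHorizonResults:
    """Held-out predictions, confusion matrices and the quadrant table."""

    def __init__(
        self,
        model: DualHorizonModel,
        train_cases: list[CaseRecord],
        test_cases: list[CaseRecord],
        results_5y: RecurrenceResults,
        results_10y: RecurrenceResults,
    ) -> None:
        self.model = model
        self.train_cases = train_cases
        self.test_cases = test_cases
        self.results_5y = results_5y
        self.results_10y = results_10y
        self._evaluate()

    def _evaluate(self) -> None:
        rows = []
        for case in self.test_cases:
            p5, _ = self.results_5y.predict_case(case)
            p10, _ = self.results_10y.predict_case(case)
            dual = combine_horizons(case.case_id, p5, p10)
            rows.append(
                {
                    "case_id": case.case_id,
                    "group": case.group,
                    "p5": p5,
                    "p10": p10,
                    "quadrant": dual.quadrant,
                    "predicted_timing": dual.predicted_timing,
                }
            )
        self.predictions = pd.DataFrame(rows)

        self.confusion: dict[tuple[str, str, str], ConfusionMatrix] = {}
        for horizon, res in (("5y", self.results_5y), ("10y", self.results_10y)):
            self.confusion[(horizon, "training", "ROI")] = res.train_roi_confusion
            labeled = [
                (c, lab)
                for c, lab in build_label_sets(self.test_cases, horizon)
                if lab is not None
            ]
            roi_truth, roi_pred, case_truth, case_pred = [], [], [], []
            for case, lab in labeled:
                probs = res.predict_roi_proba(case.roi_vectors)
                roi_truth.extend([bool(lab)] * case.n_rois)
                roi_pred.extend(list(probs > 0.5))
                p, call = res.predict_case(case)
                case_truth.append(bool(lab))
                case_pred.append(call)
            self.confusion[(horizon, "test", "ROI")] = confusion(
                roi_truth, roi_pred, level="ROI", split="test"
            )
            self.confusion[(horizon, "test", "case")] = confusion(
                case_truth, case_pred, level="case", split="test"
            )

    def quadrant_table(self) -> pd.DataFrame:
        """Cross-tabulation of true group versus predicted quadrant."""
        return pd.crosstab(self.predictions["group"], self.predictions["quadrant"])

    def quadrant_agreement(self, groups: tuple[str, ...] = ("A", "B", "D")) -> dict[str, float]:
        """Per-group fraction of test cases in their expected quadrant.

        Group C has no expected quadrant (its 10-year status is unknown)
        and is never scored.
        """
        out = {}
        for g in groups:
            sub = self.predictions[self.predictions["group"] == g]
            if len(sub) == 0:
                out[g] = float("nan")
            else:
                out[g] = float((sub["quadrant"] == EXPECTED_QUADRANT[g]).mean())
        return out

    def summary(self) -> str:
        lines = [
            "Dual-horizon recurrence prediction",
            "==================================",
            f"cohort: {len(self.model.cases)} cases "
            f"(train {len(self.train_cases)}, test {len(self.test_cases)}); "
            f"seed {self.model.seed}",
            "",
        ]
        for (horizon, split, level), cm in sorted(self.confusion.items()):
            lines.append(
                f"{horizon:>4} {split:>8} {level:>4}: accuracy "
                f"{cm.accuracy_pct:5.1f}%  (tp={cm.tp} fn={cm.fn} "
                f"fp={cm.fp} tn={cm.tn})"
            )
        lines.append("")
        lines.append("group x quadrant (test cases):")
        lines.append(self.quadrant_table().to_string())
        return "\n".join(lines)

    def plot_quadrants(self, ax=None):
        """Scatter of (p5, p10) per test case, colored by true group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        colors = {"A": "red", "B": "gold", "C": "gray", "D": "blue"}
        for g, sub in self.predictions.groupby("group"):
            ax.scatter(sub["p5"], sub["p10"], c=colors.get(g, "black"), label=f"group {g}")
        ax.axhline(0.5, color="k", lw=0.8)
        ax.axvline(0.5, color="k", lw=0.8)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("5-year recurrence probability")
        ax.set_ylabel("10-year recurrence probability")
        ax.legend(loc="lower right", fontsize=8)
        return ax
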