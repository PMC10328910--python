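"""Confusion matrices, accuracies, and result bundles.

Accuracy is reported as a percentage rounded half-up to one decimal, the
precision used for clinical classifier tables; the raw fraction is kept
alongside so nothing is lost to display rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "accuracy",
    "ResultBundle",
    "report_run",
]


@dataclass
class ConfusionMatrix:
    """Truth x prediction counts over {recurrence, non-recurrence}."""

    tp: int
    fn: int
    fp: int
    tn: int
    level: str = "case"  # "ROI" or "case"
    split: str = "test"  # "training" or "test"

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must count at least one pair")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        """Raw fraction correct in [0, 1]."""
        return (self.tp + self.tn) / self.total

    @property
    def accuracy_pct(self) -> float:
        """Percentage, rounded half-up to one decimal (display precision)."""
        pct = Decimal(100 * (self.tp + self.tn)) / Decimal(self.total)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def confusion(
    truth, predicted, level: str = "case", split: str = "test"
) -> ConfusionMatrix:
    """Tally paired boolean truth/prediction lists."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted must have equal lengths")
    if len(truth) == 0:
        raise ValueError("cannot tally an empty prediction list")
    tp = sum(1 for t, p in zip(truth, predicted) if t and p)
    fn = sum(1 for t, p in zip(truth, predicted) if t and not p)
    fp = sum(1 for t, p in zip(truth, predicted) if not t and p)
    tn = sum(1 for t, p in zip(truth, predicted) if not t and not p)
    return ConfusionMatrix(tp, fn, fp, tn, level=level, split=split)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percentage accuracy at the one-decimal display precision."""
    return cm.accuracy_pct


@dataclass
class ResultBundle:
    """Serializable record of one dual-horizon run."""

    settings: dict
    matrices: dict  # key "horizon/split/level" -> ConfusionMatrix fields
    quadrant_counts: dict  # group -> {quadrant: count}
    scatter: list  # per-case dicts: case_id, p5, p10, group, quadrant
    missing_cases: list

    def to_dict(self) -> dict:
        return {
            "settings": self.settings,
            "matrices": {k: dict(v) for k, v in self.matrices.items()},
            "quadrant_counts": self.quadrant_counts,
            "scatter": self.scatter,
            "missing_cases": self.missing_cases,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ResultBundle":
        return cls(
            settings=d["settings"],
            matrices={k: dict(v) for k, v in d["matrices"].items()},
            quadrant_counts=d["quadrant_counts"],
            scatter=d["scatter"],
            missing_cases=d["missing_cases"],
        )

    def save(self, path: str | Path) -> None:
        """Write the bundle JSON plus a scatter CSV alongside."""
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        pd.DataFrame(self.scatter).to_csv(path.with_suffix(".scatter.csv"), index=False)

    @classmethod
    def load(cls, path: str | Path) -> "ResultBundle":
        return cls.from_dict(json.loads(Path(path).read_text()))


def report_run(results, cohort=None, settings: dict | None = None) -> ResultBundle:
    """Bundle a fitted :class:`~nucleoprog.prognosis.DualHorizonResults`.

    Emits the six confusion matrices (2 horizons x {training ROI, test ROI,
    test case}), the group-by-quadrant table, and the Fig.-style scatter
    rows (p5, p10, group per test case).  Cohort cases absent from the
    predictions are listed, never silently dropped.
    """
    matrices = {}
    for (horizon, split, level), cm in results.confusion.items():
        matrices[f"{horizon}/{split}/{level}"] = asdict(cm)
    quad = results.quadrant_table()
    quadrant_counts = {g: {q: int(quad.loc[g, q]) for q in quad.columns} for g in quad.index}
    scatter = results.predictions[
        ["case_id", "p5", "p10", "group", "quadrant"]
    ].to_dict("records")
    predicted_ids = set(results.predictions["case_id"])
    trained_ids = {c.case_id for c in results.train_cases}
    missing = []
    if cohort is not None:
        missing = [
            c.case_id
            for c in cohort
            if c.case_id not in predicted_ids and c.case_id not in trained_ids
        ]
    return ResultBundle(
        settings=settings or {"seed": results.model.seed, "C": results.model.C},
        matrices=matrices,
        quadrant_counts=quadrant_counts,
        scatter=scatter,
        missing_cases=missing,
    )
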