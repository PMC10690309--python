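"""Confusion matrices, one-vs-rest metrics, and subject-level cross-testing.

The metric suite reduces a k-class confusion matrix to per-class binary
counts (positive class vs all the rest) and reports

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 TP / (2 TP + FP + FN)

computed in exact integer arithmetic, with zero-denominator ratios reported
as undefined (None) rather than coerced to 0.  The published per-class
confusion matrices for the attenuation method and for the two CNN baselines
are bundled as CSV fixtures, so every performance figure derivable from them
can be recomputed and checked.

Cross-testing rotates whole subjects (kidneys): with five subjects there are
five test folds, each holding out a different subject, and within each fold
a four-way rotation of the validation subject over the remainder.  The
Gaussian threshold method has no hyperparameters, so the validation
rotations are reported only for harness parity; models are fitted on the
non-test subjects and evaluated on the held-out one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from renoct.classifier import ABSTAIN, LikelihoodClassifier

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "SplitPlan",
    "FoldTriple",
    "CrossTestResult",
    "load_table",
    "confusion_from_calls",
    "one_vs_rest",
    "metrics",
    "report_from_table",
    "misclassification_rate",
    "format_percent",
    "make_split_plan",
    "cross_test_attenuation",
]


@dataclass
class ConfusionMatrix:
    """k-class count table: rows are true classes, columns predictions."""

    labels: tuple[str, ...]
    counts: np.ndarray
    abstained: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {k} labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("confusion CSV must have identical row/column labels")
        return cls(labels=tuple(df.columns), counts=df.to_numpy())


def load_table(name: str) -> ConfusionMatrix:
    """Load a bundled published confusion-matrix fixture.

    ``name`` is one of ``table1a`` (attenuation method, 5 classes x 10,000
    images), ``table2a`` (ResNet50, 6 classes) or ``table2b`` (InceptionV3,
    6 classes).
    """
    ref = resources.files("renoct.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_csv(path)


def confusion_from_calls(
    truth: list[str], calls: list[str], label_order: list[str] | tuple[str, ...]
) -> ConfusionMatrix:
    """Count (true, predicted) pairs; abstentions tallied per true class."""
    if len(truth) != len(calls):
        raise ValueError("truth and calls must have equal length")
    if len(truth) == 0:
        raise ValueError("empty input")
    labels = tuple(label_order)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    abstained: dict[str, int] = {}
    for t, c in zip(truth, calls):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if c == ABSTAIN:
            abstained[t] = abstained.get(t, 0) + 1
            continue
        if c not in index:
            raise ValueError(f"unknown predicted label {c!r}")
        counts[index[t], index[c]] += 1
    return ConfusionMatrix(labels=labels, counts=counts, abstained=abstained)


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest reduction of a confusion matrix for one positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def one_vs_rest(cm: ConfusionMatrix, positive: str) -> BinaryCounts:
    """Collapse a k-class matrix to binary counts for one positive class."""
    if positive not in cm.labels:
        raise ValueError(f"unknown class {positive!r}")
    i = cm.labels.index(positive)
    tp = int(cm.counts[i, i])
    fn = int(cm.counts[i].sum()) - tp
    fp = int(cm.counts[:, i].sum()) - tp
    tn = cm.total - tp - fn - fp
    return BinaryCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def metrics(bc: BinaryCounts) -> dict[str, float | None]:
    """Accuracy/precision/recall/F1 as exact fractions cast to float.

    Zero-denominator ratios are returned as None (undefined), never 0.
    """
    if bc.total == 0:
        raise ValueError("all-zero counts")

    def ratio(num: int, den: int) -> float | None:
        return float(Fraction(num, den)) if den > 0 else None

    return {
        "accuracy": ratio(bc.tp + bc.tn, bc.total),
        "precision": ratio(bc.tp, bc.tp + bc.fp),
        "recall": ratio(bc.tp, bc.tp + bc.fn),
        "f1": ratio(2 * bc.tp, 2 * bc.tp + bc.fp + bc.fn),
    }


def format_percent(fraction: float | None, decimals: int = 2) -> str:
    """Render a fraction as a percent string, rounded half-up."""
    if fraction is None:
        return "undefined"
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP))


def report_from_table(cm: ConfusionMatrix, as_percent: bool = False) -> pd.DataFrame:
    """Per-class one-vs-rest metric report for every class in the matrix.

    Returns fractions by default; ``as_percent`` yields half-up 2-decimal
    percent strings matching the conventional printed style.
    """
    rows = {}
    for label in cm.labels:
        m = metrics(one_vs_rest(cm, label))
        if as_percent:
            m = {k: format_percent(v) for k, v in m.items()}
        rows[label] = m
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["accuracy", "precision", "recall", "f1"]
    ]


def misclassification_rate(cm: ConfusionMatrix, true_class: str, predicted_class: str) -> float:
    """Fraction of ``true_class`` images predicted as ``predicted_class``."""
    i = cm.labels.index(true_class)
    j = cm.labels.index(predicted_class)
    row_total = int(cm.counts[i].sum())
    if row_total == 0:
        raise ValueError(f"no samples of class {true_class!r}")
    return float(Fraction(int(cm.counts[i, j]), row_total))


@dataclass(frozen=True)
class FoldTriple:
    """One rotation: disjoint train subjects, validation subject, test subject."""

    train: tuple[str, ...]
    validation: str
    test: str

    def __post_init__(self) -> None:
        roles = set(self.train) | {self.validation, self.test}
        if len(roles) != len(self.train) + 2:
            raise ValueError("a subject appears in two roles within one fold")


@dataclass
class SplitPlan:
    """Nested subject rotation: every subject is the test subject exactly
    once; within each test fold the validation subject rotates over the
    remaining subjects."""

    folds: list[FoldTriple]

    @property
    def test_subjects(self) -> list[str]:
        seen: list[str] = []
        for f in self.folds:
            if f.test not in seen:
                seen.append(f.test)
        return seen


def make_split_plan(subject_ids: list[str], seed: int = 0) -> SplitPlan:
    """Enumerate the nested cross-validation / cross-testing rotation.

    With n subjects the plan holds n test folds x (n-1) validation rotations;
    the subject ordering is shuffled deterministically from ``seed``.
    """
    subjects = list(subject_ids)
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    if len(subjects) < 3:
        raise ValueError("need >= 3 subjects for a train/validation/test rotation")
    order = list(np.array(subjects)[np.random.default_rng(seed).permutation(len(subjects))])
    folds = []
    for test in order:
        rest = [s for s in order if s != test]
        for validation in rest:
            train = tuple(s for s in rest if s != validation)
            folds.append(FoldTriple(train=train, validation=validation, test=test))
    return SplitPlan(folds=folds)


@dataclass
class CrossTestResult:
    """Pooled held-out confusion matrix plus per-fold metric reports."""

    pooled: ConfusionMatrix
    per_fold: dict[str, pd.DataFrame]
    abstained: dict[str, int]


def cross_test_attenuation(
    mu_table: pd.DataFrame,
    plan: SplitPlan,
    classes: list[str] | None = None,
) -> CrossTestResult:
    """Subject-rotating evaluation of the Gaussian likelihood classifier.

    For each test fold the class-conditional Gaussians are fitted on the mu
    values of all non-test subjects and the held-out subject is classified;
    the per-fold confusion matrices accumulate into a pooled matrix.
    Classes with no computable mu anywhere (the pelvis under the attenuation
    method) are excluded up front; images of the evaluated classes whose mu
    is not computable abstain and are tallied separately.  A class missing
    from a training fold raises an error naming the fold.
    """
    required = {"subject_id", "label", "mu"}
    if not required <= set(mu_table.columns):
        raise ValueError(f"mu table must have columns {sorted(required)}")
    table_subjects = set(mu_table["subject_id"])
    plan_subjects = {f.test for f in plan.folds}
    missing = plan_subjects - table_subjects
    if missing:
        raise ValueError(f"plan subjects absent from the mu table: {sorted(missing)}")

    valid = mu_table[np.isfinite(mu_table["mu"])]
    if classes is None:
        classes = sorted(valid["label"].unique())

    per_fold: dict[str, pd.DataFrame] = {}
    pooled_counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    abstained: dict[str, int] = {}
    eval_rows = mu_table[mu_table["label"].isin(classes)]

    for test in plan.test_subjects:
        train = valid[(valid["subject_id"] != test) & valid["label"].isin(classes)]
        for label in classes:
            if (train["label"] == label).sum() < 2:
                raise ValueError(
                    f"class {label!r} missing from the training data of test "
                    f"fold {test!r}"
                )
        model = LikelihoodClassifier.fit(train, classes=classes)
        held = eval_rows[eval_rows["subject_id"] == test]
        calls = model.predict(held["mu"].to_numpy())
        cm = confusion_from_calls(list(held["label"]), calls, classes)
        pooled_counts += cm.counts
        for k, v in cm.abstained.items():
            abstained[k] = abstained.get(k, 0) + v
        per_fold[test] = report_from_table(cm)

    pooled = ConfusionMatrix(labels=tuple(classes), counts=pooled_counts, abstained=abstained)
    return CrossTestResult(pooled=pooled, per_fold=per_fold, abstained=abstained)
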