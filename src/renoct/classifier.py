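"""Gaussian-intersection threshold classification of attenuation values.

Class-conditional normal distributions are fitted (by moments) to the
per-image attenuation coefficients; the decision threshold between two
classes is the crossing point of the two fitted density curves, which for
equal priors is the minimum-error cutoff.  ROC curves and the rank-statistic
AUC quantify separability independently of any one threshold.  Images whose
mu is not computable (pelvis-like zero-signal cases) abstain and are
reported separately, never silently dropped.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "ABSTAIN",
    "GaussianModel",
    "GaussianThresholdModel",
    "RocResult",
    "fit_gaussian",
    "intersection_threshold",
    "fit_threshold_model",
    "classify",
    "roc_auc",
    "one_vs_rest_pool",
    "LikelihoodClassifier",
]

#: Sentinel label for images whose attenuation coefficient is not computable.
ABSTAIN = "abstain"


@dataclass(frozen=True)
class GaussianModel:
    """A fitted class-conditional normal: N(mean, sd^2) over mu values."""

    mean: float
    sd: float
    n: int
    label: str

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 2:
            raise ValueError("need n >= 2 samples")

    def logpdf(self, x: float | np.ndarray) -> float | np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - 0.5 * math.log(2 * math.pi)


def fit_gaussian(values: np.ndarray, label: str = "") -> GaussianModel:
    """Moment fit: sample mean and sd (n-1 denominator).

    Raises on fewer than two finite samples or zero variance — a degenerate
    class distribution cannot define a crossing threshold.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError(f"need >= 2 finite samples to fit {label!r}")
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError(f"zero variance in {label!r}: cannot fit a normal")
    return GaussianModel(mean=float(x.mean()), sd=sd, n=int(x.size), label=label)


def intersection_threshold(a: GaussianModel, b: GaussianModel) -> float:
    """The mu value where the two fitted normal densities cross.

    Equal variances give the unique crossing at the midpoint of the means.
    Unequal variances solve the quadratic obtained from equating the two
    log-densities; the root lying between the means is returned (tie-break:
    the root nearer the midpoint if both qualify numerically).  If no root
    falls between the means — possible when one distribution is much wider
    and nearly concentric — the real root nearest the midpoint is returned
    with a warning.
    """
    if a.mean == b.mean and a.sd == b.sd:
        raise ValueError("identical distributions have no crossing threshold")
    mid = 0.5 * (a.mean + b.mean)
    if math.isclose(a.sd, b.sd, rel_tol=1e-12, abs_tol=0.0):
        if a.mean == b.mean:
            raise ValueError("equal means with equal sds: no usable threshold")
        return mid

    s1, s2 = a.sd, b.sd
    m1, m2 = a.mean, b.mean
    qa = 1.0 / (2 * s2 * s2) - 1.0 / (2 * s1 * s1)
    qb = m1 / (s1 * s1) - m2 / (s2 * s2)
    qc = m2 * m2 / (2 * s2 * s2) - m1 * m1 / (2 * s1 * s1) + math.log(s2 / s1)
    disc = qb * qb - 4 * qa * qc
    if disc < 0:
        raise ValueError("no real density crossing (numerically degenerate fit)")
    sq = math.sqrt(disc)
    roots = [(-qb - sq) / (2 * qa), (-qb + sq) / (2 * qa)]
    lo, hi = sorted((m1, m2))
    between = [r for r in roots if lo <= r <= hi]
    if between:
        return min(between, key=lambda r: abs(r - mid))
    warnings.warn(
        "no density crossing between the class means; using the root nearest "
        "their midpoint"
    )
    return min(roots, key=lambda r: abs(r - mid))


@dataclass(frozen=True)
class GaussianThresholdModel:
    """Two fitted classes plus the crossing-point decision threshold.

    ``decision_rule`` maps the higher-mu side of the threshold to the
    higher-mean class; values exactly at the threshold go to the higher-mean
    class (documented tie-break).
    """

    class_a: GaussianModel
    class_b: GaussianModel
    threshold: float

    @property
    def high_label(self) -> str:
        return (
            self.class_a.label
            if self.class_a.mean >= self.class_b.mean
            else self.class_b.label
        )

    @property
    def low_label(self) -> str:
        return (
            self.class_b.label
            if self.class_a.mean >= self.class_b.mean
            else self.class_a.label
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": [
                {"label": m.label, "mean": m.mean, "sd": m.sd, "n": m.n}
                for m in (self.class_a, self.class_b)
            ],
            "threshold": self.threshold,
            "decision_rule": {">= threshold": self.high_label, "< threshold": self.low_label},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GaussianThresholdModel":
        payload = json.loads(Path(path).read_text())
        a, b = (GaussianModel(**c) for c in payload["classes"])
        return cls(class_a=a, class_b=b, threshold=float(payload["threshold"]))


def fit_threshold_model(
    values_a: np.ndarray, label_a: str, values_b: np.ndarray, label_b: str
) -> GaussianThresholdModel:
    """Fit both classes and place the threshold at the density crossing."""
    a = fit_gaussian(values_a, label_a)
    b = fit_gaussian(values_b, label_b)
    return GaussianThresholdModel(class_a=a, class_b=b, threshold=intersection_threshold(a, b))


def classify(model: GaussianThresholdModel, mu: float) -> str:
    """Label a single mu value; not-computable (NaN) mu abstains."""
    if mu is None or not np.isfinite(mu):
        return ABSTAIN
    return model.high_label if mu >= model.threshold else model.low_label


@dataclass
class RocResult:
    """ROC sweep over mu cutoffs: monotone (fpr, tpr) path plus rank AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, index=False)


def roc_auc(positives: np.ndarray, negatives: np.ndarray) -> RocResult:
    """ROC curve and AUC for higher-mu-is-positive scoring.

    The AUC equals the Mann-Whitney rank statistic (ties count one half):
    the probability that a random positive scores above a random negative.
    """
    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must contain at least one finite sample")
    y = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(neg.size, dtype=int)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def one_vs_rest_pool(
    mu_table: pd.DataFrame,
    positive_class: str,
    per_class_subsample: int,
    seed: int = 0,
    *,
    normal_classes: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pool a balanced tumor-vs-normal comparison from a per-image mu table.

    Positives are every valid image of ``positive_class``; negatives take an
    equal random subsample from each normal class within every subject, so
    that the pooled negative count can match the positive count (e.g. 2,500
    images x 4 normal types x 5 subjects against 50,000 tumor images).
    Reproducible from ``seed``.
    """
    if per_class_subsample <= 0:
        raise ValueError("per_class_subsample must be >= 1")
    valid = mu_table[np.isfinite(mu_table["mu"])]
    if normal_classes is None:
        normal_classes = sorted(set(valid["label"]) - {positive_class})
    positives = valid.loc[valid["label"] == positive_class, "mu"].to_numpy()
    if positives.size == 0:
        raise ValueError(f"no valid images of positive class {positive_class!r}")

    rng = np.random.default_rng(seed)
    chunks = []
    for subject in sorted(valid["subject_id"].unique()):
        for label in normal_classes:
            cell = valid.loc[
                (valid["subject_id"] == subject) & (valid["label"] == label), "mu"
            ].to_numpy()
            if cell.size < per_class_subsample:
                raise ValueError(
                    f"subject {subject!r} class {label!r} has {cell.size} valid "
                    f"images, fewer than the requested {per_class_subsample}"
                )
            chunks.append(rng.choice(cell, size=per_class_subsample, replace=False))
    return positives, np.concatenate(chunks)


class LikelihoodClassifier:
    """Multi-class rule: nearest fitted class by Gaussian likelihood.

    Used for k-class confusion matrices where pairwise crossing thresholds
    do not compose into a single rule; assumes equal priors.  NaN mu
    abstains.
    """

    def __init__(self, models: dict[str, GaussianModel]):
        if len(models) < 2:
            raise ValueError("need at least two classes")
        self.models = dict(models)
        self.labels = list(self.models)

    @classmethod
    def fit(cls, mu_table: pd.DataFrame, classes: list[str] | None = None) -> "LikelihoodClassifier":
        """Fit one Gaussian per class from a per-image mu table."""
        valid = mu_table[np.isfinite(mu_table["mu"])]
        if classes is None:
            classes = sorted(valid["label"].unique())
        models = {}
        for label in classes:
            vals = valid.loc[valid["label"] == label, "mu"].to_numpy()
            models[label] = fit_gaussian(vals, label)
        return cls(models)

    def predict_one(self, mu: float) -> str:
        if mu is None or not np.isfinite(mu):
            return ABSTAIN
        scores = {label: m.logpdf(mu) for label, m in self.models.items()}
        return max(sorted(scores), key=lambda k: scores[k])

    def predict(self, mu_values: np.ndarray) -> list[str]:
        return [self.predict_one(m) for m in np.asarray(mu_values, dtype=float)]
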