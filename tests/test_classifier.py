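"""Gaussian threshold classifier: crossing points, ROC/AUC, pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import brentq

from renoct import (
    ABSTAIN,
    GaussianModel,
    LikelihoodClassifier,
    classify,
    fit_gaussian,
    intersection_threshold,
    one_vs_rest_pool,
    roc_auc,
)
from renoct.classifier import GaussianThresholdModel, fit_threshold_model


def N(mean, sd, label="x", n=100):
    return GaussianModel(mean=mean, sd=sd, n=n, label=label)


class TestFitGaussian:
    def test_two_point_formula(self):
        m = fit_gaussian([1.0, 3.0], "pair")
        assert m.mean == 2.0
        assert m.sd == pytest.approx(math.sqrt(2.0))
        assert m.n == 2

    def test_monte_carlo_recovery(self, rng):
        draws = rng.normal(5.0, 0.8, size=100_000)
        m = fit_gaussian(draws)
        assert m.mean == pytest.approx(5.0, abs=0.01)
        assert m.sd == pytest.approx(0.8, abs=0.01)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_gaussian([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match=">= 2"):
            fit_gaussian([1.0])
        with pytest.raises(ValueError, match=">= 2"):
            fit_gaussian([1.0, np.nan])


class TestIntersectionThreshold:
    def test_equal_variance_midpoint(self):
        assert intersection_threshold(N(1.0, 0.5), N(3.0, 0.5)) == 2.0
        assert intersection_threshold(N(0.0, 1.0), N(4.0, 1.0)) == 2.0

    def test_unequal_variance_against_numeric_root(self):
        """The quadratic root matches dense root-finding on the density
        difference, and lies between the means."""
        a, b = N(0.0, 1.0), N(2.0, 2.0)
        t = intersection_threshold(a, b)
        assert 0.0 < t < 2.0
        diff = lambda x: stats.norm.pdf(x, 0.0, 1.0) - stats.norm.pdf(x, 2.0, 2.0)
        t_oracle = brentq(diff, 0.0, 2.0, xtol=1e-14)
        assert t == pytest.approx(t_oracle, abs=1e-10)

    @pytest.mark.parametrize(
        "m1,s1,m2,s2",
        [(0, 1, 2, 2), (1, 0.3, 4, 1.5), (-3, 2, 5, 0.7), (0, 1, 0.5, 1.2)],
    )
    def test_density_equality_at_threshold(self, m1, s1, m2, s2):
        t = intersection_threshold(N(m1, s1), N(m2, s2))
        d1 = stats.norm.pdf(t, m1, s1)
        d2 = stats.norm.pdf(t, m2, s2)
        assert abs(d1 - d2) <= 1e-10

    def test_identical_distributions_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            intersection_threshold(N(1.0, 0.5), N(1.0, 0.5))

    def test_crossing_maximizes_balanced_accuracy(self):
        """For equal priors the density crossing is the balanced-accuracy-
        optimal cutoff; checked against a dense cutoff sweep on the
        population quantities."""
        a, b = N(1.0, 0.4), N(2.0, 0.9)
        t = intersection_threshold(a, b)

        def balanced_accuracy(cut):
            spec = stats.norm.cdf(cut, a.mean, a.sd)  # low class correct
            sens = 1.0 - stats.norm.cdf(cut, b.mean, b.sd)
            return 0.5 * (spec + sens)

        grid = np.linspace(a.mean - 3, b.mean + 3, 4001)
        assert balanced_accuracy(t) >= balanced_accuracy(grid).max() - 1e-9


class TestClassify:
    model = GaussianThresholdModel(
        class_a=N(1.0, 0.5, "cortex"), class_b=N(3.0, 0.5, "tumor"), threshold=2.0
    )

    def test_sides_of_threshold(self):
        assert classify(self.model, 2.5) == "tumor"
        assert classify(self.model, 1.2) == "cortex"

    def test_tie_goes_to_higher_mean_class(self):
        assert classify(self.model, 2.0) == "tumor"

    def test_not_computable_abstains(self):
        assert classify(self.model, float("nan")) == ABSTAIN

    def test_fit_threshold_model_end_to_end(self, rng):
        lo = rng.normal(2.0, 0.3, 500)
        hi = rng.normal(6.0, 0.3, 500)
        m = fit_threshold_model(lo, "normal", hi, "tumor")
        assert m.high_label == "tumor"
        assert 2.0 < m.threshold < 6.0

    def test_model_json_roundtrip(self, tmp_path):
        self.model.to_json(tmp_path / "m.json")
        back = GaussianThresholdModel.from_json(tmp_path / "m.json")
        assert back == self.model


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert r.auc == 1.0

    def test_exchangeable_groups(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        assert roc_auc(vals, vals).auc == 0.5

    def test_curve_endpoints_and_monotonicity(self, rng):
        r = roc_auc(rng.normal(5, 1, 200), rng.normal(3, 1, 200))
        assert r.fpr[0] == 0.0 and r.tpr[0] == 0.0
        assert r.fpr[-1] == 1.0 and r.tpr[-1] == 1.0
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)

    def test_binormal_closed_form(self, rng):
        """Empirical AUC on 1e4+1e4 N(3,1) vs N(5,1) draws matches the
        binormal value Phi(2/sqrt(2)) ~ 0.9214 within 0.01."""
        pos = rng.normal(5.0, 1.0, 10_000)
        neg = rng.normal(3.0, 1.0, 10_000)
        expected = stats.norm.cdf(2.0 / math.sqrt(2.0))
        assert roc_auc(pos, neg).auc == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize(
        "delta,s1,s2", [(0.5, 1.0, 1.0), (1.5, 0.5, 2.0), (3.0, 1.5, 1.5)]
    )
    def test_binormal_agreement_within_mc_error(self, delta, s1, s2):
        """Empirical AUC converges to Phi(dmu/sqrt(s1^2+s2^2)) within
        3 Monte-Carlo standard errors (Hanley-McNeil)."""
        rng = np.random.default_rng(hash((delta, s1, s2)) % 2**31)
        n = 4000
        pos = rng.normal(delta, s2, n)
        neg = rng.normal(0.0, s1, n)
        a = roc_auc(pos, neg).auc
        expected = stats.norm.cdf(delta / math.sqrt(s1**2 + s2**2))
        q1 = expected / (2 - expected)
        q2 = 2 * expected**2 / (1 + expected)
        var = (
            expected * (1 - expected)
            + (n - 1) * (q1 - expected**2)
            + (n - 1) * (q2 - expected**2)
        ) / (n * n)
        assert abs(a - expected) < 3 * math.sqrt(var) + 1e-9

    def test_auc_monotone_in_mean_separation(self):
        """With sd fixed, widening the mean gap never lowers the AUC."""
        rng = np.random.default_rng(5)
        neg = rng.normal(0.0, 1.0, 2000)
        shifts = rng.normal(0.0, 1.0, 2000)
        aucs = [roc_auc(shifts + d, neg).auc for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(b >= a for a, b in zip(aucs, aucs[1:]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestOneVsRestPool:
    @staticmethod
    def make_table(n_subjects=2, per_cell=5):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(n_subjects):
            for label, mu in [("tumor", 8.0), ("cortex", 2.5), ("medulla", 1.5)]:
                for _ in range(per_cell):
                    rows.append(
                        {
                            "subject_id": f"subject{s}",
                            "label": label,
                            "mu": rng.normal(mu, 0.2),
                        }
                    )
        return pd.DataFrame(rows)

    def test_balanced_counts(self):
        table = self.make_table(n_subjects=2, per_cell=5)
        pos, neg = one_vs_rest_pool(table, "tumor", per_class_subsample=3, seed=1)
        assert pos.size == 10  # all tumor images
        assert neg.size == 3 * 2 * 2  # subsample x normal classes x subjects

    def test_deterministic_from_seed(self):
        table = self.make_table()
        a = one_vs_rest_pool(table, "tumor", 3, seed=7)
        b = one_vs_rest_pool(table, "tumor", 3, seed=7)
        np.testing.assert_array_equal(a[1], b[1])

    def test_zero_subsample_rejected(self):
        with pytest.raises(ValueError):
            one_vs_rest_pool(self.make_table(), "tumor", 0)

    def test_insufficient_images_rejected(self):
        with pytest.raises(ValueError, match="fewer"):
            one_vs_rest_pool(self.make_table(per_cell=2), "tumor", 10)


class TestLikelihoodClassifier:
    def test_nearest_class_wins(self):
        models = {
            "cortex": N(2.5, 0.3, "cortex"),
            "tumor": N(8.0, 0.3, "tumor"),
        }
        clf = LikelihoodClassifier(models)
        assert clf.predict_one(7.5) == "tumor"
        assert clf.predict_one(2.0) == "cortex"
        assert clf.predict_one(float("nan")) == ABSTAIN

    def test_fit_from_table(self):
        table = TestOneVsRestPool.make_table(n_subjects=3, per_cell=20)
        clf = LikelihoodClassifier.fit(table)
        assert set(clf.labels) == {"tumor", "cortex", "medulla"}
        assert clf.predict_one(8.1) == "tumor"
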