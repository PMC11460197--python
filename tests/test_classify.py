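"""Logistic panels, Mann-Whitney AUC, DeLong variance and test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from plasmatmt import ConfigurationError
from plasmatmt.classify import (
    delong_test,
    eligible_proteins,
    fit_logistic_panel,
    rank_and_panel,
    roc_auc,
)

from conftest import make_matrix, make_metadata


def auc_oracle(scores, labels):
    """Brute-force pair enumeration, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s_p in pos:
        for s_n in neg:
            total += 1.0 if s_p > s_n else (0.5 if s_p == s_n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.ci[1] == 1.0

    def test_tied_pair_enumeration(self):
        res = roc_auc([3, 2, 2, 1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(3.5 / 4)

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 120))
            scores = rng.integers(0, 8, n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(auc_oracle(scores, labels),
                                            abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(base)
        assert roc_auc(3 * scores - 7, labels).auc == pytest.approx(base)

    def test_curve_endpoints_and_monotonicity(self, rng):
        res = roc_auc(rng.normal(size=60), rng.integers(0, 2, 60))
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()

    def test_ci_contains_auc(self, rng):
        res = roc_auc(rng.normal(size=80) + rng.integers(0, 2, 80),
                      rng.integers(0, 2, 80))
        assert res.ci[0] <= res.auc <= res.ci[1]

    def test_null_scores_near_half(self, rng):
        aucs = [roc_auc(rng.normal(size=200),
                        np.repeat([0, 1], 100)).auc for _ in range(20)]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_youden_threshold_marked(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        table = res.threshold_table
        best = table[table["optimal"]]
        assert len(best) == 1
        assert best["youden"].iloc[0] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_delong_se_close_to_bootstrap(self, rng):
        n = 100
        labels = np.repeat([0, 1], n // 2)
        scores = rng.normal(size=n) + labels * 1.0
        res = roc_auc(scores, labels)
        boot = []
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for _ in range(3000):
            bp = rng.choice(pos, len(pos))
            bn = rng.choice(neg, len(neg))
            boot.append(roc_auc(np.r_[bn, bp], labels).auc)
        se_boot = np.std(boot, ddof=1)
        assert np.sqrt(res.variance) == pytest.approx(se_boot, rel=0.15)


class TestDeLongTest:
    def test_identical_scores_null(self, rng):
        s = rng.normal(size=60)
        y = rng.integers(0, 2, 60)
        z, p, d = delong_test(s, s, y)
        assert (z, p, d) == (0.0, 1.0, 0.0)

    def test_monotone_transform_null(self, rng):
        s = rng.normal(size=60)
        y = np.repeat([0, 1], 30)
        z, p, d = delong_test(s, np.exp(s) + 5, y)
        assert d == pytest.approx(0.0)
        assert p == 1.0

    def test_detects_genuinely_better_marker(self, rng):
        y = np.repeat([0, 1], 150)
        good = y * 2.0 + rng.normal(size=300)
        bad = rng.normal(size=300)
        z, p, d = delong_test(good, bad, y)
        assert d > 0.2 and p < 1e-4

    def test_matches_paired_bootstrap_p(self, rng):
        """Two correlated markers: DeLong p within Monte-Carlo reach of a
        paired-bootstrap test of delta AUC = 0."""
        n = 150
        y = np.repeat([0, 1], n // 2)
        shared = rng.normal(size=n)
        a = shared + 0.9 * y + 0.8 * rng.normal(size=n)
        b = shared + 0.5 * y + 0.8 * rng.normal(size=n)
        z, p, d = delong_test(a, b, y)
        deltas = []
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        for _ in range(2000):
            take = np.r_[rng.choice(idx_neg, len(idx_neg)),
                         rng.choice(idx_pos, len(idx_pos))]
            deltas.append(roc_auc(a[take], y[take]).auc
                          - roc_auc(b[take], y[take]).auc)
        se = np.std(deltas, ddof=1)
        from scipy import stats
        p_boot = 2 * stats.norm.sf(abs(d) / se)
        # both are normal-approximation tests of the same quantity
        assert abs(np.log10(max(p, 1e-12)) - np.log10(max(p_boot, 1e-12))) < 1.0


class TestLogisticPanel:
    def test_uninformative_feature_gives_chance_auc(self, rng):
        X = pd.DataFrame({"f": np.tile(rng.normal(size=20), 2)})
        y = pd.Series(np.repeat([0, 1], 20))
        X.index = y.index
        model = fit_logistic_panel(X, y)
        assert abs(model.coefficients["f"]) < 0.5
        assert roc_auc(model.scores, y).auc == pytest.approx(0.5, abs=0.15)

    def test_separation_flagged(self):
        y = pd.Series([0, 0, 0, 1, 1, 1])
        X = pd.DataFrame({"f": [0.0, 0.1, 0.2, 1.0, 1.1, 1.2]}, index=y.index)
        model = fit_logistic_panel(X, y)
        assert model.separation
        assert roc_auc(model.scores, y).auc == 1.0

    def test_loglik_non_decreasing(self, rng):
        X = pd.DataFrame({"f": rng.normal(size=50),
                          "g": rng.normal(size=50)})
        y = pd.Series((rng.random(50) < expit(X["f"])).astype(int))
        model = fit_logistic_panel(X, y)
        path = np.array(model.loglik_path)
        assert (np.diff(path) >= -1e-9).all()
        assert model.converged

    def test_grid_search_oracle_six_points(self):
        """Coefficients maximize the exact likelihood on a 6-point fixture."""
        # classes overlap on x, so the maximum-likelihood fit is finite
        y = pd.Series([0, 1, 0, 1, 1, 0])
        x = np.array([-1.0, 0.5, 0.3, 1.5, -0.2, 0.9])
        X = pd.DataFrame({"f": x}, index=y.index)
        model = fit_logistic_panel(X, y)
        xs = (x - x.mean()) / x.std(ddof=1)

        def loglik(b0, b1):
            eta = b0 + b1 * xs
            return np.sum(y * eta - np.log1p(np.exp(eta)))

        # step 1e-3 around the IRLS solution: the exact-likelihood argmax
        # must sit within one grid step of it
        b0_grid = np.linspace(model.intercept - 0.1, model.intercept + 0.1, 201)
        b1_grid = np.linspace(model.coefficients["f"] - 0.1,
                              model.coefficients["f"] + 0.1, 201)
        ll = np.array([[loglik(b0, b1) for b1 in b1_grid] for b0 in b0_grid])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert b0_grid[i] == pytest.approx(model.intercept, abs=1.5e-3)
        assert b1_grid[j] == pytest.approx(model.coefficients["f"], abs=1.5e-3)

    def test_matches_statsmodels_glm(self, rng):
        import statsmodels.api as sm
        X = pd.DataFrame({"f": rng.normal(size=80),
                          "g": rng.normal(size=80)})
        y = pd.Series((rng.random(80) <
                       expit(0.5 * X["f"] - 0.8 * X["g"])).astype(int))
        model = fit_logistic_panel(X, y)
        Xs = (X - X.mean()) / X.std(ddof=1)
        ref = sm.GLM(y, sm.add_constant(Xs),
                     family=sm.families.Binomial()).fit()
        assert model.intercept == pytest.approx(ref.params["const"], abs=1e-5)
        assert model.coefficients["f"] == pytest.approx(ref.params["f"],
                                                        abs=1e-5)
        assert model.coefficients["g"] == pytest.approx(ref.params["g"],
                                                        abs=1e-5)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(ConfigurationError):
            fit_logistic_panel(X, pd.Series([1, 1]))


class TestEligibility:
    def test_thresholds_and_completeness(self):
        meta_table = pd.DataFrame(
            {"meta_p": [5e-5, 1e-4, 5e-5, 2e-3]},
            index=pd.Index(["P1", "P2", "P3", "P4"], name="protein_id"))
        vals = np.ones((4, 4))
        vals[2, 1] = np.nan
        mat = make_matrix(vals, protein_ids=list(meta_table.index),
                          scale="corrected")
        ids, cohort = eligible_proteins(meta_table, mat)
        # P2 sits exactly at the cutoff (strict <), P3 has a missing value
        assert ids == ["P1"]
        assert len(cohort) == 4

    def test_duplicate_controls_removed(self):
        meta_table = pd.DataFrame({"meta_p": [1e-6]},
                                  index=pd.Index(["P1"], name="protein_id"))
        mat = make_matrix(np.ones((1, 4)),
                          sample_ids=["a", "b", "b2", "c"], scale="corrected")
        meta = make_metadata(["a", "b", "b2", "c"],
                             subject_id=["sa", "sb", "sb", "sc"])
        ids, cohort = eligible_proteins(meta_table, mat, meta)
        assert cohort == ["a", "b", "c"]


class TestRankAndPanel:
    def test_strong_marker_hits_binormal_auc(self, rng):
        """A marker with standardized effect d has AUC = Phi(d / sqrt(2))."""
        from scipy import stats
        n = 200
        labels = pd.Series(np.repeat([0, 1], n),
                           index=[f"s{j}" for j in range(2 * n)])
        d = 2.0
        vals = rng.normal(size=(3, 2 * n))
        vals[0] += d * labels.to_numpy()
        mat = make_matrix(vals, sample_ids=list(labels.index),
                          scale="corrected")
        report = rank_and_panel(mat, labels, k=2)
        assert report.ranked.index[0] == "P0"
        expected = stats.norm.cdf(d / np.sqrt(2))
        assert report.ranked["auc"].iloc[0] == pytest.approx(expected,
                                                             abs=0.05)

    def test_panel_at_least_best_single(self, rng):
        n = 300
        labels = pd.Series(np.repeat([0, 1], n),
                           index=[f"s{j}" for j in range(2 * n)])
        vals = rng.normal(size=(4, 2 * n)) + 0.8 * labels.to_numpy()
        mat = make_matrix(vals, sample_ids=list(labels.index),
                          scale="corrected")
        report = rank_and_panel(mat, labels, k=4)
        assert report.panel_roc.auc >= report.ranked["auc"].max() - 0.01

    def test_inverted_marker_flipped(self, rng):
        n = 100
        labels = pd.Series(np.repeat([0, 1], n),
                           index=[f"s{j}" for j in range(2 * n)])
        vals = rng.normal(size=(1, 2 * n)) - 1.5 * labels.to_numpy()
        mat = make_matrix(vals, sample_ids=list(labels.index),
                          scale="corrected")
        report = rank_and_panel(mat, labels, k=1)
        assert bool(report.ranked["flipped"].iloc[0])
        assert report.ranked["auc"].iloc[0] > 0.5

    def test_covariate_comparison_present(self, rng):
        n = 60
        labels = pd.Series(np.repeat([0, 1], n),
                           index=[f"s{j}" for j in range(2 * n)])
        vals = rng.normal(size=(2, 2 * n)) + 0.7 * labels.to_numpy()
        mat = make_matrix(vals, sample_ids=list(labels.index),
                          scale="corrected")
        cov = pd.Series(rng.normal(size=2 * n) + 1.2 * labels.to_numpy(),
                        index=labels.index)
        report = rank_and_panel(mat, labels, covariate=cov, k=2)
        assert report.covariate_roc is not None
        z, p, dauc = report.delong_covariate_vs_combined
        assert 0 <= p <= 1

    def test_oversized_panel_warns_and_uses_all(self, rng):
        labels = pd.Series(np.repeat([0, 1], 20),
                           index=[f"s{j}" for j in range(40)])
        mat = make_matrix(rng.normal(size=(2, 40)),
                          sample_ids=list(labels.index), scale="corrected")
        with pytest.warns(UserWarning, match="panel size"):
            report = rank_and_panel(mat, labels, k=5)
        assert len(report.panel.members) == 2
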