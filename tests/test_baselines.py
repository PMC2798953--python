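"""Read-count rule, junction features, IRLS logistic fit, AUC, comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mmes_splice.baselines import (
    compare_methods,
    cross_validated_auc,
    extract_features,
    fit_logit,
    rank_auc,
    read_count_call,
)


def calls_with_R(r_values):
    return pd.DataFrame(
        {"junction_id": [f"j{i}" for i in range(len(r_values))], "R": r_values,
         "p_value": 0.5, "log10_p": np.log10(0.5)}
    )


class TestReadCount:
    def test_boundary(self):
        acc = read_count_call(calls_with_R([1, 2, 3]), R_threshold=2)
        assert list(acc) == [False, True, True]

    def test_threshold_one_accepts_everything(self):
        assert read_count_call(calls_with_R([1, 5]), 1).all()

    def test_monotone_in_threshold(self):
        calls = calls_with_R(list(range(1, 10)))
        prev = set(read_count_call(calls, 1).index[read_count_call(calls, 1)])
        for thr in range(2, 10):
            acc = read_count_call(calls, thr)
            cur = set(acc.index[acc])
            assert cur <= prev
            prev = cur


def frame_from_rows(rows):
    """rows: (junction_id, offset, L_arm, R_arm, M, N)"""
    df = pd.DataFrame(
        rows, columns=["junction_id", "offset", "L_arm", "R_arm", "M", "N"]
    )
    df["is_unique"] = True
    return df


class TestFeatures:
    def test_single_read_junction(self):
        f = extract_features(frame_from_rows([("j", 3, 18, 7, 1, 6)]))
        row = f.iloc[0]
        assert (row.n_reads, row.n_distinct_offsets, row.offset_entropy) == (1, 1, 0.0)
        assert row.min_mismatches == 1 and row.mean_mismatches == 1.0
        assert row.max_overhang == 7

    def test_two_offsets_equal_frequency_entropy_one_bit(self):
        f = extract_features(
            frame_from_rows(
                [("j", 3, 18, 7, 0, 7), ("j", 9, 12, 13, 0, 12)]
            )
        )
        assert f.iloc[0].offset_entropy == pytest.approx(1.0)

    def test_centered_read_overhang(self):
        f = extract_features(frame_from_rows([("j", 9, 12, 13, 0, 12)]))
        assert f.iloc[0].max_overhang == 12

    def test_max_mmes_only_when_requested(self):
        rows = [("j", 3, 18, 7, 0, 7), ("j", 9, 12, 13, 0, 12)]
        assert "max_mmes" not in extract_features(frame_from_rows(rows)).columns
        with_m = extract_features(frame_from_rows(rows), include_mmes=True)
        assert with_m.iloc[0].max_mmes == 12


def scipy_logit_oracle(X, y):
    """Brute-force maximum likelihood on the raw feature scale."""
    X1 = np.column_stack([np.ones(len(y)), X])

    def nll(beta):
        eta = X1 @ beta
        return np.sum(np.log1p(np.exp(-(2 * y - 1) * eta)))

    res = optimize.minimize(nll, np.zeros(X1.shape[1]), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        y = np.array([1] * 25 + [0] * 75)
        model = fit_logit(np.zeros((100, 0)), y, feature_names=[])
        assert model.coef[0] == pytest.approx(math.log(0.25 / 0.75), abs=1e-8)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(50, 2))
        eta = 0.5 + X @ np.array([1.0, -0.7])
        y = (rng.random(50) < 1 / (1 + np.exp(-eta))).astype(float)
        model = fit_logit(X, y)
        oracle = scipy_logit_oracle(X, y)
        assert np.allclose(model.coef_raw, oracle, atol=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(23)
        X = rng.normal(size=(200, 3))
        y = (rng.random(200) < 1 / (1 + np.exp(-(X @ [0.8, -0.5, 0.2])))).astype(float)
        model = fit_logit(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(model.coef_raw, ref.params, atol=1e-6)
        assert model.lrt_chi2 == pytest.approx(ref.llr, rel=1e-6)

    def test_replication_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 2))
        y = (rng.random(40) < 0.5).astype(float)
        if y.sum() in (0, len(y)):
            y[0] = 1 - y[0]
        m1 = fit_logit(X, y)
        m2 = fit_logit(np.vstack([X, X]), np.concatenate([y, y]))
        assert np.allclose(m1.coef, m2.coef, atol=1e-8)

    def test_separation_flagged_and_ordering_preserved(self):
        X = np.concatenate([np.linspace(-2, -1, 20), np.linspace(1, 2, 20)])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        model = fit_logit(X, y)
        assert model.separated
        p = model.predict_proba(X)
        assert p[y == 1].min() > p[y == 0].max()

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logit(np.zeros((5, 1)), np.ones(5))

    def test_wald_and_lrt_reported(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 2))
        y = (rng.random(300) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        model = fit_logit(X, y)
        assert model.wald_z is not None and len(model.wald_z) == 3
        assert model.lrt_df == 2 and model.lrt_chi2 > 0
        assert 0 <= model.lrt_pvalue <= 1


class TestAuc:
    def test_perfect_classifier(self):
        assert rank_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 10_000
        scores = rng.normal(size=n)
        labels = rng.random(n) < 0.5
        n1, n0 = labels.sum(), (~labels).sum()
        se = math.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(rank_auc(scores, labels) - 0.5) < 3 * se

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.4
        a = rank_auc(scores, labels)
        assert rank_auc(np.exp(scores), labels) == pytest.approx(a)
        assert rank_auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        scores = rng.normal(size=500).round(1)  # ties on purpose
        labels = rng.random(500) < 0.3
        assert rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores)
        )

    def test_cross_validation_requires_both_classes_per_fold(self):
        X = pd.DataFrame({"x": np.arange(20.0)})
        y = np.array([1] * 3 + [0] * 17)
        with pytest.raises(ValueError):
            cross_validated_auc(X, y, k_folds=10, seed=0)

    def test_cross_validation_deterministic(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame({"x": rng.normal(size=80), "z": rng.normal(size=80)})
        y = (rng.random(80) < 0.5).astype(int)
        a1 = cross_validated_auc(X, y, k_folds=4, seed=1)
        a2 = cross_validated_auc(X, y, k_folds=4, seed=1)
        assert a1 == a2


class TestCompare:
    def series(self, mapping):
        return pd.Series(mapping)

    def test_identical_sets_all_common(self):
        a = self.series({"j1": True, "j2": True, "j3": False})
        out = compare_methods(a, a).set_index("category")
        assert out.loc["Common", "n"] == 2
        assert out.loc["A_uniq", "n"] == 0 and out.loc["B_uniq", "n"] == 0

    def test_disjoint_sets(self):
        a = self.series({"j1": True, "j2": False})
        b = self.series({"j1": False, "j2": True})
        out = compare_methods(a, b).set_index("category")
        assert out.loc["Common", "n"] == 0
        assert out.loc["A_uniq", "n"] == 1 and out.loc["B_uniq", "n"] == 1

    def test_known_overlap_counts(self):
        universe = [f"j{i}" for i in range(30)]
        a = self.series({j: j in {f"j{i}" for i in range(10)} for j in universe})
        b = self.series({j: j in {f"j{i}" for i in range(3, 15)} for j in universe})
        out = compare_methods(a, b).set_index("category")
        assert out.loc["Common", "n"] == 7
        assert out.loc["A_uniq", "n"] == 3
        assert out.loc["B_uniq", "n"] == 5

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            compare_methods(
                self.series({"j1": True}), self.series({"j2": True})
            )

    def test_ppv_with_truth(self):
        a = self.series({"j1": True, "j2": True, "j3": False})
        b = self.series({"j1": True, "j2": False, "j3": False})
        out = compare_methods(a, b, truth={"j1"}).set_index("category")
        assert out.loc["Common", "ppv"] == 1.0
        assert out.loc["A_uniq", "ppv"] == 0.0
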