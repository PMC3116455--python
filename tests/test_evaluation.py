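import numpy as np
import pytest
from scipy import stats

from ppisem.evaluation import (
    CVPlan,
    EvaluationError,
    auc_score,
    compute_metrics,
    corrected_ttest,
    make_folds,
    run_experiment,
    tune_gaussian_theta,
)
from ppisem.synthetic import GeneratorSpec, generate_labeled


class TestMakeFolds:
    def test_sentence_scheme_equal_folds(self):
        plan = CVPlan(k=10, r=1, scheme="sentence", seed=0)
        folds = make_folds([str(i) for i in range(100)], None, plan)[0]
        assert [len(f) for f in folds] == [10] * 10

    def test_fold_sizes_within_one(self):
        plan = CVPlan(k=7, r=1, scheme="sentence", seed=0)
        folds = make_folds([str(i) for i in range(94)], None, plan)[0]
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_partition_per_repetition(self):
        plan = CVPlan(k=5, r=3, scheme="sentence", seed=1)
        for rep_folds in make_folds([str(i) for i in range(53)], None, plan):
            allidx = np.sort(np.concatenate(rep_folds))
            np.testing.assert_array_equal(allidx, np.arange(53))

    def test_abstract_scheme_never_splits_abstract(self):
        abstracts = [f"ab{i // 4}" for i in range(80)]  # 20 abstracts
        plan = CVPlan(k=10, r=3, scheme="abstract", seed=2)
        folds = make_folds([str(i) for i in range(80)], abstracts, plan)
        for rep_folds in folds:
            seen = {}
            for f, idx in enumerate(rep_folds):
                for i in idx:
                    a = abstracts[i]
                    assert seen.setdefault(a, f) == f

    def test_abstract_scheme_requires_ids(self):
        with pytest.raises(EvaluationError):
            make_folds(["a", "b"], None, CVPlan(k=2, r=1, scheme="abstract"))

    def test_too_many_folds(self):
        with pytest.raises(EvaluationError):
            make_folds(["a", "b"], None, CVPlan(k=3, r=1))
        with pytest.raises(EvaluationError):
            make_folds(
                ["a", "b", "c"],
                ["x", "x", "x"],
                CVPlan(k=2, r=1, scheme="abstract"),
            )

    def test_deterministic_given_seed(self):
        plan = CVPlan(k=4, r=2, seed=9)
        ids = [str(i) for i in range(37)]
        f1 = make_folds(ids, None, plan)
        f2 = make_folds(ids, None, plan)
        for a, b in zip(f1, f2):
            for fa, fb in zip(a, b):
                np.testing.assert_array_equal(fa, fb)


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=3, FP=1, FN=2, TN=4
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.3, 0.2, 0.1])
        ms = compute_metrics(labels, scores)
        assert ms.precision == pytest.approx(0.75)
        assert ms.recall == pytest.approx(0.6)
        assert ms.f_score == pytest.approx(2 * 0.75 * 0.6 / 1.35)
        assert ms.f_score == pytest.approx(0.66667, abs=1e-4)
        assert ms.error_pct == pytest.approx(30.0)

    def test_perfect_ranking_auc(self):
        labels = np.array([0, 0, 1, 1])
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        assert compute_metrics(labels, scores).auc == 1.0

    def test_f_symmetric_point(self):
        # P = R = 0.5 -> F = 0.5: TP=1, FP=1, FN=1
        labels = np.array([1, 1, 0])
        scores = np.array([0.9, 0.1, 0.8])
        ms = compute_metrics(labels, scores)
        assert ms.precision == 0.5 and ms.recall == 0.5 and ms.f_score == 0.5

    def test_zero_denominators(self):
        ms = compute_metrics(np.array([1, 0]), np.array([0.1, 0.2]))
        assert ms.precision == 0.0 and ms.recall == 0.0 and ms.f_score == 0.0

    def test_single_class_auc_missing_with_warning(self):
        with pytest.warns(UserWarning):
            ms = compute_metrics(np.array([1, 1]), np.array([0.9, 0.8]))
        assert ms.auc is None

    def test_auc_ties_half_credit(self):
        labels = np.array([1, 0])
        scores = np.array([0.5, 0.5])
        assert auc_score(labels, scores) == 0.5

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(5):
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(50), 1)  # force ties
            assert auc_score(labels, scores) == pytest.approx(
                roc_auc_score(labels, scores)
            )


class TestCorrectedTTest:
    def test_identical_vectors(self):
        a = np.linspace(0, 1, 100)
        t, p = corrected_ttest(a, a)
        assert t == 0.0 and p == 1.0

    def test_constant_difference_degenerate(self):
        a = np.full(100, 0.8)
        b = np.full(100, 0.7)
        t, p = corrected_ttest(a, b)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_hand_computed_fixture(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.75, 0.05, 100)
        b = rng.normal(0.70, 0.05, 100)
        t, p = corrected_ttest(a, b, k=10, r=10)
        d = a - b
        expected_t = d.mean() / np.sqrt(d.var(ddof=1) * (1 / 100 + 1 / 9))
        expected_p = 2 * stats.t.sf(abs(expected_t), df=99)
        assert t == pytest.approx(expected_t)
        assert p == pytest.approx(expected_p)

    def test_reduces_to_classical_paired_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0.7, 0.1, 100)
        b = rng.normal(0.68, 0.1, 100)
        t_corr, _ = corrected_ttest(a, b, k=10, r=10, test_fraction=0.0)
        t_classical = stats.ttest_rel(a, b).statistic
        assert t_corr == pytest.approx(t_classical)

    def test_monotone_in_mean_difference(self):
        rng = np.random.default_rng(4)
        noise = rng.normal(0, 0.05, 100)
        ts = []
        for shift in (0.01, 0.03, 0.09):
            t, _ = corrected_ttest(noise + shift, np.zeros(100))
            ts.append(t)
        assert ts[0] < ts[1] < ts[2]

    def test_conservative_under_null(self):
        # identical pipelines, different seeds: rejection rate stays low
        rng = np.random.default_rng(5)
        rejections = 0
        n_exp = 100
        for _ in range(n_exp):
            base = rng.normal(0.8, 0.04, 100)
            other = rng.normal(0.8, 0.04, 100)
            _, p = corrected_ttest(base, other)
            rejections += p < 0.05
        assert rejections <= 15  # ~10% would already be conservative

    def test_length_check(self):
        with pytest.raises(EvaluationError):
            corrected_ttest(np.ones(50), np.ones(50), k=10, r=10)


class TestTuneTheta:
    @staticmethod
    def _xor_blobs(seed=7, n=160):
        # neighbouring blob centres are sqrt(10) apart, so theta = 0.1
        # matches the length scale while tiny thetas degenerate to a
        # near-linear kernel that cannot express the XOR labelling
        rng = np.random.default_rng(seed)
        s = np.sqrt(5.0)
        centers = np.array([[s, s], [-s, -s], [s, -s], [-s, s]])
        labels = np.array([0, 0, 1, 1])
        idx = rng.integers(0, 4, n)
        X = centers[idx] + rng.normal(0, 1.0, (n, 2))
        return X, labels[idx]

    def test_known_optimum_selected(self):
        X, y = self._xor_blobs()
        theta = tune_gaussian_theta([X], ["gaussian"], [{}], y)
        assert theta == 0.1

    def test_tie_breaks_to_smaller(self, monkeypatch):
        import ppisem.evaluation as ev

        monkeypatch.setattr(
            ev, "_fit_predict_auc", lambda *a, **k: 0.5
        )
        X, y = self._xor_blobs(n=60)
        theta = ev.tune_gaussian_theta([X], ["gaussian"], [{}], y, grid=(0.01, 0.1, 1.0))
        assert theta == 0.01

    def test_single_value_grid(self):
        X, y = self._xor_blobs(n=30)
        assert tune_gaussian_theta([X], ["gaussian"], [{}], y, grid=(0.5,)) == 0.5


class TestRunExperiment:
    @staticmethod
    def _config(seed=0, scheme="sentence", r=2, k=5):
        spec = GeneratorSpec(
            n_background=40,
            n_trigger_clusters=3,
            synonyms_per_cluster=2,
            n_labeled_sentences=120,
            positive_rate=0.4,
            sentence_length=(4, 7),
            n_unlabeled_sentences=50,
            seed=seed,
        )
        return {
            "seed": seed,
            "labeled_sentences": generate_labeled(spec),
            "cv": {"k": k, "r": r, "scheme": scheme},
            "tuning": {"mode": "none"},
            "classifier": {"max_iter": 15},
            "pipelines": [
                {
                    "name": "plain_gaussian",
                    "kernels": [{"kind": "gaussian", "theta": 0.1}],
                }
            ],
        }

    def test_complete_table_row(self):
        result = run_experiment(self._config())
        row = result["rows"][0]
        assert row.pipeline == "plain_gaussian"
        assert row.n_folds == 10
        assert set(row.mean) <= {"f_score", "error_pct", "precision", "recall", "auc"}
        assert len(result["fold_records"]["plain_gaussian"]) == 10

    def test_determinism(self):
        r1 = run_experiment(self._config(seed=5))
        r2 = run_experiment(self._config(seed=5))
        a = [rec.metrics for rec in r1["fold_records"]["plain_gaussian"]]
        b = [rec.metrics for rec in r2["fold_records"]["plain_gaussian"]]
        assert a == b

    def test_both_schemes_run_and_compare(self):
        res_s = run_experiment(self._config(scheme="sentence", r=2, k=5))
        res_a = run_experiment(self._config(scheme="abstract", r=2, k=5))
        fa = [r.metrics.auc for r in res_s["fold_records"]["plain_gaussian"]]
        fb = [r.metrics.auc for r in res_a["fold_records"]["plain_gaussian"]]
        t, p = corrected_ttest(fa, fb, k=5, r=2)
        assert np.isfinite(t) and 0.0 <= p <= 1.0

    def test_invalid_config_rejected_before_compute(self):
        cfg = self._config()
        cfg["pipelines"][0]["kernels"][0]["kind"] = "sigmoid"
        with pytest.raises(EvaluationError):
            run_experiment(cfg)

    def test_unknown_smoother_rejected(self):
        cfg = self._config()
        cfg["pipelines"][0]["kernels"][0]["smoother"] = "ghost"
        with pytest.raises(EvaluationError):
            run_experiment(cfg)

    def test_smoothed_and_distance_kernels_via_config(self):
        from ppisem.synthetic import generate_unlabeled

        spec = GeneratorSpec(
            n_background=40,
            n_trigger_clusters=3,
            synonyms_per_cluster=2,
            n_labeled_sentences=80,
            positive_rate=0.4,
            sentence_length=(4, 7),
            n_unlabeled_sentences=300,
            seed=8,
        )
        cfg = {
            "seed": 8,
            "labeled_sentences": generate_labeled(spec),
            "unlabeled_tokens": generate_unlabeled(spec),
            "cv": {"k": 4, "r": 1},
            "tuning": {"mode": "none"},
            "classifier": {"max_iter": 10},
            "smoothers": {
                "hal3": {"model": "hal", "L": 3},
                "hal_l1": {"model": "hal_distance", "L": 3, "l": 1},
                "beag": {"model": "beagle", "D": 64},
            },
            "pipelines": [
                {
                    "name": "combo",
                    "mode": "infer",
                    "kernels": [
                        {"kind": "gaussian", "theta": 1e-5, "smoother": "hal3"},
                        {"kind": "gaussian", "theta": 1e-5, "smoother": "hal_l1"},
                        {"kind": "cosine", "smoother": "beag"},
                    ],
                }
            ],
        }
        result = run_experiment(cfg)
        recs = result["fold_records"]["combo"]
        assert len(recs) == 4
        for rec in recs:
            assert 0.0 <= rec.metrics.error_pct <= 100.0

    def test_provenance_block(self):
        res = run_experiment(self._config())
        prov = res["provenance"]
        assert "stop_list_hash" in prov and "seed" in prov
        assert prov["n_sentences"] == 120
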