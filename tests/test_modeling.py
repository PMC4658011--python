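import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

import radbpe as rb
from radbpe.errors import PairingError, RadbpeError
from radbpe.modeling import (
    chi2_statistic,
    exact_signed_rank_p,
    linear_svm_decision,
    rank_auc,
    _discretize,
)
from radbpe.tables import BlockSpec


class TestChi2Rank:
    def test_perfectly_aligned_binary_feature_scores_40(self):
        # 2x2 table [[20,0],[0,20]]: chi2 = sum (O-E)^2/E = 4 * (10^2/10) = 40
        y = np.repeat([0, 1], 20)
        frame = pd.DataFrame({"flag": y.astype(float)})
        ranked = rb.chi2_rank(frame, y)
        assert ranked[0] == ("flag", pytest.approx(40.0))

    def test_statistic_matches_scipy_contingency_oracle(self, rng):
        for _ in range(20):
            y = (rng.random(120) < 0.4).astype(int)
            if y.sum() in (0, 120):
                continue
            x = rng.normal(size=120) + 0.5 * y
            codes = _discretize(x, 10)
            table = pd.crosstab(codes, y).to_numpy()
            expected = stats.chi2_contingency(table, correction=False).statistic
            assert chi2_statistic(codes, y) == pytest.approx(expected)

    def test_independent_feature_rarely_significant(self):
        significant = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = (rng.random(1000) < 0.5).astype(int)
            x = rng.normal(size=1000)
            stat = chi2_statistic(_discretize(x, 10), y)
            p = stats.chi2.sf(stat, df=9)
            significant += p < 0.05
        assert significant <= 5  # ~5% nominal

    def test_label_permutation_decorrelates_ranking(self, study_table):
        rng = np.random.default_rng(0)
        frame = study_table.frame
        orig = rb.chi2_rank(frame, study_table.labels)
        orig_rank = {name: i for i, (name, _) in enumerate(orig)}
        rhos = []
        for _ in range(10):
            perm = rng.permutation(study_table.labels)
            if perm.sum() in (0, len(perm)):
                continue
            shuffled = rb.chi2_rank(frame, perm)
            rhos.append(stats.spearmanr(
                [orig_rank[n] for n, _ in shuffled], range(len(shuffled))
            ).statistic)
        assert abs(np.mean(rhos)) < 0.2

    def test_single_class_rejected(self):
        frame = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(RadbpeError):
            rb.chi2_rank(frame, np.zeros(10, dtype=int))


class TestFastSvmPath:
    def test_decision_values_match_public_svc(self, rng):
        # the low-level path used inside SFFS must agree with the public
        # estimator to numerical precision, including sign orientation
        for _ in range(10):
            X = rng.standard_normal((60, 4))
            y = (rng.random(60) < 0.35).astype(int)
            if y.sum() in (0, 60):
                continue
            Xt = rng.standard_normal((15, 4))
            fast = linear_svm_decision(X, y, Xt, 1.0)
            ref = SVC(kernel="linear", C=1.0).fit(X, y).decision_function(Xt)
            assert np.allclose(fast, ref, atol=1e-8)

    def test_rank_auc_matches_sklearn(self, rng):
        for _ in range(10):
            y = (rng.random(40) < 0.3).astype(int)
            if y.sum() in (0, 40):
                continue
            s = rng.normal(size=40)
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s))


class TestSffs:
    @staticmethod
    def _config(**kw):
        defaults = dict(folds=5, repetitions=1, rank_keep=10, sffs_max_size=5,
                        inner_folds=5, seed=0)
        defaults.update(kw)
        return rb.CvConfig(**defaults)

    def test_dominant_feature_selected_alone(self, rng):
        n = 80
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 8))
        X[:, 3] = y * 10.0 + rng.normal(scale=0.01, size=n)  # perfect separator
        sel = rb.sffs_select(X, y, list(range(8)), self._config(), inner_seed=1)
        assert sel == [3]

    def test_max_size_one_equals_exhaustive_single_search(self, rng):
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        y[:5] = 1
        y[-5:] = 0
        X = rng.standard_normal((n, 6)) + 0.4 * y[:, None] * rng.random(6)
        cfg = self._config(sffs_max_size=1)
        from radbpe.modeling import _inner_auc
        from sklearn.model_selection import StratifiedKFold

        sel = rb.sffs_select(X, y, list(range(6)), cfg, inner_seed=3)
        splits = list(StratifiedKFold(5, shuffle=True, random_state=3).split(X, y))
        scores = [_inner_auc(X, y, (j,), splits, 1.0) for j in range(6)]
        assert sel == [int(np.argmax(scores))]

    def test_jointly_informative_pair_selected_together(self):
        # suppressor construction: x1 = signal + w, x2 = w; each is nearly
        # uninformative alone but x1 - x2 separates the classes, so the
        # floating search must keep both
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            y = np.repeat([0, 1], n // 2)
            signal = y + 0.3 * rng.standard_normal(n)
            w = 3.0 * rng.standard_normal(n)
            X = np.column_stack([
                signal + w,
                w,
                rng.standard_normal((n, 4)).T.reshape(4, n).T,
            ])
            sel = rb.sffs_select(X, y, list(range(6)), self._config(), inner_seed=seed)
            hits += {0, 1} <= set(sel)
        assert hits >= 8


class TestNestedCv:
    @staticmethod
    def _small_table(seed=0, n=60):
        spec = rb.FeatureTableSpec(
            n_cases=n,
            prevalence=0.25,
            blocks={
                "tumor_texture": BlockSpec(8, effect_size=0.8, within_correlation=0.3),
                "bpe_texture": BlockSpec(8, effect_size=1.5, within_correlation=0.3),
            },
            seed=seed,
        )
        return rb.generate_feature_table(spec)

    @staticmethod
    def _fast_config(**kw):
        defaults = dict(folds=5, repetitions=2, rank_keep=8, sffs_max_size=4,
                        inner_folds=3, seed=0)
        defaults.update(kw)
        return rb.CvConfig(**defaults)

    def test_deterministic_given_seed(self):
        table = self._small_table()
        cfg = self._fast_config()
        a = rb.run_nested_cv(table, cfg, scope="bpe")
        b = rb.run_nested_cv(table, cfg, scope="bpe")
        for m in a.metrics:
            assert np.array_equal(a.metrics[m], b.metrics[m])
        assert a.selections == b.selections

    def test_metrics_match_confusion_counts(self):
        table = self._small_table()
        res = rb.run_nested_cv(table, self._fast_config(), scope="bpe")
        tp, fp, tn, fn = res.confusion[0, 0]
        n = tp + fp + tn + fn
        assert res.metrics["accuracy"][0, 0] == pytest.approx((tp + tn) / n)
        assert res.metrics["sensitivity"][0, 0] == pytest.approx(tp / (tp + fn))
        assert res.metrics["specificity"][0, 0] == pytest.approx(tn / (tn + fp))

    def test_each_case_tested_once_per_repetition(self):
        table = self._small_table()
        res = rb.run_nested_cv(table, self._fast_config(), scope="bpe")
        for rep in range(res.config.repetitions):
            assert res.confusion[rep].sum() == table.n_cases

    def test_summary_ci_brackets_mean(self):
        table = self._small_table()
        res = rb.run_nested_cv(table, self._fast_config(repetitions=4), scope="bpe")
        for m, s in res.summary().items():
            assert s["ci"][0] <= s["mean"] + 1e-9
            assert s["mean"] <= s["ci"][1] + 1e-9

    def test_truncation_stability_with_pure_noise_features(self):
        # noise columns that cannot enter the chi2 top-k must not perturb the
        # fold-wise results
        base = self._small_table()
        res_a = rb.run_nested_cv(base, self._fast_config(rank_keep=6), scope="bpe")

        rng = np.random.default_rng(99)
        frame = base.frame.copy()
        blocks = dict(base.blocks)
        for i in range(4):
            # constant-plus-epsilon columns: chi2 statistic ~ 0
            name = f"parenchyma noise {i}"
            frame[name] = 1000.0 + 1e-9 * rng.standard_normal(len(frame))
            blocks[name] = "bpe_texture"
        bigger = rb.FeatureTable(frame, base.labels, base.case_ids, blocks)
        res_b = rb.run_nested_cv(bigger, self._fast_config(rank_keep=6), scope="bpe")
        assert np.array_equal(res_a.metrics["auc"], res_b.metrics["auc"])

    def test_impossible_stratification_errors(self):
        table = self._small_table(n=60)
        with pytest.raises(RadbpeError):
            rb.run_nested_cv(table, self._fast_config(folds=20), scope="bpe")

    def test_constant_columns_dropped_with_warning(self):
        base = self._small_table()
        frame = base.frame.copy()
        frame["parenchyma SER flat"] = 1.0
        blocks = dict(base.blocks, **{"parenchyma SER flat": "bpe_texture"})
        table = rb.FeatureTable(frame, base.labels, base.case_ids, blocks)
        with pytest.warns(UserWarning, match="constant"):
            rb.run_nested_cv(table, self._fast_config(), scope="bpe")


class TestWilcoxon:
    def test_identical_results_give_p_one(self):
        x = np.array([0.7, 0.8, 0.9, 0.6])
        assert rb.wilcoxon_signed_rank(x, x) == 1.0

    def test_ten_positive_differences_exact_p(self):
        x = np.arange(1.0, 11.0)
        y = np.zeros(10)
        assert rb.wilcoxon_signed_rank(x, y) == pytest.approx(2 / 1024)

    def test_exact_enumeration_matches_scipy(self, rng):
        for _ in range(20):
            d = rng.normal(size=12)
            d = d[d != 0]
            ours = exact_signed_rank_p(d)
            ref = stats.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.5, size=100) + 0.3
        ours = rb.wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x - y, method="approx", correction=False).pvalue
        assert ours == pytest.approx(ref)

    def test_compare_models_requires_identical_partitions(self):
        table = TestNestedCv._small_table()
        cfg_a = TestNestedCv._fast_config(seed=0)
        cfg_b = TestNestedCv._fast_config(seed=1)
        a = rb.run_nested_cv(table, cfg_a, scope="bpe")
        b = rb.run_nested_cv(table, cfg_b, scope="bpe")
        with pytest.raises(PairingError):
            rb.compare_models(a, b)


class TestSelectionFrequency:
    def test_frequencies_and_floor(self):
        table = TestNestedCv._small_table()
        res = rb.run_nested_cv(table, TestNestedCv._fast_config(), scope="bpe")
        freq = rb.selection_frequency(res)
        total = res.config.repetitions * res.config.folds
        manual = {}
        for rep in res.selections:
            for sel in rep:
                for name in sel:
                    manual[name] = manual.get(name, 0) + 1
        for name, pct in freq.items():
            assert pct == pytest.approx(100.0 * manual[name] / total)
        floor = rb.selection_frequency(res, floor=50.0)
        assert all(v >= 50.0 for v in floor.values)

    def test_dominant_feature_selected_in_most_folds(self):
        spec = rb.FeatureTableSpec(
            n_cases=80,
            prevalence=0.5,
            blocks={
                "bpe_texture": BlockSpec(1, effect_size=2.0),
                "tumor_texture": BlockSpec(7, effect_size=0.0),
            },
            seed=4,
        )
        table = rb.generate_feature_table(spec)
        res = rb.run_nested_cv(table, TestNestedCv._fast_config(repetitions=2),
                               scope="tumor+bpe")
        freq = rb.selection_frequency(res)
        assert freq.index[0] == "parenchyma rate in mean"
        assert freq.iloc[0] >= 90.0
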