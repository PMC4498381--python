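"""Decoding, VDM, module similarity, SVM generalization, model comparison."""

import itertools
import json

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import snm3f as sf


class TestLdaDecodeLoo:
    def test_far_separated_clusters_decode_perfectly(self, rng):
        a = rng.normal(0.0, 0.01, size=(10, 1, 2))
        b = rng.normal(5.0, 0.01, size=(10, 1, 2))
        coeffs = np.concatenate([a, b])
        labels = [1] * 10 + [2] * 10
        assert sf.lda_decode_loo(np.abs(coeffs), labels) == 1.0

    def test_one_dimensional_two_class_example(self):
        coeffs = np.array([0.0, 0.1, 10.0, 10.1]).reshape(-1, 1, 1)
        assert sf.lda_decode_loo(coeffs, [1, 1, 2, 2]) == 1.0

    def test_identical_class_distributions_decode_at_chance(self):
        rng = np.random.default_rng(42)
        S, K = 400, 4
        coeffs = rng.uniform(size=(S, 2, 2))
        labels = np.repeat(np.arange(K), S // K)
        dec = sf.lda_decode_loo(coeffs, labels)
        se = np.sqrt((1 / K) * (1 - 1 / K) / S)
        assert abs(dec - 1 / K) < 3 * se

    def test_matches_sklearn_lda_loo(self, rng):
        # independent cross-check on a well-conditioned instance
        coeffs = np.concatenate(
            [
                rng.normal([0, 0], 1.0, size=(15, 2)),
                rng.normal([2.5, 1.0], 1.0, size=(15, 2)),
                rng.normal([-1.0, 3.0], 1.0, size=(15, 2)),
            ]
        )
        labels = np.repeat([1, 2, 3], 15)
        mine = sf.lda_decode_loo(coeffs, labels)
        correct = 0
        for s in range(len(labels)):
            mask = np.arange(len(labels)) != s
            clf = LinearDiscriminantAnalysis(solver="lsqr")
            clf.fit(coeffs[mask], labels[mask])
            correct += clf.predict(coeffs[s : s + 1])[0] == labels[s]
        assert mine == pytest.approx(correct / len(labels))

    def test_relabeling_invariance(self, rng):
        coeffs = rng.uniform(size=(24, 2, 2))
        labels = np.repeat([1, 2, 3], 8)
        remapped = np.array([{1: 7, 2: 1, 3: 99}[x] for x in labels])
        assert sf.lda_decode_loo(coeffs, labels) == sf.lda_decode_loo(
            coeffs, remapped
        )

    def test_requires_two_trials_per_class(self):
        with pytest.raises(ValueError):
            sf.lda_decode_loo(np.ones((3, 1, 1)), [1, 2, 2])


class TestVdm:
    def test_worked_examples(self):
        assert round(sf.vdm(0.797, 0.8), 3) == 0.638
        assert round(sf.vdm(0.770, 1.0), 3) == 0.770

    def test_boundary_values(self):
        assert sf.vdm(1.0, 0.0) == 0.0
        assert sf.vdm(1.0, 0.3) == pytest.approx(0.3)

    def test_negative_vaf_clamps_to_zero(self):
        assert sf.vdm(-0.5, 0.9) == 0.0

    def test_always_in_unit_interval(self, rng):
        for _ in range(50):
            v = rng.uniform(-2, 1)
            d = rng.uniform(0, 1)
            assert 0.0 <= sf.vdm(v, d) <= 1.0

    def test_rejects_invalid_dec(self):
        with pytest.raises(ValueError):
            sf.vdm(0.5, 1.5)


class TestModuleSimilarity:
    def test_identical_sets_identity_pairing(self, rng):
        mods = rng.uniform(size=(3, 6))
        res = sf.module_similarity(mods, mods)
        assert res.pairs == [(0, 0), (1, 1), (2, 2)]
        assert np.allclose(res.correlations, 1.0)

    def test_affine_invariance(self, rng):
        mods = rng.uniform(size=(2, 8))
        res = sf.module_similarity(mods, 0.3 + 2.0 * mods)
        assert np.allclose(res.correlations, 1.0)

    def test_pairing_matches_exhaustive_search(self, rng):
        for _ in range(5):
            a = rng.uniform(size=(3, 7))
            b = rng.uniform(size=(3, 7))
            res = sf.module_similarity(a, b)
            R = np.corrcoef(np.vstack([a, b]))[:3, 3:]
            best = max(
                itertools.permutations(range(3)),
                key=lambda p: sum(R[i, p[i]] for i in range(3)),
            )
            assert [j for _, j in sorted(res.pairs)] == list(best)

    def test_zero_variance_module_reported_missing(self):
        a = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        b = np.array([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        with pytest.warns(RuntimeWarning):
            res = sf.module_similarity(a, b)
        assert any(r is None for r in res.correlations)


class TestSvmClassifyCv:
    @staticmethod
    def _fit_fn(ds):
        return sf.fit_snm3f(ds, 2, 2, sf.FitOptions(n_restarts=3, seed=1))

    def test_noise_free_separable_tasks_classify_perfectly(self):
        synth = sf.generate(sf.toy_spec(seed=5, noise_fraction=0.0))
        d = synth.dataset
        mean, sd = sf.svm_classify_cv(
            d, d.labels, 2, 2, self._fit_fn, n_train_per_task=5, n_splits=5, seed=0
        )
        assert mean == 1.0 and sd == 0.0

    def test_shuffled_labels_score_at_chance(self):
        synth = sf.generate(sf.toy_spec(seed=6, noise_fraction=0.0))
        d = synth.dataset
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(d.labels)
        mean, _ = sf.svm_classify_cv(
            d, shuffled, 2, 2, self._fit_fn, n_train_per_task=5, n_splits=5, seed=0
        )
        K = 4
        n_test = 40 - 5 * K
        se = np.sqrt((1 / K) * (1 - 1 / K) / (n_test * 5))
        assert abs(mean - 1 / K) < 3 * se + 0.15  # small-sample slack

    def test_same_seed_reproduces_scores(self, toy_noisy):
        d = toy_noisy.dataset
        args = (d, d.labels, 2, 2, self._fit_fn)
        out1 = sf.svm_classify_cv(*args, n_train_per_task=5, n_splits=3, seed=9)
        out2 = sf.svm_classify_cv(*args, n_train_per_task=5, n_splits=3, seed=9)
        assert out1 == out2

    def test_train_size_must_leave_test_data(self, toy_noisy):
        d = toy_noisy.dataset
        with pytest.raises(ValueError):
            sf.svm_classify_cv(
                d, d.labels, 2, 2, self._fit_fn, n_train_per_task=10
            )


class TestCompareModels:
    def test_identical_models_give_identical_reports(self, toy_noisy):
        d = toy_noisy.dataset
        m = sf.fit_snm3f(d, 2, 2, sf.FitOptions(n_restarts=2, seed=0)).model
        rep_a, rep_b = sf.compare_models(d, d.labels, m, m)
        assert rep_a.vaf == rep_b.vaf and rep_a.dec == rep_b.dec
        assert np.allclose(rep_a.similarity["spatial"]["correlations"], 1.0)
        assert np.allclose(rep_a.similarity["temporal"]["correlations"], 1.0)

    def test_discriminative_fit_has_smaller_j_ratio(self, toy_noisy):
        d = toy_noisy.dataset
        opts = sf.FitOptions(n_restarts=5, seed=0)
        m0 = sf.fit_snm3f(d, 2, 2, opts).model
        m1 = sf.fit_dsnm3f_mult(
            d, d.labels, 2, 2, sf.toy_tuned_params(), opts
        ).model
        rep0, rep1 = sf.compare_models(d, d.labels, m0, m1)
        assert rep1.j_ratio <= rep0.j_ratio

    def test_report_json_round_trip(self, toy_noisy):
        d = toy_noisy.dataset
        m = sf.fit_snm3f(d, 2, 2, sf.FitOptions(n_restarts=2, seed=0)).model
        rep, _ = sf.compare_models(d, d.labels, m, m)
        restored = sf.EvaluationReport.from_json(rep.to_json())
        assert restored.to_dict() == rep.to_dict()
        json.loads(rep.to_json())  # valid JSON
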