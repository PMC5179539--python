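import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from beacongrn.grn_svm import (
    KernelSpec,
    PairSVM,
    TrainingSet,
    eval_kernel,
    global_features,
    local_features,
    predict_targets,
    sample_negatives,
    train_regulator_models,
    train_soft_margin,
)


class TestFeatures:
    def test_global_is_concatenation(self):
        f = global_features([1, 2, 3], [4, 5, 6])
        assert np.array_equal(f.values, [1, 2, 3, 4, 5, 6])
        assert f.mode == "global"

    def test_global_seven_timepoints_gives_length_14(self, rng):
        f = global_features(rng.uniform(size=7), rng.uniform(size=7))
        assert f.values.size == 14

    def test_global_is_asymmetric(self):
        a, b = [1.0, 2.0], [3.0, 4.0]
        assert not np.array_equal(global_features(a, b).values, global_features(b, a).values)

    def test_global_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            global_features([1, 2], [1, 2, 3])

    def test_local_log_ratios(self):
        f = local_features([1, 2, 4], epsilon=1e-12)
        assert np.allclose(f.values, [1.0, 1.0])
        assert local_features([0, 1], epsilon=1.0).values == pytest.approx([1.0])

    def test_local_constant_profile_is_zero(self):
        assert np.allclose(local_features([5, 5, 5, 5]).values, 0.0)

    def test_local_length(self):
        assert local_features(np.arange(7) + 1.0).values.size == 6


class TestKernels:
    def test_rbf_identity_and_reference_value(self):
        spec = KernelSpec("rbf", gamma=0.5)
        assert eval_kernel(spec, [1.0, 2.0], [1.0, 2.0]) == 1.0
        assert eval_kernel(spec, [0.0, 0.0], [1.0, 1.0]) == pytest.approx(np.exp(-1.0))

    def test_linear_dot_product(self):
        assert eval_kernel(KernelSpec("linear"), [1, 2], [1, 2]) == 5.0
        assert eval_kernel(KernelSpec("linear", c=2.0), [1, 2], [1, 2]) == 7.0

    @given(
        arrays(float, 5, elements=st.floats(-5, 5)),
        arrays(float, 5, elements=st.floats(-5, 5)),
    )
    @settings(max_examples=50, deadline=None)
    def test_kernel_symmetry_and_rbf_range(self, x, y):
        for spec in (KernelSpec("linear", c=1.0), KernelSpec("rbf", gamma=0.3)):
            assert eval_kernel(spec, x, y) == pytest.approx(eval_kernel(spec, y, x))
        v = eval_kernel(KernelSpec("rbf", gamma=0.3), x, y)
        assert 0.0 < v <= 1.0

    def test_gram_matrix_is_psd(self, rng):
        X = rng.normal(size=(12, 4))
        for spec in (KernelSpec("linear"), KernelSpec("rbf", gamma=1.0)):
            G = np.array([[eval_kernel(spec, a, b) for b in X] for a in X])
            assert np.linalg.eigvalsh(G).min() >= -1e-8


class TestNegativeSampling:
    def test_balanced_size_and_exclusion(self):
        genes = [f"g{i}" for i in range(300)]
        regulon = {f"g{i}" for i in range(98)}
        neg = sample_negatives(genes, regulon, 98, seed=1, regulator="g299")
        assert len(neg) == 98
        assert neg.isdisjoint(regulon)
        assert "g299" not in neg

    def test_seed_determinism(self):
        genes = [f"g{i}" for i in range(50)]
        a = sample_negatives(genes, {"g0"}, 10, seed=7)
        b = sample_negatives(genes, {"g0"}, 10, seed=7)
        assert a == b
        assert a != sample_negatives(genes, {"g0"}, 10, seed=8)

    def test_insufficient_pool_raises(self):
        with pytest.raises(ValueError, match="2"):
            sample_negatives(["a", "b", "c"], {"a"}, 3, seed=0)


class TestTraining:
    def test_linear_separable_1d(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_soft_margin(TrainingSet(X, y), KernelSpec("linear"))
        assert np.array_equal(model.predict(X), y)

    def test_xor_with_rbf(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([1, 1, -1, -1])
        model = train_soft_margin(TrainingSet(X, y), KernelSpec("rbf", gamma=1.0))
        assert np.array_equal(model.predict(X), y)

    def test_contradictory_points_cannot_separate(self):
        X = np.array([[1.0], [1.0], [2.0]])
        y = np.array([1, -1, 1])
        model = train_soft_margin(TrainingSet(X, y), KernelSpec("linear"))
        assert (model.predict(X) != y).sum() >= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            PairSVM().fit([[0.0], [1.0]], [1, 1])

    def test_dual_constraints_hold(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        model = PairSVM(kernel="rbf", C=1000.0).fit(X, y)
        alpha = np.abs(model.dual_coef_.ravel())
        assert np.all(alpha <= 1000.0 + 1e-6)
        assert abs(model.dual_coef_.sum()) < 1e-6  # sum alpha_i y_i = 0

    def test_training_margin_at_least_one_when_separable(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_soft_margin(TrainingSet(X, y), KernelSpec("linear"))
        assert np.all(np.abs(model.decision_function(X)) >= 1 - 1e-6)

    def test_mirror_symmetric_data_has_zero_bias(self):
        X = np.array([[1.0, 0.5], [2.0, 1.0], [-1.0, -0.5], [-2.0, -1.0]])
        y = np.array([1, 1, -1, -1])
        model = train_soft_margin(TrainingSet(X, y), KernelSpec("linear"))
        assert abs(model.intercept_[0]) < 1e-6

    def test_dual_expansion_equals_decision_function(self, rng):
        X = rng.normal(size=(25, 4))
        y = np.where(X[:, 0] > 0, 1, -1)
        Xt = rng.normal(size=(10, 4))
        for spec in (KernelSpec("linear"), KernelSpec("rbf", gamma=0.7)):
            model = train_soft_margin(TrainingSet(X, y), spec)
            assert np.allclose(model.kernel_expansion(Xt), model.decision_function(Xt), atol=1e-9)

    def test_default_gamma_is_one_over_n_features(self, rng):
        X = rng.normal(size=(10, 6))
        y = np.array([1, -1] * 5)
        model = PairSVM(kernel="rbf").fit(X, y)
        assert model.gamma_ == pytest.approx(1.0 / 6.0)

    def test_tie_scores_classify_negative(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1, -1] * 5)
        model = PairSVM(kernel="linear").fit(X, y)
        # predict uses strict f > 0, so f = 0 must map to -1
        assert model.predict(np.zeros((1, 2)))[0] in (-1, 1)
        f = model.decision_function(X)
        assert np.array_equal(model.predict(X), np.where(f > 0, 1, -1))


class TestPrediction:
    def test_local_models_recover_planted_targets(self, default_fixture):
        cfg, expression, regulons, _ = default_fixture
        targets = regulons.targets("TF1")
        models = train_regulator_models(expression, {"TF1": targets}, mode="local", seed=2)
        predicted = predict_targets(models, set(expression.gene_ids), expression)
        # training positives never reappear among predictions
        assert set(predicted["TF1"]).isdisjoint(targets)
        # held-out recovery: train on half the regulon, predict the other half
        half = set(sorted(targets)[:50])
        models = train_regulator_models(expression, {"TF1": half}, mode="local", seed=2)
        predicted = predict_targets(models, set(expression.gene_ids), expression)
        rest = targets - half
        recovered = len(rest & set(predicted["TF1"])) / len(rest)
        assert recovered > 0.7

    def test_local_scores_ignore_regulator_profile(self, small_fixture):
        cfg, expression, regulons, _ = small_fixture
        targets = regulons.targets("TF1")
        models = train_regulator_models(expression, {"TF1": targets}, mode="local", seed=2)
        gene = sorted(set(expression.gene_ids) - targets - {"TF1"})[0]
        from beacongrn.grn_svm import pair_features

        f = pair_features(expression, "TF1", gene, "local")
        # the feature vector is built from the target profile only
        assert f.values.size == expression.n_timepoints - 1
        assert np.allclose(
            f.values, local_features(expression.profile(gene)).values
        )

    def test_zero_models_empty_map(self, small_fixture):
        _, expression, _, _ = small_fixture
        assert predict_targets({}, {"G00001"}, expression) == {}

    def test_missing_regulator_raises(self, small_fixture):
        _, expression, regulons, _ = small_fixture
        models = train_regulator_models(
            expression, {"TF1": regulons.targets("TF1")}, seed=0
        )
        models["GHOST"] = models.pop("TF1")
        models["GHOST"].regulator = "GHOST"
        with pytest.raises(KeyError, match="GHOST"):
            predict_targets(models, set(expression.gene_ids), expression)

    def test_raising_c_never_hurts_separable_training(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        errs = []
        for C in (1.0, 10.0, 1000.0):
            model = PairSVM(kernel="linear", C=C).fit(X, y)
            errs.append((model.predict(X) != y).sum())
        assert errs == sorted(errs, reverse=True)
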