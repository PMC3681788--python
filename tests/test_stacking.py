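"""Stacked generalization: kernel normalization/mixing, level-1 dataset
provenance, the three level-1 learners and end-to-end stacking."""

from types import SimpleNamespace

import numpy as np
import pytest

from ddikernels import stacking
from ddikernels.evaluation import confusion, prf
from ddikernels.stacking import (
    Level1Dataset,
    LookupScoreLearner,
    audit_provenance,
    build_level1_dataset,
    choose_threshold_max_f,
    combine_kernels,
    normalize_kernel,
    predict_stacked,
    ranksvm_pairs,
    train_mlr,
    train_ranksvm,
    train_stacked,
    train_svm_level1,
)


def random_psd(rng, n=6):
    B = rng.random((n, n)) - 0.3
    return B @ B.T + 0.5 * np.eye(n)


def simulated_instances(rng, n=200, prevalence=0.1, separation=1.0,
                        noise_sd=0.55):
    """Instances carrying an informative and a pure-noise score column."""
    y = (rng.random(n) < prevalence).astype(int)
    if y.sum() == 0:
        y[0] = 1
    info = y * separation + rng.normal(0, noise_sd, n)
    noise = rng.normal(0, 1.0, n)
    insts = [SimpleNamespace(pair_id=f"i{k}",
                             label="positive" if y[k] else "negative")
             for k in range(n)]
    learners = [LookupScoreLearner("info", {f"i{k}": info[k] for k in range(n)}),
                LookupScoreLearner("noise", {f"i{k}": noise[k] for k in range(n)})]
    return insts, learners, y


class TestNormalize:
    def test_unit_diagonal(self):
        K = random_psd(np.random.default_rng(0))
        assert np.allclose(np.diag(normalize_kernel(K)), 1.0)

    def test_scale_invariance(self):
        K = random_psd(np.random.default_rng(1))
        assert np.allclose(normalize_kernel(K), normalize_kernel(7 * K))

    def test_entrywise_formula(self):
        K = random_psd(np.random.default_rng(2))
        Kn = normalize_kernel(K)
        for i in range(K.shape[0]):
            for j in range(K.shape[0]):
                assert Kn[i, j] == pytest.approx(
                    K[i, j] / np.sqrt(K[i, i] * K[j, j]))

    def test_idempotent(self):
        K = random_psd(np.random.default_rng(3))
        Kn = normalize_kernel(K)
        assert np.allclose(normalize_kernel(Kn), Kn)

    def test_zero_diagonal_rejected(self):
        K = np.array([[0.0, 0.1], [0.1, 1.0]])
        with pytest.raises(ValueError, match="instance 0"):
            normalize_kernel(K)


class TestCombine:
    def test_single_weight_returns_first_kernel(self):
        rng = np.random.default_rng(4)
        Ks = [random_psd(rng) for _ in range(3)]
        assert np.allclose(combine_kernels(Ks, [1, 0, 0]), Ks[0])

    def test_equal_weights_give_entrywise_mean(self):
        rng = np.random.default_rng(5)
        Ks = [random_psd(rng) for _ in range(3)]
        assert np.allclose(combine_kernels(Ks, [1, 1, 1]),
                           sum(Ks) / 3)

    def test_convex_combination_of_psd_stays_psd(self):
        rng = np.random.default_rng(6)
        Ks = [random_psd(rng) for _ in range(3)]
        K = combine_kernels(Ks, [0.45, 0.4, 0.15])
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            combine_kernels([np.eye(2)], [0.0])


class TestLevel1Dataset:
    def test_shape_and_determinism(self):
        rng = np.random.default_rng(7)
        insts, learners, _ = simulated_instances(rng, n=30)
        ds1 = build_level1_dataset(insts, learners, J=5, seed=3)
        ds2 = build_level1_dataset(insts, learners, J=5, seed=3)
        assert ds1.X.shape == (30, 2)
        assert np.array_equal(ds1.X, ds2.X)
        assert np.array_equal(ds1.fold_of, ds2.fold_of)

    @pytest.mark.parametrize("J", [2, 5, 10])
    def test_no_leakage_for_any_fold_count(self, J):
        rng = np.random.default_rng(8)
        insts, learners, _ = simulated_instances(rng, n=60)
        ds = build_level1_dataset(insts, learners, J=J, seed=1)
        assert audit_provenance(ds)
        # every instance scored exactly once, folds partition the data
        assert (ds.fold_of >= 0).all()
        all_train = set().union(*ds.fold_train_ids.values())
        assert all_train == set(ds.instance_ids)

    def test_rejects_single_fold(self):
        with pytest.raises(ValueError):
            build_level1_dataset([], [], J=1)


def _dataset(X, y):
    n = len(y)
    return Level1Dataset(X=np.asarray(X, float), y=np.asarray(y),
                         instance_ids=[f"i{k}" for k in range(n)],
                         learner_names=["a", "b"][: X.shape[1]],
                         fold_of=np.zeros(n, int))


class TestMlr:
    def test_perfectly_separating_score(self):
        X = np.array([[1.0], [0.9], [0.0], [0.1]])
        y = np.array([1, 1, 0, 0])
        model = train_mlr(_dataset(X, y))
        assert model.predict(X) == ["positive", "positive",
                                    "negative", "negative"]

    def test_uninformative_scores_give_near_zero_weights(self):
        # symmetric scores carry no signal: closed-form least squares -> w=0
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        y = np.array([1, 1, 0, 0])
        model = train_mlr(_dataset(X, y))
        assert abs(model.weights[0]) < 1e-6

    def test_duplicated_columns_handled_by_ridge(self, caplog):
        X = np.array([[1.0, 1.0], [0.9, 0.9], [0.0, 0.0], [0.1, 0.1]])
        y = np.array([1, 1, 0, 0])
        model = train_mlr(_dataset(X, y))
        assert np.isfinite(model.weights).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_mlr(_dataset(np.ones((3, 1)), np.ones(3, int)))


class TestRankSvmPairs:
    def test_m_times_n_difference_vectors(self):
        X = np.arange(10).reshape(5, 2).astype(float)
        ds = _dataset(X, np.array([1, 1, 0, 0, 0]))
        diffs, labels = ranksvm_pairs(ds)
        assert diffs.shape == (6, 2)  # M=2, N=3
        assert (labels == 1).all()

    def test_zero_difference_retained(self):
        X = np.array([[0.5], [0.5]])
        ds = _dataset(X, np.array([1, 0]))
        diffs, labels = ranksvm_pairs(ds)
        assert diffs.shape == (1, 1) and diffs[0, 0] == 0.0
        assert labels[0] == 1

    def test_cap_subsamples_reproducibly(self):
        rng = np.random.default_rng(11)
        X = rng.random((20, 2))
        y = np.array([1] * 10 + [0] * 10)
        ds = _dataset(X, y)
        d1, _ = ranksvm_pairs(ds, cap=10, seed=5)
        d2, _ = ranksvm_pairs(ds, cap=10, seed=5)
        assert d1.shape == (10, 2)
        assert np.array_equal(d1, d2)

    def test_mirrored_doubles_pairs(self):
        X = np.arange(10).reshape(5, 2).astype(float)
        ds = _dataset(X, np.array([1, 1, 0, 0, 0]))
        diffs, labels = ranksvm_pairs(ds, mirrored=True)
        assert diffs.shape == (12, 2)
        assert set(labels) == {1.0, -1.0}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ranksvm_pairs(_dataset(np.ones((3, 1)), np.zeros(3, int)))


def test_threshold_maximizes_f():
    scores = np.array([0.9, 0.8, 0.2, 0.1, 0.15])
    y = np.array([1, 1, 0, 0, 0])
    t = choose_threshold_max_f(scores, y)
    pred = ["positive" if s >= t else "negative" for s in scores]
    gold = ["positive" if v else "negative" for v in y]
    _, _, f = prf(confusion(gold, pred))
    assert f == 1.0


class TestWeightRecovery:
    """All three level-1 learners should weight an informative base scorer
    above a pure-noise one."""

    @pytest.mark.parametrize("trainer", [
        train_mlr, train_svm_level1, lambda ds: train_ranksvm(ds, seed=0)])
    def test_informative_base_outweighs_noise(self, trainer):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            insts, learners, _ = simulated_instances(rng, n=300)
            ds = build_level1_dataset(insts, learners, J=5, seed=seed)
            model = trainer(ds)
            if abs(model.weights[0]) > abs(model.weights[1]):
                hits += 1
        assert hits >= 4


class TestStackedEndToEnd:
    def test_perfectly_informative_base_gives_f_one(self):
        rng = np.random.default_rng(21)
        y = np.array([1] * 10 + [0] * 90)
        rng.shuffle(y)
        insts = [SimpleNamespace(pair_id=f"i{k}",
                                 label="positive" if y[k] else "negative")
                 for k in range(100)]
        learners = [
            LookupScoreLearner("oracle", {f"i{k}": float(y[k]) for k in range(100)}),
            LookupScoreLearner("noise",
                               {f"i{k}": rng.normal() for k in range(100)}),
        ]
        for kind in ("mlr", "svm", "ranksvm"):
            model = train_stacked(insts, learner_kind=kind, J=5, seed=2,
                                  learners=learners)
            labels, _ = predict_stacked(model, insts)
            gold = [i.label for i in insts]
            _, _, f = prf(confusion(gold, labels))
            assert f == 1.0, kind

    def test_prediction_order_invariance_and_determinism(self):
        rng = np.random.default_rng(22)
        insts, learners, _ = simulated_instances(rng, n=80)
        model = train_stacked(insts, learner_kind="ranksvm", J=4, seed=9,
                              learners=learners)
        labels1, scores1 = predict_stacked(model, insts)
        perm = rng.permutation(len(insts))
        labels2, scores2 = predict_stacked(model, [insts[i] for i in perm])
        for k, i in enumerate(perm):
            assert labels2[k] == labels1[i]
            assert scores2[k] == pytest.approx(scores1[i])

    def test_untrained_model_rejected(self):
        model = stacking.StackedModel(level0=[], level1=None,
                                      learner_kind="mlr", seed=0)
        with pytest.raises(RuntimeError):
            predict_stacked(model, [])

    def test_kernel_learners_on_fixture_corpus(self, small_instances,
                                               small_corpus):
        """The real three-kernel stack separates the cue-driven fixture data."""
        from ddikernels.feature_kernel import DrugBankSnapshot

        _, snapshot = small_corpus
        learners = stacking.default_learners(
            snapshot=DrugBankSnapshot(snapshot))
        model = train_stacked(small_instances, learner_kind="ranksvm", J=3,
                              seed=1, learners=learners)
        labels, scores = predict_stacked(model, small_instances)
        gold = [i.label for i in small_instances]
        _, _, f = prf(confusion(gold, labels))
        assert f >= 0.9

    def test_model_roundtrip(self, tmp_path):
        rng = np.random.default_rng(23)
        insts, learners, _ = simulated_instances(rng, n=60)
        model = train_stacked(insts, learner_kind="mlr", J=3, seed=4,
                              learners=learners)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = stacking.StackedModel.load(path)
        l1, s1 = predict_stacked(model, insts)
        l2, s2 = predict_stacked(loaded, insts)
        assert l1 == l2
        assert np.allclose(s1, s2)
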