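"""Stacked generalization over the three kernel classifiers.

Level-0 learners score candidate instances (signed decision values of a
linear SVM on sparse features, or of SVMs over precomputed graph/tree kernel
Gram matrices).  A J-fold cross-validation produces a level-1 dataset in
which every row was scored by models whose training fold excluded that
instance; a level-1 generalizer (multi-response linear regression, a linear
SVM, or a Ranking SVM on positive-minus-negative score differences) then
learns how to weight the level-0 scores.  The final model re-fits the
level-0 learners on all data.

Fixed-weight kernel mixing (cosine-normalize each Gram, then form a convex
combination) is also provided for comparison with learned stacking.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from . import feature_kernel as fk
from . import graph_kernel as gk
from . import tree_kernel as tk
from .evaluation import confusion, prf
from .types import NEGATIVE, POSITIVE

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kernel matrix utilities

def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Cosine normalization K(x,y)/sqrt(K(x,x) K(y,y)); unit diagonal."""
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if (d <= 0).any():
        bad = int(np.argmin(d))
        raise ValueError(f"cannot normalize: instance {bad} has "
                         f"self-kernel {d[bad]:g} <= 0")
    s = 1.0 / np.sqrt(d)
    Kn = K * np.outer(s, s)
    np.fill_diagonal(Kn, 1.0)
    return Kn


def combine_kernels(kernels, weights) -> np.ndarray:
    """Weighted sum of equally shaped kernel matrices; weights renormalized to 1."""
    weights = np.asarray(weights, dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("weights must be non-negative and not all zero")
    weights = weights / weights.sum()
    out = np.zeros_like(np.asarray(kernels[0], dtype=float))
    for w, K in zip(weights, kernels, strict=True):
        out += w * np.asarray(K, dtype=float)
    return out


# ---------------------------------------------------------------------------
# level-0 learners

class FeatureKernelLearner:
    """Linear SVM over the sparse feature-based-kernel vectors (c = 0.006)."""

    name = "feature"

    def __init__(self, c: float = 0.006, config: fk.FeatureConfig = None,
                 lexicons: fk.Lexicons = None,
                 snapshot: fk.DrugBankSnapshot = None):
        self.c = c
        self.config = config or fk.FeatureConfig()
        self.lexicons = lexicons or fk.Lexicons()
        self.snapshot = snapshot
        self._vec = None
        self._clf = None

    def _vectors(self, instances):
        return [fk.assemble_vector(i, self.config, self.lexicons, self.snapshot)
                for i in instances]

    @staticmethod
    def _as_int32_csr(X):
        X = X.tocsr()
        X.indices = X.indices.astype(np.int32)
        X.indptr = X.indptr.astype(np.int32)
        return X

    def fit(self, instances):
        self._vec = DictVectorizer(sparse=True)
        X = self._as_int32_csr(self._vec.fit_transform(self._vectors(instances)))
        y = [1 if i.label == POSITIVE else 0 for i in instances]
        self._clf = LinearSVC(C=self.c, max_iter=20000)
        self._clf.fit(X, y)
        return self

    def decision_scores(self, instances) -> np.ndarray:
        X = self._as_int32_csr(self._vec.transform(self._vectors(instances)))
        return self._clf.decision_function(X)


class _PrecomputedKernelLearner:
    """SVM over a precomputed, cosine-normalized Gram matrix."""

    def __init__(self, c: float = 1.0):
        self.c = c
        self._train = None
        self._self_k = None
        self._clf = None

    # subclasses supply pairwise kernel evaluation
    def _pair_kernel(self, a, b) -> float:  # pragma: no cover - abstract
        raise NotImplementedError

    def _gram(self, A, B, self_a, self_b):
        K = np.empty((len(A), len(B)))
        for i, x in enumerate(A):
            for j, y in enumerate(B):
                K[i, j] = self._pair_kernel(x, y)
        denom = np.sqrt(np.outer(self_a, self_b))
        denom[denom == 0] = 1.0
        return K / denom

    def fit(self, instances):
        self._train = list(instances)
        self._self_k = np.array(
            [max(self._pair_kernel(x, x), 1e-12) for x in self._train])
        K = self._gram(self._train, self._train, self._self_k, self._self_k)
        y = [1 if i.label == POSITIVE else 0 for i in instances]
        self._clf = SVC(kernel="precomputed", C=self.c)
        self._clf.fit(K, y)
        return self

    def decision_scores(self, instances) -> np.ndarray:
        self_t = np.array([max(self._pair_kernel(x, x), 1e-12)
                           for x in instances])
        K = self._gram(instances, self._train, self_t, self._self_k)
        return self._clf.decision_function(K)


class GraphKernelLearner(_PrecomputedKernelLearner):
    """All-paths graph kernel SVM; graphs and Neumann matrices are cached."""

    name = "graph"

    def __init__(self, c: float = 1.0, config: gk.GraphConfig = None):
        super().__init__(c)
        self.config = config or gk.GraphConfig()
        self._cache = {}

    def _graph(self, inst):
        key = id(inst)
        if key not in self._cache:
            g = gk.build_graph_representation(inst, self.config)
            self._cache[key] = (g, gk.neumann_graph_matrix(g.adjacency))
        return self._cache[key]

    def _pair_kernel(self, a, b):
        ga, Ga = self._graph(a)
        gb, Gb = self._graph(b)
        return gk.graph_kernel_value(ga, gb, Ga, Gb)


class TreeKernelLearner(_PrecomputedKernelLearner):
    """Convolution tree kernel SVM over SPT + dependency-path trees."""

    name = "tree"

    def __init__(self, c: float = 1.0, config: tk.TreeKernelConfig = None):
        super().__init__(c)
        self.config = config or tk.TreeKernelConfig()
        self._cache = {}

    def _trees(self, inst):
        key = id(inst)
        if key not in self._cache:
            self._cache[key] = tk.instance_trees(inst, self.config)
        return self._cache[key]

    def _pair_kernel(self, a, b):
        spt1, dpt1 = self._trees(a)
        spt2, dpt2 = self._trees(b)
        score = 0.0
        if spt1 is not None and spt2 is not None:
            score += tk.normalized_cd_kernel(spt1, spt2, self.config.lambda_decay)
        if dpt1 is not None and dpt2 is not None:
            score += tk.normalized_cd_kernel(dpt1, dpt2, self.config.lambda_decay)
        return score


class LookupScoreLearner:
    """Level-0 stand-in whose scores are a fixed per-instance lookup.

    Useful for controlled experiments on the stacking layer itself (e.g. one
    informative and one pure-noise scorer); training is a no-op, so the
    cross-validation provenance contract still holds trivially.
    """

    def __init__(self, name: str, scores_by_id: dict):
        self.name = name
        self.scores_by_id = dict(scores_by_id)

    def fit(self, instances):
        return self

    def decision_scores(self, instances) -> np.ndarray:
        return np.array([self.scores_by_id[i.pair_id] for i in instances])


def default_learners(lexicons=None, snapshot=None,
                     feature_c=0.006, graph_c=1.0, tree_c=1.0):
    return [
        FeatureKernelLearner(c=feature_c, lexicons=lexicons, snapshot=snapshot),
        GraphKernelLearner(c=graph_c),
        TreeKernelLearner(c=tree_c),
    ]


# ---------------------------------------------------------------------------
# level-1 dataset

@dataclass
class Level1Dataset:
    """Cross-validated level-0 scores: rows z_n, labels y_n, fold provenance."""

    X: np.ndarray                 # (N, T) level-0 scores
    y: np.ndarray                 # (N,) 1 = positive
    instance_ids: list
    learner_names: list
    fold_of: np.ndarray           # (N,) fold index that scored each row
    fold_train_ids: dict = field(default_factory=dict)  # fold -> set of ids


def build_level1_dataset(instances, learners, J: int = 10,
                         seed: int = 0) -> Level1Dataset:
    """J-fold stratified cross-validation of the level-0 learners.

    Every instance is scored exactly once, by models trained on the J-1
    folds that exclude it; the provenance (which ids trained the scoring
    models) is recorded for auditing.
    """
    if J < 2:
        raise ValueError("J must be >= 2")
    instances = list(instances)
    y = np.array([1 if i.label == POSITIVE else 0 for i in instances])
    ids = [i.pair_id for i in instances]
    N, T = len(instances), len(learners)
    X = np.zeros((N, T))
    fold_of = np.full(N, -1)
    fold_train_ids = {}
    skf = StratifiedKFold(n_splits=J, shuffle=True, random_state=seed)
    for j, (train_idx, test_idx) in enumerate(skf.split(np.zeros(N), y)):
        train = [instances[i] for i in train_idx]
        test = [instances[i] for i in test_idx]
        if len({inst.label for inst in train}) < 2:
            log.warning("fold %d: training part has a single class", j)
        fold_train_ids[j] = {instances[i].pair_id for i in train_idx}
        for t, learner in enumerate(learners):
            model = copy.deepcopy(learner)
            model.fit(train)
            X[test_idx, t] = model.decision_scores(test)
        fold_of[test_idx] = j
    return Level1Dataset(X=X, y=y, instance_ids=ids,
                         learner_names=[l.name for l in learners],
                         fold_of=fold_of, fold_train_ids=fold_train_ids)


def audit_provenance(ds: Level1Dataset) -> bool:
    """True iff no level-1 row was scored by a model trained on its instance."""
    for i, pid in enumerate(ds.instance_ids):
        j = int(ds.fold_of[i])
        if j < 0 or pid in ds.fold_train_ids.get(j, set()):
            return False
    return True


# ---------------------------------------------------------------------------
# level-1 learners

@dataclass
class LinearModel:
    """Level-1 hypothesis: weights over the level-0 scores plus bias/threshold."""

    weights: np.ndarray
    bias: float
    threshold: float
    kind: str

    def scores(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X):
        return [POSITIVE if s >= self.threshold else NEGATIVE
                for s in self.scores(X)]


def train_mlr(ds: Level1Dataset) -> LinearModel:
    """Multi-response linear regression level-1 learner.

    One least-squares regression per class on 0/1 responses; with two classes
    this reduces to a single response thresholded at 0.5.  A rank-deficient
    design falls back to a tiny ridge penalty.
    """
    if len(set(ds.y.tolist())) < 2:
        raise ValueError("MLR needs both classes present")
    D = np.column_stack([ds.X, np.ones(len(ds.y))])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        eps = 1e-8
        log.warning("rank-deficient level-1 design; ridge fallback eps=%g", eps)
        coef = np.linalg.solve(D.T @ D + eps * np.eye(D.shape[1]), D.T @ ds.y)
    else:
        coef, *_ = np.linalg.lstsq(D, ds.y.astype(float), rcond=None)
    return LinearModel(weights=coef[:-1], bias=float(coef[-1]),
                       threshold=0.5, kind="mlr")


def train_svm_level1(ds: Level1Dataset, c: float = 0.1) -> LinearModel:
    """Linear SVM level-1 learner (c = 0.1); threshold at decision value 0."""
    clf = LinearSVC(C=c, max_iter=20000)
    clf.fit(ds.X, ds.y)
    return LinearModel(weights=clf.coef_.ravel().copy(),
                       bias=float(clf.intercept_[0]), threshold=0.0,
                       kind="svm")


def ranksvm_pairs(ds: Level1Dataset, mirrored: bool = False,
                  cap: int = None, seed: int = 0):
    """Positive-minus-negative score-difference vectors for the Ranking SVM.

    With M positives and N negatives there are M*N one-sided (+1) pairs
    (mirrored adds the negated copies).  When M*N exceeds ``cap`` a seeded
    subsample of exactly ``cap`` pairs is drawn.
    """
    pos = ds.X[ds.y == 1]
    neg = ds.X[ds.y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("Ranking SVM needs both classes present")
    m, n = len(pos), len(neg)
    idx = np.arange(m * n)
    if cap is not None and len(idx) > cap:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=cap, replace=False)
        idx.sort()
    diffs = pos[idx // n] - neg[idx % n]
    labels = np.ones(len(diffs))
    if mirrored:
        diffs = np.vstack([diffs, -diffs])
        labels = np.concatenate([labels, -np.ones(len(idx))])
    return diffs, labels


def choose_threshold_max_f(scores, y) -> float:
    """Decision threshold maximizing F on (scores, 0/1 labels)."""
    order = np.argsort(scores)
    uniq = np.unique(np.asarray(scores)[order])
    best_t, best_f = uniq[0], -1.0
    gold = [POSITIVE if v else NEGATIVE for v in y]
    for t in uniq:
        pred = [POSITIVE if s >= t else NEGATIVE for s in scores]
        _, _, f = prf(confusion(gold, pred))
        if f > best_f:
            best_f, best_t = f, t
    return float(best_t)


def train_ranksvm(ds: Level1Dataset, c: float = 10.0, cap: int = 100000,
                  seed: int = 0) -> LinearModel:
    """Ranking SVM level-1 learner (c = 10).

    The ranking weight vector is fit on the pairwise difference vectors
    (solved as the equivalent mirrored +/-1 problem with no intercept); a
    ranking score alone assigns no class, so the classification threshold is
    chosen to maximize F on the level-1 training scores.
    """
    diffs, labels = ranksvm_pairs(ds, mirrored=True, cap=cap, seed=seed)
    clf = LinearSVC(C=c, fit_intercept=False, max_iter=20000)
    clf.fit(diffs, labels)
    w = clf.coef_.ravel().copy()
    threshold = choose_threshold_max_f(ds.X @ w, ds.y)
    return LinearModel(weights=w, bias=0.0, threshold=threshold,
                       kind="ranksvm")


_LEVEL1_TRAINERS = {
    "mlr": lambda ds, seed: train_mlr(ds),
    "svm": lambda ds, seed: train_svm_level1(ds),
    "ranksvm": lambda ds, seed: train_ranksvm(ds, seed=seed),
}


# ---------------------------------------------------------------------------
# the stacked model

@dataclass
class StackedModel:
    """Final level-0 models (trained on all data) plus the level-1 hypothesis."""

    level0: list
    level1: LinearModel
    learner_kind: str
    seed: int

    def save(self, path):
        joblib.dump({"version": 1, "model": self}, path)

    @classmethod
    def load(cls, path):
        payload = joblib.load(path)
        if payload.get("version") != 1:
            raise ValueError("unsupported model archive version")
        return payload["model"]


def train_stacked(instances, learner_kind: str = "ranksvm", J: int = 10,
                  seed: int = 0, learners=None) -> StackedModel:
    """Full stacked-generalization training.

    Level-1 features come from J-fold cross-validated level-0 scores; the
    level-1 learner is one of {mlr, svm, ranksvm}; the returned level-0
    models are re-fit on all the data.
    """
    if learner_kind not in _LEVEL1_TRAINERS:
        raise ValueError(f"unknown level-1 learner {learner_kind!r}")
    learners = learners if learners is not None else default_learners()
    ds = build_level1_dataset(instances, learners, J=J, seed=seed)
    level1 = _LEVEL1_TRAINERS[learner_kind](ds, seed)
    final = []
    for learner in learners:
        model = copy.deepcopy(learner)
        model.fit(list(instances))
        final.append(model)
    return StackedModel(level0=final, level1=level1,
                        learner_kind=learner_kind, seed=seed)


def level0_scores(model: StackedModel, instances) -> np.ndarray:
    return np.column_stack([l.decision_scores(list(instances))
                            for l in model.level0])


def predict_stacked(model: StackedModel, instances):
    """(labels, level-1 scores) for new instances."""
    if model.level1 is None or not model.level0:
        raise RuntimeError("model is not trained")
    X = level0_scores(model, instances)
    scores = model.level1.scores(X)
    labels = model.level1.predict(X)
    return labels, scores
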