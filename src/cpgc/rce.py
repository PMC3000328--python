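"""Recursive cluster elimination SVM (RCE-SVM).

The classifier splits the cohort into a training and a held-out test half,
then iterates three steps on the training half only:

1. **cluster** — K-means over the features (each feature is a point whose
   coordinates are its standardized values across training subjects);
2. **score** — each cluster is scored by the mean held-out-fold accuracy of a
   linear SVM trained on that cluster's features, over ``n_reps`` random
   stratified ``n_folds`` partitions of the training subjects;
3. **eliminate** — the lowest-scoring 10% of clusters (at least one) are
   dropped, the surviving features merged, and the cluster count reduced by
   10% for the next round.

After every scoring pass the *evolving test accuracy* is recorded: one linear
SVM trained on all surviving training features and evaluated on the untouched
test half. The procedure ends at one cluster; the best iteration is the one
with maximum test accuracy (ties resolved toward fewer features) and its
surviving features, ranked by their cluster scores, form the final ranking.

All statistics that shape the feature selection (standardization, clustering,
cluster scores) are functions of the training half alone.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from ._svm import MAX_EPOCHS, TOL, score_clusters_kernel, train_eval
from .features import FeatureTable

logger = logging.getLogger(__name__)


@dataclass
class RCEConfig:
    """Settings of the RCE-SVM procedure (defaults reproduce the reference
    protocol: 10 folds, 500 repetitions, bottom 10% eliminated)."""

    n_folds: int = 10
    n_reps: int = 500
    elim_frac: float = 0.10
    svm_cost: float = 1.0
    seed: int = 0
    recluster_each_rep: bool = False

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (0.0 < self.elim_frac < 1.0):
            raise ValueError("elim_frac must lie in (0, 1)")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass
class RCEIteration:
    n_clusters: int
    surviving_feature_names: list[str]
    cluster_scores: np.ndarray
    feature_scores: np.ndarray  # each feature's cluster score
    evolving_test_accuracy: float


@dataclass
class RCEResult:
    """Full audit trail of one RCE-SVM run."""

    iterations: list[RCEIteration]
    best_iteration: int
    final_ranking: list[tuple[str, float]]
    config: RCEConfig
    train_subject_ids: list[str] = field(default_factory=list)
    test_subject_ids: list[str] = field(default_factory=list)

    @property
    def best_accuracy(self) -> float:
        return self.iterations[self.best_iteration].evolving_test_accuracy

    @property
    def baseline_accuracy(self) -> float:
        """Test accuracy of the SVM on all features (first iteration), i.e.
        the no-elimination baseline."""
        return self.iterations[0].evolving_test_accuracy

    def accuracy_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.iterations)),
                "n_clusters": [it.n_clusters for it in self.iterations],
                "n_features": [len(it.surviving_feature_names) for it in self.iterations],
                "test_accuracy": [it.evolving_test_accuracy for it in self.iterations],
            }
        )

    def ranking_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [f for f, _ in self.final_ranking],
                "score": [s for _, s in self.final_ranking],
                "rank": np.arange(1, len(self.final_ranking) + 1),
            }
        )

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "best_iteration": self.best_iteration,
            "best_accuracy": self.best_accuracy,
            "baseline_accuracy": self.baseline_accuracy,
            "final_ranking": [
                {"feature": f, "score": s, "rank": i + 1}
                for i, (f, s) in enumerate(self.final_ranking)
            ],
            "train_subject_ids": self.train_subject_ids,
            "test_subject_ids": self.test_subject_ids,
            "iterations": [
                {
                    "n_clusters": it.n_clusters,
                    "n_features": len(it.surviving_feature_names),
                    "surviving_feature_names": it.surviving_feature_names,
                    "cluster_scores": it.cluster_scores.tolist(),
                    "evolving_test_accuracy": it.evolving_test_accuracy,
                }
                for it in self.iterations
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# -- building blocks ----------------------------------------------------------


def split_cohort(table: FeatureTable, seed: int) -> tuple[FeatureTable, FeatureTable]:
    """Deterministic stratified half-split (per-class counts differ by <= 1)."""
    rng = np.random.default_rng(seed)
    train_rows, test_rows = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(table.labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls} has {idx.size} subject(s); need >= 2")
        idx = rng.permutation(idx)
        half = int(math.ceil(idx.size / 2))
        train_rows.append(idx[:half])
        test_rows.append(idx[half:])
    train = np.sort(np.concatenate(train_rows))
    test = np.sort(np.concatenate(test_rows))
    return table.subset(rows=train), table.subset(rows=test)


def _standardize_train(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (values - mu) / sd, mu, sd


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (deterministic ids)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _kmeans_labels(profiles: np.ndarray, n: int, seed: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        km = KMeans(n_clusters=n, n_init=10, random_state=seed).fit(profiles)
    return km.labels_


def initial_cluster_count(train: FeatureTable, seed: int) -> int:
    """Largest n <= n_features for which K-means leaves no cluster empty.

    Starts at the number of features and decrements until all clusters are
    occupied (duplicated feature profiles force a smaller n).
    """
    f = train.n_features
    if f == 1:
        return 1
    profiles, _, _ = _standardize_train(train.values)
    profiles = profiles.T  # features as points
    n = f
    while n > 1:
        labels = _kmeans_labels(profiles, n, seed)
        if np.unique(labels).size == n:
            return n
        n -= 1
    return 1


def cluster_features(train: FeatureTable, n: int, seed: int) -> np.ndarray:
    """K-means assignment (feature -> cluster id) on standardized profiles.

    Cluster ids are canonicalized by first appearance. Retries with fresh
    seeds if a cluster comes back empty, then falls back to a smaller n.
    """
    f = train.n_features
    if not (1 <= n <= f):
        raise ValueError(f"n={n} must lie in 1..{f}")
    if n == 1:
        return np.zeros(f, dtype=int)
    profiles, _, _ = _standardize_train(train.values)
    profiles = profiles.T
    for attempt in range(5):
        labels = _kmeans_labels(profiles, n, seed + attempt)
        if np.unique(labels).size == n:
            return _canonical_labels(labels)
    logger.warning("cluster_features: empty clusters persist at n=%d; reducing", n)
    while n > 1:
        n -= 1
        labels = _kmeans_labels(profiles, n, seed)
        if np.unique(labels).size == n:
            return _canonical_labels(labels)
    return np.zeros(f, dtype=int)


def _stratified_fold_ids(
    labels01: np.ndarray, n_folds: int, n_reps: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_reps, n_subjects) random stratified fold assignments."""
    n = labels01.size
    counts = np.bincount(labels01, minlength=2)
    if n_folds > counts.min():
        raise ValueError(
            f"n_folds={n_folds} exceeds smallest class count {counts.min()} in training half"
        )
    out = np.empty((n_reps, n), dtype=np.int64)
    for r in range(n_reps):
        for cls in (0, 1):
            idx = rng.permutation(np.flatnonzero(labels01 == cls))
            fold_perm = rng.permutation(n_folds)
            out[r, idx] = fold_perm[np.arange(idx.size) % n_folds]
    return out


def _assignment_to_csr(assignment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n_clusters = int(assignment.max()) + 1
    order = np.argsort(assignment, kind="stable")
    counts = np.bincount(assignment, minlength=n_clusters)
    ptr = np.concatenate([[0], np.cumsum(counts)])
    return order.astype(np.int64), ptr.astype(np.int64)


def score_clusters(
    train: FeatureTable,
    assignment: np.ndarray,
    config: RCEConfig,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated linear-SVM score of every cluster.

    For each of ``n_reps`` repetitions a fresh stratified ``n_folds``
    partition of the training subjects is drawn; every cluster is scored by
    the SVM trained on its features alone, cycling all held-out folds. The
    score is the mean held-out accuracy over folds and repetitions.

    Returns (scores, rep_scores) with rep_scores of shape (n_reps, n_clusters).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    x, _, _ = _standardize_train(train.values)
    y = np.where(train.labels == 1, 1.0, -1.0)
    fold_ids = _stratified_fold_ids(train.labels, config.n_folds, config.n_reps, rng)
    feat_idx, feat_ptr = _assignment_to_csr(np.asarray(assignment))
    scores, rep_scores = score_clusters_kernel(
        np.ascontiguousarray(x),
        y,
        feat_idx,
        feat_ptr,
        fold_ids,
        config.n_folds,
        float(config.svm_cost),
        MAX_EPOCHS,
        TOL,
    )
    return scores, rep_scores


def eliminate_clusters(
    assignment: np.ndarray, scores: np.ndarray, elim_frac: float
) -> np.ndarray:
    """Indices of features surviving elimination of the worst clusters.

    Removes ceil(elim_frac * n_clusters) lowest-scoring clusters, at least one
    but never all; ties are broken toward the smaller cluster id. With a
    single cluster this is a no-op (termination signal).
    """
    assignment = np.asarray(assignment)
    scores = np.asarray(scores)
    n_clusters = scores.size
    if n_clusters < 2:
        return np.arange(assignment.size)
    n_elim = min(n_clusters - 1, max(1, math.ceil(elim_frac * n_clusters)))
    order = sorted(range(n_clusters), key=lambda c: (scores[c], c))
    dead = set(order[:n_elim])
    return np.flatnonzero(~np.isin(assignment, list(dead)))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# -- the estimator -------------------------------------------------------------


class RCESVC(ClassifierMixin, BaseEstimator):
    """Recursive-cluster-elimination linear SVM classifier.

    ``fit`` performs the full protocol: deterministic stratified half-split
    of the cohort, the cluster / score / eliminate loop on the training half,
    evolving test accuracy on the held-out half, and selection of the best
    iteration. ``predict`` applies the linear SVM trained on the training
    half restricted to the best iteration's features.

    Parameters
    ----------
    n_folds, n_reps, elim_frac, C : the protocol settings
        Defaults 10 folds, 500 repetitions, bottom 10% eliminated, cost 1.
    recluster_each_rep : bool
        If True, K-means is re-run for every repetition and scores are
        averaged at the feature level before cluster elimination (the literal
        "clustering repeated 500 times" reading); default False re-partitions
        only the cross-validation folds.
    random_state : int
        Seeds the split, clustering and fold draws; identical seeds give
        bit-identical results.

    Attributes
    ----------
    result_ : RCEResult
    best_features_ : list of str
        Ranked surviving features of the best iteration.
    classes_ : ndarray of the two class labels.
    """

    def __init__(
        self,
        n_folds: int = 10,
        n_reps: int = 500,
        elim_frac: float = 0.10,
        C: float = 1.0,
        recluster_each_rep: bool = False,
        random_state: int = 0,
    ):
        self.n_folds = n_folds
        self.n_reps = n_reps
        self.elim_frac = elim_frac
        self.C = C
        self.recluster_each_rep = recluster_each_rep
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------

    def _to_table(self, X, y) -> FeatureTable:
        if isinstance(X, FeatureTable):
            return X
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(values.shape[1])]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_.size}")
        labels = (y == self.classes_[1]).astype(int)
        return FeatureTable(values=values, labels=labels, feature_names=names)

    def fit(self, X, y=None):
        if isinstance(X, FeatureTable):
            table = X
            self.classes_ = np.array([0, 1])
        else:
            if y is None:
                raise ValueError("y is required unless X is a FeatureTable")
            table = self._to_table(X, y)
        config = RCEConfig(
            n_folds=self.n_folds,
            n_reps=self.n_reps,
            elim_frac=self.elim_frac,
            svm_cost=self.C,
            seed=self.random_state,
            recluster_each_rep=self.recluster_each_rep,
        )
        self.n_features_in_ = table.n_features
        self.feature_names_in_ = np.asarray(table.feature_names, dtype=object)
        self._run(table, config)
        return self

    def _run(self, table: FeatureTable, config: RCEConfig) -> None:
        train, test = split_cohort(table, config.seed)
        counts = np.bincount(train.labels, minlength=2)
        if config.n_folds > counts.min():
            raise ValueError(
                f"n_folds={config.n_folds} exceeds smallest training class count {counts.min()}"
            )
        xtr, mu, sd = _standardize_train(train.values)
        xte = (test.values - mu) / sd
        ytr = np.where(train.labels == 1, 1.0, -1.0)
        yte = np.where(test.labels == 1, 1.0, -1.0)

        active = np.arange(table.n_features)
        train_std = FeatureTable(
            values=xtr,
            labels=train.labels,
            feature_names=train.feature_names,
            subject_ids=train.subject_ids,
        )
        n = initial_cluster_count(train_std, _sub_seed(config.seed, 0, 0))
        iterations: list[RCEIteration] = []
        weights: list[np.ndarray] = []
        it = 0
        while True:
            sub = train_std.subset(cols=active)
            seed_it = _sub_seed(config.seed, 1, it)
            if config.recluster_each_rep:
                assignment, scores = self._score_reclustered(sub, n, config, seed_it)
            else:
                assignment = cluster_features(sub, n, seed_it)
                scores, _ = score_clusters(sub, assignment, config, seed=seed_it)
            w, acc = train_eval(xtr[:, active], ytr, xte[:, active], yte, config.svm_cost)
            iterations.append(
                RCEIteration(
                    n_clusters=n,
                    surviving_feature_names=[table.feature_names[i] for i in active],
                    cluster_scores=np.asarray(scores),
                    feature_scores=np.asarray(scores)[assignment],
                    evolving_test_accuracy=acc,
                )
            )
            weights.append(w)
            logger.info(
                "RCE iteration %d: n_clusters=%d, n_features=%d, test_accuracy=%.3f",
                it, n, active.size, acc,
            )
            if n <= 1 or active.size <= 1:
                break
            keep_local = eliminate_clusters(assignment, scores, config.elim_frac)
            active = active[keep_local]
            n = min(n - 1, max(1, _round_half_up(0.9 * n)), active.size)
            it += 1

        best = 0
        best_key = (-np.inf, -np.inf)
        for i, rec in enumerate(iterations):
            key = (rec.evolving_test_accuracy, -len(rec.surviving_feature_names))
            if key > best_key:
                best_key = key
                best = i
        rec = iterations[best]
        order = sorted(
            range(len(rec.surviving_feature_names)),
            key=lambda j: (-rec.feature_scores[j], j),
        )
        ranking = [
            (rec.surviving_feature_names[j], float(rec.feature_scores[j])) for j in order
        ]
        self.result_ = RCEResult(
            iterations=iterations,
            best_iteration=best,
            final_ranking=ranking,
            config=config,
            train_subject_ids=train.subject_ids,
            test_subject_ids=test.subject_ids,
        )
        self.best_features_ = [f for f, _ in ranking]
        name_to_col = {f: i for i, f in enumerate(table.feature_names)}
        self._best_cols = np.array(
            sorted(name_to_col[f] for f in rec.surviving_feature_names), dtype=int
        )
        # final predictor: SVM of the best iteration (train half, best features)
        self._w = weights[best]
        self._mu, self._sd = mu, sd

    def _score_reclustered(
        self, sub: FeatureTable, n: int, config: RCEConfig, seed_it: int
    ) -> tuple[np.ndarray, np.ndarray]:
        """Literal reading: fresh K-means per repetition, feature-level
        averaging of scores, elimination on a reference clustering."""
        one_rep = RCEConfig(
            n_folds=config.n_folds,
            n_reps=1,
            elim_frac=config.elim_frac,
            svm_cost=config.svm_cost,
            seed=config.seed,
        )
        feat_scores = np.zeros(sub.n_features)
        for r in range(config.n_reps):
            seed_r = _sub_seed(seed_it, 2, r)
            assignment_r = cluster_features(sub, n, seed_r)
            scores_r, _ = score_clusters(sub, assignment_r, one_rep, seed=seed_r)
            feat_scores += scores_r[assignment_r]
        feat_scores /= config.n_reps
        assignment = cluster_features(sub, n, seed_it)
        cluster_scores = np.array(
            [feat_scores[assignment == c].mean() for c in range(int(assignment.max()) + 1)]
        )
        return assignment, cluster_scores

    def predict(self, X):
        if not hasattr(self, "_w"):
            raise ValueError("RCESVC is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        elif isinstance(X, FeatureTable):
            X = X.values
        X = np.asarray(X, dtype=float)
        xs = (X - self._mu) / self._sd
        cols = self._best_cols
        d = cols.size
        margin = xs[:, cols] @ self._w[:d] + self._w[d]
        return np.where(margin >= 0, self.classes_[1], self.classes_[0])

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y)))


def _sub_seed(seed: int, stream: int, index: int) -> int:
    """Deterministic derived seed below 2^31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stream, index))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_rce_svm(table: FeatureTable, config: RCEConfig) -> RCEResult:
    """Run the full RCE-SVM protocol on a labeled feature table."""
    clf = RCESVC(
        n_folds=config.n_folds,
        n_reps=config.n_reps,
        elim_frac=config.elim_frac,
        C=config.svm_cost,
        recluster_each_rep=config.recluster_each_rep,
        random_state=config.seed,
    )
    clf.fit(table)
    return clf.result_
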