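"""Compiled linear SVM used inside the recursive-cluster-elimination loop.

The RCE scoring step trains on the order of 10^5--10^6 linear SVMs per
cohort, each on a few dozen subjects and a handful of features. This module
implements the standard dual coordinate-descent solver for the L1-hinge
C-SVM (the liblinear algorithm) under numba, with the bias handled as an
augmented, regularized constant feature:

    min_w 0.5 ||w||^2 + C sum_i max(0, 1 - y_i (w . [x_i, 1]))

Coordinates are swept in a fixed order, so the solver is fully deterministic.
Tests cross-check its decisions against scikit-learn's libsvm-based SVC.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# stopping rule: loose enough for speed, tight enough that held-out
# predictions agree with a fully converged solver (checked in tests)
MAX_EPOCHS = 60
TOL = 5e-3


@njit(cache=True)
def svm_train(X, y, C, max_epochs, tol):  # pragma: no cover - compiled
    """Dual coordinate descent; returns w of length d+1 (last entry = bias)."""
    n, d = X.shape
    w = np.zeros(d + 1)
    alpha = np.zeros(n)
    qii = np.empty(n)
    for i in range(n):
        s = 1.0  # augmented bias feature
        for j in range(d):
            s += X[i, j] * X[i, j]
        qii[i] = s
    for _ in range(max_epochs):
        max_pg = 0.0
        for i in range(n):
            s = w[d]
            for j in range(d):
                s += w[j] * X[i, j]
            g = y[i] * s - 1.0
            if alpha[i] == 0.0:
                pg = min(g, 0.0)
            elif alpha[i] == C:
                pg = max(g, 0.0)
            else:
                pg = g
            apg = abs(pg)
            if apg > max_pg:
                max_pg = apg
            if apg > 1e-12:
                a_old = alpha[i]
                a_new = min(max(a_old - g / qii[i], 0.0), C)
                da = (a_new - a_old) * y[i]
                if da != 0.0:
                    alpha[i] = a_new
                    for j in range(d):
                        w[j] += da * X[i, j]
                    w[d] += da
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def svm_accuracy(w, X, y):  # pragma: no cover - compiled
    n, d = X.shape
    correct = 0
    for i in range(n):
        s = w[d]
        for j in range(d):
            s += w[j] * X[i, j]
        if (1.0 if s >= 0.0 else -1.0) == y[i]:
            correct += 1
    return correct / n


@njit(cache=True)
def score_clusters_kernel(
    X, y, feat_idx, feat_ptr, fold_ids, n_folds, C, max_epochs, tol
):  # pragma: no cover - compiled
    """Mean held-out fold accuracy per cluster over all repetitions.

    Parameters
    ----------
    X : (n_subjects, n_features) standardized training matrix
    y : (n_subjects,) labels in {-1, +1}
    feat_idx, feat_ptr : CSR layout of cluster -> feature columns
    fold_ids : (n_reps, n_subjects) fold assignment per repetition
    n_folds : folds per repetition
    C, max_epochs, tol : SVM solver settings

    Returns
    -------
    scores : (n_clusters,) mean accuracy
    rep_scores : (n_reps, n_clusters) per-repetition mean fold accuracy
    """
    n, _ = X.shape
    n_clusters = feat_ptr.shape[0] - 1
    n_reps = fold_ids.shape[0]
    rep_scores = np.zeros((n_reps, n_clusters))
    for c in range(n_clusters):
        lo, hi = feat_ptr[c], feat_ptr[c + 1]
        dc = hi - lo
        Xc = np.empty((n, dc))
        for i in range(n):
            for j in range(dc):
                Xc[i, j] = X[i, feat_idx[lo + j]]
        for r in range(n_reps):
            acc_sum = 0.0
            for f in range(n_folds):
                n_tr = 0
                n_te = 0
                for i in range(n):
                    if fold_ids[r, i] == f:
                        n_te += 1
                    else:
                        n_tr += 1
                Xtr = np.empty((n_tr, dc))
                ytr = np.empty(n_tr)
                Xte = np.empty((n_te, dc))
                yte = np.empty(n_te)
                a = 0
                b = 0
                for i in range(n):
                    if fold_ids[r, i] == f:
                        for j in range(dc):
                            Xte[b, j] = Xc[i, j]
                        yte[b] = y[i]
                        b += 1
                    else:
                        for j in range(dc):
                            Xtr[a, j] = Xc[i, j]
                        ytr[a] = y[i]
                        a += 1
                w = svm_train(Xtr, ytr, C, max_epochs, tol)
                acc_sum += svm_accuracy(w, Xte, yte)
            rep_scores[r, c] = acc_sum / n_folds
    scores = np.zeros(n_clusters)
    for c in range(n_clusters):
        s = 0.0
        for r in range(n_reps):
            s += rep_scores[r, c]
        scores[c] = s / n_reps
    return scores, rep_scores


def train_eval(Xtr, ytr, Xte, yte, C, max_epochs=MAX_EPOCHS, tol=TOL):
    """Train on (Xtr, ytr), return (weights, held-out accuracy). Labels +-1."""
    Xtr = np.ascontiguousarray(Xtr, dtype=np.float64)
    Xte = np.ascontiguousarray(Xte, dtype=np.float64)
    w = svm_train(Xtr, np.asarray(ytr, dtype=np.float64), float(C), max_epochs, tol)
    acc = svm_accuracy(w, Xte, np.asarray(yte, dtype=np.float64))
    return w, float(acc)
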