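"""Reference evaluations of the pipeline on synthetic study-scale data.

Self-contained experiments exercising every stage end to end — coefficient
recovery at realistic and asymptotic series lengths, correlation purging on
the instantaneous-copy construction, BIC order selection, planted-difference
recovery by the full connectivity + RCE-SVM pipeline, the permutation null,
least-squares oracle equivalence and seed determinism. Shared by the test
suite and ``scripts/acceptance.py``; every quantity is recomputed from
simulation at call time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import ConnectivityFeatureExtractor, FeatureTable
from .mvar import MVAR
from .rce import RCEConfig, run_rce_svm
from .synthetic import (
    CohortSpec,
    GroupModel,
    calibrated_spec,
    simulate_cohort,
    simulate_subject,
    stable_random_spec,
)


def _sub_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# -- coefficient recovery ------------------------------------------------------


def coefficient_recovery_mae(T: int, seed: int = 0, k: int = 9) -> float:
    """Mean absolute error of fitted lag coefficients on one order-1 subject.

    Simulates a k-region order-1 modified VAR subject of length ``T`` (no
    between-subject jitter, so the generative coefficients are the truth),
    fits the model at the true order and averages |a_hat - a| over all k*k
    lag entries.
    """
    spec = stable_random_spec(
        k=k, T=T, p=1, n_planted_diffs=1, effect_size=0.0,
        seed=seed, between_subject_jitter_sd=0.0,
    )
    ts = simulate_subject(spec, "A", _sub_seed(seed, 1))
    model = MVAR(order=1, include_zero_lag=True).fit(ts)
    return float(np.abs(model.lag_coeffs_[0] - spec.group_a.lags[0]).mean())


# -- correlation purging -------------------------------------------------------


def purging_trial(seed: int, T: int = 5000) -> tuple[float, float]:
    """Naive GC and CPGC on the spurious edge of the instantaneous-copy system.

    x1 is AR(1) with coefficient 0.9; x2 = x1(t) + 0.1 * noise is a zero-lag
    copy. A plain VAR misreads the copy as a lagged influence x1 -> x2; the
    zero-lag term of the modified model absorbs it. Returns
    (|naive_gc|, |cpgc|) on entry (2, 1).
    """
    rng = np.random.default_rng(seed)
    burn = 100
    e = rng.normal(size=T + burn)
    x1 = np.zeros(T + burn)
    for t in range(1, T + burn):
        x1[t] = 0.9 * x1[t - 1] + e[t]
    x2 = x1 + 0.1 * rng.normal(size=T + burn)
    x = np.column_stack([x1, x2])[burn:]
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    naive = MVAR(order=1, include_zero_lag=False).fit(x).causality_matrix()
    purged = MVAR(order=1, include_zero_lag=True).fit(x).causality_matrix()
    return float(abs(naive[1, 0])), float(abs(purged[1, 0]))


def purging_success_count(n_seeds: int = 20, seed: int = 0) -> tuple[int, float, float]:
    """Seeds (of ``n_seeds``) where |naive| > 5|cpgc| and |cpgc| < 0.05,
    plus the median naive/cpgc ratio and median |cpgc|."""
    ok = 0
    ratios, cpgcs = [], []
    for i in range(n_seeds):
        naive, cp = purging_trial(_sub_seed(seed, 2, i))
        ratios.append(naive / max(cp, 1e-12))
        cpgcs.append(cp)
        if naive > 5 * cp and cp < 0.05:
            ok += 1
    return ok, float(np.median(ratios)), float(np.median(cpgcs))


# -- BIC order selection -------------------------------------------------------


def _order2_spec(T: int = 1000) -> CohortSpec:
    # fixed stable 3-region order-2 system with lag-2 magnitudes of 0.4
    a1 = np.diag([0.3, 0.3, 0.3])
    a2 = np.array(
        [
            [0.4, 0.0, 0.0],
            [0.4, -0.4, 0.0],
            [0.0, 0.4, 0.4],
        ]
    )
    g = GroupModel(zero_lag=np.zeros((3, 3)), lags=[a1, a2])
    return CohortSpec(
        group_a=g, group_b=g, k=3, T=T, n_a=1, n_b=1,
        between_subject_jitter_sd=0.0, seed=0,
    )


def bic_order2_rate(n_sims: int = 100, seed: int = 0, T: int = 1000) -> float:
    """Fraction of simulations where BIC recovers the true order 2."""
    from .mvar import select_order_bic

    spec = _order2_spec(T)
    hits = 0
    for i in range(n_sims):
        ts = simulate_subject(spec, "A", _sub_seed(seed, 3, i))
        hits += select_order_bic(ts, p_max=4, include_zero_lag=True) == 2
    return hits / n_sims


# -- full pipeline: planted-difference recovery --------------------------------


@dataclass
class PipelineReplicate:
    best_accuracy: float
    baseline_accuracy: float
    planted_all_survive: bool
    n_features_best: int


def pipeline_replicate(
    seed: int,
    n_reps: int = 50,
    target_effect_sd: float = 1.5,
    n_planted: int = 3,
) -> PipelineReplicate:
    """One synthetic cohort through the whole pipeline.

    Simulates a 30+26 cohort (9 regions, 210 time points) with ``n_planted``
    directed lag-1 differences calibrated to ``target_effect_sd`` sd at the
    CPGC-feature level, extracts the 108 instantaneous+causal features and
    runs RCE-SVM (10 folds, ``n_reps`` repetitions).
    """
    spec = calibrated_spec(
        k=9, T=210, p=1, n_planted_diffs=n_planted,
        target_effect_sd=target_effect_sd, seed=seed,
    )
    panel, labels = simulate_cohort(spec)
    table = (
        ConnectivityFeatureExtractor(feature_set="instantaneous_plus_causal", order=1)
        .fit(panel)
        .transform(panel)
    )
    result = run_rce_svm(table, RCEConfig(n_folds=10, n_reps=n_reps, seed=_sub_seed(seed, 4)))
    best = result.iterations[result.best_iteration]
    survived = set(spec.planted_feature_names()) <= set(best.surviving_feature_names)
    return PipelineReplicate(
        best_accuracy=result.best_accuracy,
        baseline_accuracy=result.baseline_accuracy,
        planted_all_survive=bool(survived),
        n_features_best=len(best.surviving_feature_names),
    )


def null_replicate(seed: int, n_reps: int = 50) -> float:
    """Best-iteration test accuracy under permuted labels on an effect-free
    cohort (permutation-null control)."""
    spec = stable_random_spec(
        k=9, T=210, p=1, n_planted_diffs=3, effect_size=0.0, seed=seed
    )
    panel, labels = simulate_cohort(spec)
    table = (
        ConnectivityFeatureExtractor(feature_set="instantaneous_plus_causal", order=1)
        .fit(panel)
        .transform(panel)
    )
    rng = np.random.default_rng(_sub_seed(seed, 5))
    table.labels = rng.permutation(table.labels)
    result = run_rce_svm(table, RCEConfig(n_folds=10, n_reps=n_reps, seed=_sub_seed(seed, 6)))
    return float(result.best_accuracy)


# -- least-squares oracle ------------------------------------------------------


def ols_oracle_max_error(seed: int = 0, k: int = 3, p: int = 2, T: int = 50) -> float:
    """Max |difference| between fitted coefficients and the explicit
    normal-equations solution (X'X)^{-1} X'y per target."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(T, k))
    model = MVAR(order=p, include_zero_lag=True).fit(x)
    n_eff = T - p
    lag_block = np.column_stack(
        [np.ones(n_eff)] + [x[p - n : T - n, :] for n in range(1, p + 1)]
    )
    worst = 0.0
    for i in range(k):
        others = [j for j in range(k) if j != i]
        design = np.column_stack([lag_block[:, :1], x[p:, others], lag_block[:, 1:]])
        coef = np.linalg.solve(design.T @ design, design.T @ x[p:, i])
        fitted = np.concatenate(
            [
                [model.intercepts_[i]],
                model.zero_lag_[i, others],
                np.concatenate([model.lag_coeffs_[n][i, :] for n in range(p)]),
            ]
        )
        worst = max(worst, float(np.max(np.abs(coef - fitted))))
    return worst


# -- determinism ---------------------------------------------------------------


def determinism_check(seed: int = 0, n_reps: int = 10) -> bool:
    """Two identically seeded runs give bit-identical accuracy curves and
    rankings."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(24, 20))
    labels = np.repeat([0, 1], 12)
    values[labels == 1, :2] += 1.0
    table = FeatureTable(values=values, labels=labels, feature_names=[f"f{i}" for i in range(20)])
    cfg = RCEConfig(n_folds=5, n_reps=n_reps, seed=seed)
    r1 = run_rce_svm(table, cfg)
    r2 = run_rce_svm(table, cfg)
    curves_equal = all(
        a.evolving_test_accuracy == b.evolving_test_accuracy
        and np.array_equal(a.cluster_scores, b.cluster_scores)
        and a.surviving_feature_names == b.surviving_feature_names
        for a, b in zip(r1.iterations, r2.iterations)
    )
    return curves_equal and r1.final_ranking == r2.final_ranking and r1.best_iteration == r2.best_iteration
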