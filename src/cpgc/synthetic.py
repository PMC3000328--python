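"""Synthetic cohorts from generative (modified) VAR models.

Cohorts are simulated from the same model family that the estimator fits:

    X(t) = A'(0) X(t) + sum_{n=1..p} A'(n) X(t-n) + E(t),

with diag(A'(0)) = 0 and Gaussian innovations. Solving for X(t) gives the
reduced-form recursion X(t) = (I - A'(0))^{-1} (sum_n A'(n) X(t-n) + E(t)),
whose companion matrix must have spectral radius < 1 (checked at
construction). Group differences are planted as shifts of chosen directed
lag-path weights, giving ground truth for feature-selection tests. Defaults
mirror a realistic two-group resting-state study: 9 regions, 210 time points
at TR = 2 s, 30 + 26 subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import compute_connectivity, extract_features
from .timeseries import SubjectTimeSeries, TimeSeriesPanel, default_region_names

MAX_DRAW_ATTEMPTS = 100
STABILITY_MARGIN = 0.95


@dataclass
class GroupModel:
    """Generative coefficients of one group: symmetric zero-lag coupling and
    p lag matrices."""

    zero_lag: np.ndarray
    lags: list[np.ndarray]

    def __post_init__(self) -> None:
        self.zero_lag = np.asarray(self.zero_lag, dtype=float)
        self.lags = [np.asarray(a, dtype=float) for a in self.lags]
        k = self.zero_lag.shape[0]
        if self.zero_lag.shape != (k, k):
            raise ValueError("zero_lag must be square")
        if np.any(np.diag(self.zero_lag) != 0):
            raise ValueError("zero_lag diagonal must be zero")
        if not np.allclose(self.zero_lag, self.zero_lag.T):
            raise ValueError("zero_lag must be symmetric")
        for a in self.lags:
            if a.shape != (k, k):
                raise ValueError("all lag matrices must be k x k")

    @property
    def k(self) -> int:
        return self.zero_lag.shape[0]

    @property
    def order(self) -> int:
        return len(self.lags)


def spectral_radius(zero_lag: np.ndarray, lags: list[np.ndarray]) -> float:
    """Spectral radius of the reduced-form companion matrix."""
    k = zero_lag.shape[0]
    p = len(lags)
    m = np.linalg.inv(np.eye(k) - zero_lag)
    comp = np.zeros((k * p, k * p))
    for n, a in enumerate(lags):
        comp[:k, n * k : (n + 1) * k] = m @ a
    if p > 1:
        comp[k:, : k * (p - 1)] = np.eye(k * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class CohortSpec:
    """Two-group cohort specification with planted directed differences."""

    group_a: GroupModel
    group_b: GroupModel
    k: int = 9
    T: int = 210
    innovation_sd: float = 1.0
    n_a: int = 30
    n_b: int = 26
    between_subject_jitter_sd: float = 0.02
    seed: int = 0
    sampling_interval: float = 2.0
    planted_paths: list[tuple[int, int, int]] = field(default_factory=list)
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.group_a.k != self.k or self.group_b.k != self.k:
            raise ValueError("group models must match k")
        if self.group_a.order != self.group_b.order:
            raise ValueError("groups must share the model order")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        if self.between_subject_jitter_sd < 0:
            raise ValueError("between_subject_jitter_sd must be >= 0")
        for name, g in (("A", self.group_a), ("B", self.group_b)):
            rho = spectral_radius(g.zero_lag, g.lags)
            if rho >= 1.0:
                raise ValueError(
                    f"group {name} model is non-stationary (spectral radius {rho:.3f})"
                )
        if self.region_names is None:
            self.region_names = default_region_names(self.k)

    @property
    def order(self) -> int:
        return self.group_a.order

    def planted_feature_names(self) -> list[str]:
        """Directed feature names ("SRC->TGT") of the planted paths."""
        return [
            f"{self.region_names[src]}->{self.region_names[tgt]}"
            for (tgt, src, _lag) in self.planted_paths
        ]


def _draw_group(rng: np.random.Generator, k: int, p: int, density: float) -> GroupModel:
    lags = []
    for n in range(p):
        a = np.zeros((k, k))
        scale = 0.5**n
        np.fill_diagonal(a, rng.uniform(0.2, 0.4, size=k) * scale)
        mask = rng.random((k, k)) < density
        np.fill_diagonal(mask, False)
        signs = rng.choice([-1.0, 1.0], size=(k, k))
        a += mask * signs * rng.uniform(0.15, 0.35, size=(k, k)) * scale
        lags.append(a)
    zl = np.zeros((k, k))
    n_pairs = max(1, k // 3)
    iu = np.array([(i, j) for i in range(k) for j in range(i + 1, k)])
    chosen = rng.choice(len(iu), size=n_pairs, replace=False)
    for c in chosen:
        i, j = iu[c]
        w = rng.uniform(0.2, 0.4) * rng.choice([-1.0, 1.0])
        zl[i, j] = zl[j, i] = w
    return GroupModel(zero_lag=zl, lags=lags)


def stable_random_spec(
    k: int = 9,
    T: int = 210,
    p: int = 1,
    n_planted_diffs: int = 3,
    effect_size: float | np.ndarray = 0.4,
    seed: int = 0,
    density: float = 0.15,
    n_a: int = 30,
    n_b: int = 26,
    between_subject_jitter_sd: float = 0.02,
    innovation_sd: float = 1.0,
) -> CohortSpec:
    """Draw a sparse stable base model and plant group differences.

    Group B equals group A except that ``n_planted_diffs`` randomly chosen
    directed lag-1 path weights are shifted by ``effect_size`` (a scalar, or
    one shift per planted path). The base model and the chosen paths depend
    only on ``seed``, never on ``effect_size``, so effect sweeps share
    ground truth.
    """
    if n_planted_diffs > k * (k - 1):
        raise ValueError("n_planted_diffs exceeds the number of directed paths")
    shifts = np.broadcast_to(np.asarray(effect_size, dtype=float), (n_planted_diffs,))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    group_a = None
    for _ in range(MAX_DRAW_ATTEMPTS):
        cand = _draw_group(rng, k, p, density)
        if spectral_radius(cand.zero_lag, cand.lags) < STABILITY_MARGIN:
            group_a = cand
            break
    if group_a is None:
        raise RuntimeError(
            "could not draw a stable base model; try smaller coefficients/density"
        )

    path_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    directed = [(tgt, src) for tgt in range(k) for src in range(k) if src != tgt]
    for _ in range(MAX_DRAW_ATTEMPTS):
        chosen = path_rng.choice(len(directed), size=n_planted_diffs, replace=False)
        paths = [(directed[c][0], directed[c][1], 1) for c in chosen]
        lags_b = [a.copy() for a in group_a.lags]
        for (tgt, src, lag), shift in zip(paths, shifts):
            lags_b[lag - 1][tgt, src] += shift
        group_b = GroupModel(zero_lag=group_a.zero_lag.copy(), lags=lags_b)
        if spectral_radius(group_b.zero_lag, group_b.lags) < STABILITY_MARGIN:
            break
    else:
        raise RuntimeError(
            "planted shifts destabilize the model; try a smaller effect_size"
        )
    return CohortSpec(
        group_a=group_a,
        group_b=group_b,
        k=k,
        T=T,
        n_a=n_a,
        n_b=n_b,
        innovation_sd=innovation_sd,
        between_subject_jitter_sd=between_subject_jitter_sd,
        seed=seed,
        planted_paths=paths,
    )


def simulate_subject(spec: CohortSpec, group: str, subject_seed: int) -> SubjectTimeSeries:
    """Simulate one subject of the given group ("A" or "B").

    Innovations are Gaussian; zero-lag mixing is applied through
    (I - A'(0))^{-1}; a burn-in of 10 x order samples is discarded. Optional
    per-subject jitter perturbs the lag coefficients (redrawn until stable).
    """
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    model = spec.group_a if group == "A" else spec.group_b
    rng = np.random.default_rng(subject_seed)
    k, p = spec.k, spec.order

    lags = [a.copy() for a in model.lags]
    if spec.between_subject_jitter_sd > 0:
        for _ in range(20):
            cand = [
                a + rng.normal(0.0, spec.between_subject_jitter_sd, size=(k, k))
                for a in model.lags
            ]
            if spectral_radius(model.zero_lag, cand) < 1.0:
                lags = cand
                break

    eye_minus = np.eye(k) - model.zero_lag
    if abs(np.linalg.det(eye_minus)) < 1e-12:
        raise ValueError("(I - A'(0)) is singular; zero-lag coupling too strong")
    mix = np.linalg.inv(eye_minus)

    burn = 10 * p
    total = spec.T + burn + p
    x = np.zeros((total, k))
    innov = rng.normal(0.0, spec.innovation_sd, size=(total, k))
    for t in range(p, total):
        drive = innov[t].copy()
        for n in range(1, p + 1):
            drive += lags[n - 1] @ x[t - n]
        x[t] = mix @ drive
    data = x[p + burn :]
    return SubjectTimeSeries(
        data=data,
        sampling_interval=spec.sampling_interval,
        region_names=list(spec.region_names),
        subject_id=f"{group}{subject_seed}",
    )


def simulate_cohort(spec: CohortSpec) -> tuple[TimeSeriesPanel, np.ndarray]:
    """Simulate the full two-group cohort (labels: group A -> 0, B -> 1)."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(2,))
    seeds = ss.generate_state(spec.n_a + spec.n_b) % (2**31 - 1)
    subjects = []
    for i in range(spec.n_a):
        s = simulate_subject(spec, "A", int(seeds[i]))
        s.subject_id = f"A{i + 1:02d}"
        subjects.append(s)
    for i in range(spec.n_b):
        s = simulate_subject(spec, "B", int(seeds[spec.n_a + i]))
        s.subject_id = f"B{i + 1:02d}"
        subjects.append(s)
    labels = np.concatenate([np.zeros(spec.n_a, dtype=int), np.ones(spec.n_b, dtype=int)])
    return TimeSeriesPanel(subjects=subjects, labels=labels), labels


def planted_feature_sd(
    spec: CohortSpec, n_subjects: int = 120, seed: int = 12345, order: int | None = None
) -> np.ndarray:
    """Across-subject sd of each planted CPGC feature under the group-A model.

    Simulates a calibration batch from group A, fits the modified VAR per
    subject, and returns one standard deviation per planted directed feature.
    Used to express planted coefficient shifts in feature-level sd units.
    """
    order = spec.order if order is None else order
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(3,))
    seeds = ss.generate_state(n_subjects) % (2**31 - 1)
    conn = []
    for s in seeds:
        subj = simulate_subject(spec, "A", int(s))
        conn.append(compute_connectivity(subj, order=order))
    table = extract_features(
        conn, np.zeros(n_subjects, dtype=int), feature_set="causal"
    )
    names = spec.planted_feature_names()
    cols = [table.feature_names.index(nm) for nm in names]
    return table.values[:, cols].std(axis=0, ddof=1)


def calibrated_spec(
    k: int = 9,
    T: int = 210,
    p: int = 1,
    n_planted_diffs: int = 3,
    target_effect_sd: float = 1.5,
    seed: int = 0,
    n_calibration_subjects: int = 120,
    **kwargs,
) -> CohortSpec:
    """Cohort spec whose planted shifts equal ``target_effect_sd`` times the
    across-subject sd of the corresponding estimated CPGC features.

    The base model and planted paths are drawn once from ``seed`` (effect
    size zero), each planted feature's sd is measured on a group-A
    calibration batch, and the same spec is rebuilt with per-path calibrated
    coefficient shifts.
    """
    base = stable_random_spec(
        k=k, T=T, p=p, n_planted_diffs=n_planted_diffs, effect_size=0.0, seed=seed, **kwargs
    )
    sds = planted_feature_sd(base, n_subjects=n_calibration_subjects, seed=seed + 1)
    deltas = target_effect_sd * sds
    return stable_random_spec(
        k=k, T=T, p=p, n_planted_diffs=n_planted_diffs, effect_size=deltas, seed=seed, **kwargs
    )
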