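"""Connectivity feature extraction and group-difference testing.

Per subject, four k x k connectivity matrices are derived from the fitted
models:

* ``cpgc`` — correlation-purged Granger causality (lag-coefficient sums from
  the zero-lag-inclusive fit); directed, zero diagonal.
* ``gc_naive`` — the same sums from the plain VAR fit; directed.
* ``instantaneous`` — symmetrized A'(0); undirected, zero diagonal.
* ``pearson`` — sample correlation; undirected, unit diagonal.

Feature tables flatten these matrices cohort-wide: undirected matrices
contribute the k(k-1)/2 upper-triangle entries, directed matrices all k(k-1)
off-diagonal entries named ``"SRC->TGT"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .mvar import MVAR, pearson_matrix, select_order_bic
from .timeseries import SubjectTimeSeries, TimeSeriesPanel

FEATURE_SETS = ("pearson", "instantaneous", "instantaneous_plus_causal", "causal")


@dataclass
class ConnectivitySet:
    """All connectivity matrices of one subject. Entry (i, j) of a directed
    matrix is the influence of region j on region i."""

    cpgc: np.ndarray
    gc_naive: np.ndarray
    instantaneous: np.ndarray
    pearson: np.ndarray
    region_names: list[str]
    order: int = 1

    def __post_init__(self) -> None:
        k = len(self.region_names)
        for name in ("cpgc", "gc_naive", "instantaneous", "pearson"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            setattr(self, name, m)
        for name in ("cpgc", "gc_naive", "instantaneous"):
            if np.any(np.diag(getattr(self, name)) != 0):
                raise ValueError(f"{name} diagonal must be zero")
        if not np.allclose(np.diag(self.pearson), 1.0):
            raise ValueError("pearson diagonal must be 1")


def compute_connectivity(
    ts: SubjectTimeSeries,
    order: int | str = "bic",
    p_max: int = 5,
    absolute: bool = False,
) -> ConnectivitySet:
    """Fit the plain and modified VAR to one subject; collect all matrices."""
    if order == "bic":
        p = select_order_bic(ts, p_max=p_max, include_zero_lag=True)
    else:
        p = int(order)
    mvar = MVAR(order=p, include_zero_lag=True).fit(ts)
    var = MVAR(order=p, include_zero_lag=False).fit(ts)
    return ConnectivitySet(
        cpgc=mvar.causality_matrix(absolute=absolute),
        gc_naive=var.causality_matrix(absolute=absolute),
        instantaneous=mvar.instantaneous_matrix(),
        pearson=pearson_matrix(ts),
        region_names=list(ts.region_names),
        order=p,
    )


@dataclass
class FeatureTable:
    """Subjects x named features with binary labels — the interchange type
    between connectivity extraction and classification."""

    values: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x features)")
        n, f = self.values.shape
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values contain non-finite entries")
        if self.labels.size != n:
            raise ValueError("one label per subject required")
        if len(self.feature_names) != f:
            raise ValueError("one name per feature column required")
        if len(set(self.feature_names)) != f:
            raise ValueError("feature names must be unique")
        if not self.subject_ids:
            self.subject_ids = [f"S{i + 1:03d}" for i in range(n)]
        if len(self.subject_ids) != n:
            raise ValueError("one subject_id per row required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows=None, cols=None) -> "FeatureTable":
        rows = np.arange(self.n_subjects) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_features) if cols is None else np.asarray(cols)
        return FeatureTable(
            values=self.values[np.ix_(rows, cols)],
            labels=self.labels[rows],
            feature_names=[self.feature_names[c] for c in cols],
            subject_ids=[self.subject_ids[r] for r in rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        if "subject_id" not in df.columns or "label" not in df.columns:
            raise ValueError("feature table needs 'subject_id' and 'label' columns")
        feats = [c for c in df.columns if c not in ("subject_id", "label")]
        return cls(
            values=df[feats].to_numpy(dtype=float),
            labels=df["label"].to_numpy(),
            feature_names=feats,
            subject_ids=[str(s) for s in df["subject_id"]],
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def _undirected_names(names: list[str], tag: str) -> list[str]:
    sep = "<->" if tag == "inst" else "~"
    return [
        f"{names[i]}{sep}{names[j]}"
        for i in range(len(names))
        for j in range(i + 1, len(names))
    ]


def _directed_names(names: list[str]) -> list[str]:
    return [
        f"{src}->{tgt}" for tgt in names for src in names if src != tgt
    ]


def _flatten_undirected(m: np.ndarray) -> np.ndarray:
    k = m.shape[0]
    iu = np.triu_indices(k, k=1)
    return m[iu]


def _flatten_directed(m: np.ndarray) -> np.ndarray:
    # feature "SRC->TGT" is matrix entry (row TGT, col SRC)
    k = m.shape[0]
    vals = []
    for tgt in range(k):
        for src in range(k):
            if src != tgt:
                vals.append(m[tgt, src])
    return np.asarray(vals)


def extract_features(
    conn: list[ConnectivitySet],
    labels,
    feature_set: str = "instantaneous_plus_causal",
    subject_ids: list[str] | None = None,
) -> FeatureTable:
    """Flatten per-subject connectivity into a cohort feature table.

    ``pearson`` / ``instantaneous`` give k(k-1)/2 undirected features;
    ``causal`` gives k(k-1) directed CPGC features named ``SRC->TGT``;
    ``instantaneous_plus_causal`` concatenates the latter two.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    if not conn:
        raise ValueError("empty cohort")
    names = conn[0].region_names
    for c in conn[1:]:
        if c.region_names != names:
            raise ValueError("subjects have mismatched region sets")

    rows, feat_names = [], []
    if feature_set == "pearson":
        feat_names = _undirected_names(names, "pearson")
        rows = [_flatten_undirected(c.pearson) for c in conn]
    elif feature_set == "instantaneous":
        feat_names = _undirected_names(names, "inst")
        rows = [_flatten_undirected(c.instantaneous) for c in conn]
    elif feature_set == "causal":
        feat_names = _directed_names(names)
        rows = [_flatten_directed(c.cpgc) for c in conn]
    else:  # instantaneous_plus_causal
        feat_names = _undirected_names(names, "inst") + _directed_names(names)
        rows = [
            np.concatenate([_flatten_undirected(c.instantaneous), _flatten_directed(c.cpgc)])
            for c in conn
        ]
    return FeatureTable(
        values=np.vstack(rows),
        labels=labels,
        feature_names=feat_names,
        subject_ids=subject_ids or [],
    )


def ttest_features(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per feature, raw (uncorrected) p-values.

    Returns a DataFrame with columns feature, t, p, mean_0, mean_1,
    significant (p < alpha). Degenerate zero-variance features with equal
    means are reported as t=0, p=1.
    """
    g0 = table.values[table.labels == 0]
    g1 = table.values[table.labels == 1]
    if g0.shape[0] < 2 or g1.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects for a t-test")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g0, g1, equal_var=False, axis=0)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(g0.mean(axis=0), g1.mean(axis=0))
    t[degenerate & equal_means] = 0.0
    p[degenerate & equal_means] = 1.0
    t[degenerate & ~equal_means] = np.inf
    p[degenerate & ~equal_means] = 0.0
    return pd.DataFrame(
        {
            "feature": table.feature_names,
            "t": t,
            "p": p,
            "mean_0": g0.mean(axis=0),
            "mean_1": g1.mean(axis=0),
            "significant": p < alpha,
        }
    )


class ConnectivityFeatureExtractor(BaseEstimator, TransformerMixin):
    """Panel -> FeatureTable transformer.

    Fits the plain and modified VAR per subject (order per subject by BIC, or
    fixed), and flattens the requested connectivity matrices into a labeled
    feature table.

    Parameters
    ----------
    feature_set : one of {"pearson", "instantaneous", "instantaneous_plus_causal", "causal"}
    order : int or "bic"
    p_max : int
        BIC search bound when order="bic".
    absolute : bool
        Use sum of |coefficients| instead of the signed sum for causality.
    force_modal_order : bool
        When order="bic", re-fit every subject at the cohort's modal selected
        order instead of each subject's own.
    """

    def __init__(
        self,
        feature_set: str = "instantaneous_plus_causal",
        order: int | str = "bic",
        p_max: int = 5,
        absolute: bool = False,
        force_modal_order: bool = False,
    ):
        self.feature_set = feature_set
        self.order = order
        self.p_max = p_max
        self.absolute = absolute
        self.force_modal_order = force_modal_order

    def fit(self, X: TimeSeriesPanel, y=None):
        if not isinstance(X, TimeSeriesPanel):
            raise TypeError("ConnectivityFeatureExtractor expects a TimeSeriesPanel")
        self.region_names_ = list(X.region_names)
        return self

    def transform(self, X: TimeSeriesPanel) -> FeatureTable:
        conn = self.connectivity_sets(X)
        return extract_features(
            conn, X.labels, feature_set=self.feature_set, subject_ids=X.subject_ids
        )

    def connectivity_sets(self, X: TimeSeriesPanel) -> list[ConnectivitySet]:
        orders: list[int]
        if self.order == "bic":
            orders = [
                select_order_bic(s, p_max=self.p_max, include_zero_lag=True)
                for s in X.subjects
            ]
            if self.force_modal_order:
                modal = int(np.bincount(orders).argmax())
                orders = [modal] * len(orders)
        else:
            orders = [int(self.order)] * len(X.subjects)
        return [
            compute_connectivity(s, order=p, absolute=self.absolute)
            for s, p in zip(X.subjects, orders)
        ]
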