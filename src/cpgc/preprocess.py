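"""Time-series-level preprocessing before connectivity estimation.

The standard resting-state cleanup chain operating on extracted ROI series:

1. nuisance regression — per region, replace the series by its residual from
   an OLS fit on the confound series (e.g. white-matter and CSF averages);
2. zero-phase band-pass filtering, default 0.009--0.08 Hz;
3. per-region z-scoring (sample sd, denominator T-1).

All operations preserve shape and region order and return new objects.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.linalg
import scipy.signal
from sklearn.base import BaseEstimator, TransformerMixin

from .timeseries import SubjectTimeSeries, TimeSeriesPanel

logger = logging.getLogger(__name__)

DEFAULT_F_LO = 0.009
DEFAULT_F_HI = 0.08
_FILTER_ORDER = 4


def nuisance_regress(ts: SubjectTimeSeries, confounds: np.ndarray) -> SubjectTimeSeries:
    """Regress confound series out of every region column.

    Confounds are demeaned and an intercept is always included, so the
    residuals are exactly orthogonal to each confound column and have zero
    mean. Collinear confound columns are dropped with a warning.
    """
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    t = ts.n_timepoints
    if c.shape[0] != t:
        raise ValueError(f"confounds have {c.shape[0]} rows, time series has {t}")
    if c.shape[1] < 1:
        raise ValueError("need at least one confound column")
    c = c - c.mean(axis=0)

    # drop rank-deficient columns via pivoted QR
    _, r, piv = scipy.linalg.qr(c, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(c.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    keep = np.sort(piv[: int(np.sum(diag > tol))])
    if keep.size < c.shape[1]:
        dropped = sorted(set(range(c.shape[1])) - set(keep.tolist()))
        logger.warning(
            "nuisance_regress: dropping collinear confound columns %s", dropped
        )
        c = c[:, keep]
    if c.shape[1] == 0:
        raise ValueError("all confound columns are constant or collinear")

    design = np.column_stack([np.ones(t), c])
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    resid = ts.data - design @ beta
    return ts.with_data(resid)


def bandpass(
    ts: SubjectTimeSeries,
    f_lo: float = DEFAULT_F_LO,
    f_hi: float = DEFAULT_F_HI,
) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass per region column.

    A 4th-order Butterworth filter is applied forward and backward
    (``filtfilt``) with reflect padding, so there is no phase distortion —
    essential when lagged coefficients will be interpreted causally.
    """
    nyq = 1.0 / (2.0 * ts.sampling_interval)
    if not (0.0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < f_lo < f_hi < Nyquist={nyq:g} Hz"
        )
    b, a = scipy.signal.butter(
        _FILTER_ORDER, [f_lo, f_hi], btype="bandpass", fs=1.0 / ts.sampling_interval
    )
    padlen = min(ts.n_timepoints - 1, 3 * max(len(a), len(b)))
    out = scipy.signal.filtfilt(b, a, ts.data, axis=0, padtype="even", padlen=padlen)
    return ts.with_data(out)


def zscore(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Standardize each region column to mean 0, sample sd 1 (ddof=1)."""
    mu = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.region_names[i] for i in bad]
        raise ValueError(f"zero-variance region(s): {names}")
    return ts.with_data((ts.data - mu) / sd)


def preprocess_subject(
    ts: SubjectTimeSeries,
    do_nuisance: bool = True,
    do_bandpass: bool = True,
    do_zscore: bool = True,
    f_lo: float = DEFAULT_F_LO,
    f_hi: float = DEFAULT_F_HI,
) -> SubjectTimeSeries:
    """Nuisance regression, then band-pass, then z-score (each optional).

    Nuisance regression is skipped (not an error) when the subject carries no
    confound series.
    """
    if do_nuisance and ts.confounds is not None:
        ts = nuisance_regress(ts, ts.confounds)
    if do_bandpass:
        ts = bandpass(ts, f_lo=f_lo, f_hi=f_hi)
    if do_zscore:
        ts = zscore(ts)
    return ts


class TimeSeriesPreprocessor(BaseEstimator, TransformerMixin):
    """Cohort-level preprocessing transformer.

    Applies :func:`preprocess_subject` to every subject of a
    :class:`~cpgc.timeseries.TimeSeriesPanel`. Stateless (``fit`` only
    validates), so it can sit at the head of an sklearn pipeline feeding the
    connectivity feature extractor.

    Parameters
    ----------
    do_nuisance, do_bandpass, do_zscore : bool
        Which stages to run. Defaults all on; z-scoring last makes model
        coefficients comparable across subjects.
    f_lo, f_hi : float
        Band edges in Hz (defaults 0.009 and 0.08).
    """

    def __init__(
        self,
        do_nuisance: bool = True,
        do_bandpass: bool = True,
        do_zscore: bool = True,
        f_lo: float = DEFAULT_F_LO,
        f_hi: float = DEFAULT_F_HI,
    ):
        self.do_nuisance = do_nuisance
        self.do_bandpass = do_bandpass
        self.do_zscore = do_zscore
        self.f_lo = f_lo
        self.f_hi = f_hi

    def fit(self, X: TimeSeriesPanel, y=None):
        if not isinstance(X, TimeSeriesPanel):
            raise TypeError("TimeSeriesPreprocessor expects a TimeSeriesPanel")
        self.n_features_in_ = X.subjects[0].n_regions
        return self

    def transform(self, X: TimeSeriesPanel) -> TimeSeriesPanel:
        subjects = [
            preprocess_subject(
                s,
                do_nuisance=self.do_nuisance,
                do_bandpass=self.do_bandpass,
                do_zscore=self.do_zscore,
                f_lo=self.f_lo,
                f_hi=self.f_hi,
            )
            for s in X.subjects
        ]
        return TimeSeriesPanel(subjects=subjects, labels=X.labels)
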