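"""Core containers for per-subject region time series and cohorts.

A subject is a (T time points x k regions) real matrix sampled at a fixed
repetition interval (TR, seconds). A cohort is an ordered collection of
subjects, all sharing the same regions, plus a binary group label per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Region labels used when simulating the default 9-node arousal-regulation /
#: executive-control network (bilateral amygdala, bilateral lateral PFC,
#: bilateral parietal, anterior/posterior cingulate, medial PFC).
DEFAULT_9ROI_NAMES = [
    "L_Amygdala",
    "R_Amygdala",
    "L_PFC",
    "R_PFC",
    "L_Parietal",
    "R_Parietal",
    "ACC",
    "PCC",
    "MPFC",
]


def default_region_names(k: int) -> list[str]:
    if k == len(DEFAULT_9ROI_NAMES):
        return list(DEFAULT_9ROI_NAMES)
    return [f"R{i + 1}" for i in range(k)]


@dataclass
class SubjectTimeSeries:
    """One subject's multivariate region time series.

    Parameters
    ----------
    data : ndarray of shape (T, k)
        One column per region, one row per time point. T >= 2, k >= 2,
        no missing values.
    sampling_interval : float
        Repetition time (TR) in seconds.
    region_names : list of str, optional
        Column labels; defaults to R1..Rk (or the canonical 9-ROI names).
    subject_id : str
    confounds : ndarray of shape (T, m), optional
        Nuisance series (e.g. white-matter and CSF averages) aligned with
        ``data``; consumed by :func:`cpgc.preprocess.nuisance_regress`.
    """

    data: np.ndarray
    sampling_interval: float = 2.0
    region_names: list[str] | None = None
    subject_id: str = ""
    confounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x region) matrix")
        t, k = self.data.shape
        if t < 2 or k < 2:
            raise ValueError(f"need T >= 2 and k >= 2 regions, got T={t}, k={k}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite values in time series")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive seconds")
        if self.region_names is None:
            self.region_names = default_region_names(k)
        else:
            self.region_names = [str(r) for r in self.region_names]
        if len(self.region_names) != k:
            raise ValueError(
                f"{len(self.region_names)} region names for {k} data columns"
            )
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.ndim == 1:
                self.confounds = self.confounds[:, None]
            if self.confounds.shape[0] != t:
                raise ValueError(
                    f"confounds have {self.confounds.shape[0]} rows, expected T={t}"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "SubjectTimeSeries":
        """Copy of this subject with replaced data (shape preserved)."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class TimeSeriesPanel:
    """Cohort of subjects sharing region set and ordering, with binary labels."""

    subjects: list[SubjectTimeSeries]
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.subjects) == 0:
            raise ValueError("empty cohort")
        if self.labels.size != len(self.subjects):
            raise ValueError("one label per subject required")
        uniq = np.unique(self.labels)
        if uniq.size > 2 or not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"labels must be binary 0/1, got classes {uniq.tolist()}")
        names = self.subjects[0].region_names
        for s in self.subjects[1:]:
            if s.region_names != names:
                raise ValueError(
                    f"subject {s.subject_id!r} region names differ from cohort"
                )

    @property
    def region_names(self) -> list[str]:
        return self.subjects[0].region_names

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)
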