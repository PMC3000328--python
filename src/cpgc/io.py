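"""Cohort readers and writers.

The interchange dialect is CSV with a header row: per-subject time series
(columns = regions, rows = time points), optional parallel confound files,
and a cohort manifest with columns ``subject_id``, ``time_series_path``,
``label`` and optional ``confounds_path``. Structured results are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import SubjectTimeSeries, TimeSeriesPanel
from .synthetic import CohortSpec

MANIFEST_COLUMNS = ("subject_id", "time_series_path", "label")


def write_subject_csv(ts: SubjectTimeSeries, path) -> None:
    pd.DataFrame(ts.data, columns=ts.region_names).to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # round-trip float parsing so write -> read preserves values exactly
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_subject_csv(
    path, subject_id: str = "", sampling_interval: float = 2.0, confounds_path=None
) -> SubjectTimeSeries:
    df = read_table(path)
    confounds = None
    if confounds_path is not None and str(confounds_path) not in ("", "nan"):
        confounds = read_table(confounds_path).to_numpy(dtype=float)
    return SubjectTimeSeries(
        data=df.to_numpy(dtype=float),
        sampling_interval=sampling_interval,
        region_names=[str(c) for c in df.columns],
        subject_id=subject_id or Path(path).stem,
        confounds=confounds,
    )


def read_cohort(manifest_path, sampling_interval: float = 2.0) -> tuple[TimeSeriesPanel, np.ndarray]:
    """Load a cohort from a manifest CSV; validates shapes, labels and paths.

    Labels may be any two distinct values; they are mapped to 0/1 by sorted
    order. Errors name the offending manifest row / subject.
    """
    manifest_path = Path(manifest_path)
    mf = read_table(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in mf.columns]
    if missing:
        raise ValueError(f"manifest lacks required column(s): {missing}")
    if mf["subject_id"].duplicated().any():
        dup = mf.loc[mf["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id(s) in manifest: {dup}")
    classes = sorted(mf["label"].unique().tolist())
    if len(classes) > 2:
        raise ValueError(f"labels must be binary; manifest has classes {classes}")
    base = manifest_path.parent
    subjects, labels = [], []
    for row in mf.itertuples(index=False):
        sid = str(row.subject_id)
        ts_path = Path(row.time_series_path)
        if not ts_path.is_absolute():
            ts_path = base / ts_path
        if not ts_path.exists():
            raise FileNotFoundError(f"subject {sid!r}: missing time series file {ts_path}")
        conf = getattr(row, "confounds_path", None)
        conf_path = None
        if conf is not None and not (isinstance(conf, float) and np.isnan(conf)) and str(conf):
            conf_path = Path(str(conf))
            if not conf_path.is_absolute():
                conf_path = base / conf_path
            if not conf_path.exists():
                raise FileNotFoundError(f"subject {sid!r}: missing confounds file {conf_path}")
        try:
            subjects.append(
                read_subject_csv(
                    ts_path,
                    subject_id=sid,
                    sampling_interval=sampling_interval,
                    confounds_path=conf_path,
                )
            )
        except ValueError as exc:
            raise ValueError(f"subject {sid!r}: {exc}") from exc
        labels.append(classes.index(row.label))
    labels = np.asarray(labels, dtype=int)
    try:
        panel = TimeSeriesPanel(subjects=subjects, labels=labels)
    except ValueError as exc:
        raise ValueError(f"manifest {manifest_path.name}: {exc}") from exc
    return panel, labels


def write_cohort(
    panel: TimeSeriesPanel,
    outdir,
    spec: CohortSpec | None = None,
) -> Path:
    """Write per-subject CSVs plus a manifest; optionally a ground-truth JSON
    naming the planted paths. Returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, label in zip(panel.subjects, panel.labels):
        fname = f"{ts.subject_id}.csv"
        write_subject_csv(ts, outdir / fname)
        rows.append({"subject_id": ts.subject_id, "time_series_path": fname, "label": int(label)})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if spec is not None:
        truth = {
            "seed": spec.seed,
            "k": spec.k,
            "T": spec.T,
            "order": spec.order,
            "n_a": spec.n_a,
            "n_b": spec.n_b,
            "planted_paths": [
                {"feature": name, "target": tgt, "source": src, "lag": lag}
                for name, (tgt, src, lag) in zip(
                    spec.planted_feature_names(), spec.planted_paths
                )
            ],
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)
    return manifest


def write_connectivity_csv(matrix: np.ndarray, region_names: list[str], path) -> None:
    pd.DataFrame(matrix, index=region_names, columns=region_names).to_csv(path)
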