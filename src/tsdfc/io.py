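"""Reading and writing subject time series, manifests and labelled matrices.

Time series are delimited text (TSV/CSV), one file per subject, with an
optional header row of ROI names.  Internally everything is stored
time-by-ROI: ``data[t, r]`` is the BOLD value of ROI ``r`` at scan ``t``.
Square inputs are ambiguous, so the orientation is always an explicit
argument — it is never guessed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiTimeSeries",
    "CohortManifest",
    "ManifestEntry",
    "read_timeseries",
    "write_timeseries",
    "zscore_rois",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "write_manifest",
]


@dataclass(frozen=True)
class RoiTimeSeries:
    """One subject's BOLD time series: ``M`` time points by ``N`` ROIs."""

    subject_id: str
    data: np.ndarray  # (M, N), float
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        if data.ndim != 2:
            raise ValueError("time series data must be a 2-D matrix")
        m, n = data.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 time points and 2 ROIs, got {m}x{n}")
        if not np.all(np.isfinite(data)):
            t, r = np.argwhere(~np.isfinite(data))[0]
            raise ValueError(
                f"non-finite value at time point {t + 1}, ROI {r + 1} "
                f"of subject {self.subject_id!r}"
            )
        if len(self.roi_names) != n:
            raise ValueError(
                f"{len(self.roi_names)} ROI names for {n} data columns"
            )
        if len(set(self.roi_names)) != n:
            raise ValueError("ROI names must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    path: str
    label: int  # +1 (patient) or -1 (control)


@dataclass(frozen=True)
class CohortManifest:
    """Ordered cohort listing; subject order here fixes stacking order downstream."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        ids = [e.subject_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in manifest")
        for e in self.entries:
            if e.label not in (+1, -1):
                raise ValueError(
                    f"label of {e.subject_id!r} must be +1 or -1, got {e.label}"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [e.subject_id for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e.label for e in self.entries], dtype=int)

    def require_both_classes(self) -> None:
        labels = set(e.label for e in self.entries)
        if labels != {+1, -1}:
            raise ValueError(
                "classification requires both +1 and -1 labels in the manifest"
            )

    def __len__(self) -> int:
        return len(self.entries)


def _auto_roi_names(n: int) -> tuple[str, ...]:
    return tuple(f"ROI_{i + 1}" for i in range(n))


def read_timeseries(
    path: str | Path,
    orientation: str = "time_by_roi",
    subject_id: str | None = None,
) -> RoiTimeSeries:
    """Read one subject's delimited time-series file.

    Parameters
    ----------
    path
        TSV or CSV file.  An optional first row of non-numeric ROI names is
        treated as a header.
    orientation
        ``"time_by_roi"`` (rows are scans) or ``"roi_by_time"`` (rows are
        ROIs; the matrix is transposed on read).  There is no auto-detection.
    subject_id
        Defaults to the file stem.
    """
    if orientation not in ("time_by_roi", "roi_by_time"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for raw in csv.reader(fh, delimiter=delim):
            cells = [c.strip() for c in raw]
            if cells and any(cells):
                rows.append(cells)
    if not rows:
        raise ValueError(f"{path}: empty file")

    def is_number(s: str) -> bool:
        try:
            v = float(s)
        except ValueError:
            return False
        return np.isfinite(v)

    header: list[str] | None = None
    if not all(is_number(c) for c in rows[0]):
        header = rows[0]
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: header but no data rows")

    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(
                f"{path}: ragged row {i + 1 + (header is not None)} "
                f"({len(r)} cells, expected {width})"
            )
    body = np.empty((len(rows), width), dtype=float)
    for i, r in enumerate(rows):
        for j, c in enumerate(r):
            try:
                v = float(c)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {c!r} at row {i + 1}, column {j + 1}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite cell {c!r} at row {i + 1}, column {j + 1}"
                )
            body[i, j] = v

    if orientation == "roi_by_time":
        body = body.T
    n = body.shape[1]
    if header is not None:
        if len(header) != n and orientation == "time_by_roi":
            raise ValueError(f"{path}: header has {len(header)} names for {n} columns")
        names = tuple(header[:n]) if len(header) >= n else _auto_roi_names(n)
    else:
        names = _auto_roi_names(n)
    return RoiTimeSeries(
        subject_id=subject_id or path.stem, data=body, roi_names=names
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.DataFrame(ts.data, columns=list(ts.roi_names))
    df.to_csv(path, sep=delim, index=False, float_format="%.17g")


def zscore_rois(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each ROI column to mean 0, sample SD 1 (ddof=1).

    Pearson correlation is invariant to the ddof convention, so the choice
    is cosmetic; sample SD is used throughout.  A constant column is a dead
    regressor and raises.
    """
    data = ts.data
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ValueError(
            f"ROI {ts.roi_names[flat[0]]!r} of subject {ts.subject_id!r} "
            "is constant over time (zero variance)"
        )
    return RoiTimeSeries(
        subject_id=ts.subject_id, data=(data - mu) / sd, roi_names=ts.roi_names
    )


def write_matrix(
    matrix: np.ndarray,
    path: str | Path,
    labels: Sequence[str] | None = None,
    require_symmetric: bool = False,
) -> None:
    """Serialize a labelled square matrix as delimited text (lossless to 1e-12)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if require_symmetric:
        if matrix.shape[0] != matrix.shape[1] or not np.allclose(
            matrix, matrix.T, atol=1e-10
        ):
            raise ValueError("matrix is not symmetric")
    if labels is None:
        labels = [f"V{i + 1}" for i in range(matrix.shape[1])]
    if len(labels) != matrix.shape[1]:
        raise ValueError("label count does not match matrix width")
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    index = list(labels) if matrix.shape[0] == matrix.shape[1] else None
    df = pd.DataFrame(matrix, columns=list(labels), index=index)
    df.to_csv(path, sep=delim, index=index is not None, float_format="%.17g")


def read_matrix(
    path: str | Path,
    require_symmetric: bool = False,
) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    delim = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=delim, index_col=0)
    labels = [str(c) for c in df.columns]
    values = df.to_numpy(dtype=float)
    if require_symmetric:
        row_labels = [str(i) for i in df.index]
        if row_labels != labels:
            raise ValueError(f"{path}: row labels do not match column labels")
        if not np.allclose(values, values.T, atol=1e-10):
            raise ValueError(f"{path}: matrix is not symmetric")
    return values, labels


def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV with columns subject_id, path, label."""
    df = pd.read_csv(path)
    required = {"subject_id", "path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    entries = [
        ManifestEntry(str(r.subject_id), str(r.path), int(r.label))
        for r in df.itertuples(index=False)
    ]
    return CohortManifest(entries=tuple(entries))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        [(e.subject_id, e.path, e.label) for e in manifest.entries],
        columns=["subject_id", "path", "label"],
    ).to_csv(path, index=False)


def load_cohort(
    manifest: CohortManifest,
    base_dir: str | Path | None = None,
    orientation: str = "time_by_roi",
    normalize: bool = True,
) -> list[RoiTimeSeries]:
    """Load every subject listed in a manifest, in manifest order."""
    out = []
    for e in manifest.entries:
        p = Path(e.path)
        if base_dir is not None and not p.is_absolute():
            p = Path(base_dir) / p
        ts = read_timeseries(p, orientation=orientation, subject_id=e.subject_id)
        out.append(zscore_rois(ts) if normalize else ts)
    return out
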