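"""Low-order functional connectivity: static and sliding-window networks.

The static network is the Pearson correlation matrix of the full ROI time
series.  The dynamic network (DFCN) is the ordered stack of correlation
matrices computed over overlapping sliding windows of length ``L`` advanced
by step ``delta``; with ``delta = 1`` a series of ``M`` scans yields
``K = M - L + 1`` windows.  The static network is the ``L = M`` limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import RoiTimeSeries

__all__ = [
    "ConnMatrix",
    "WindowSpec",
    "DfcnStack",
    "pearson_matrix",
    "window_count",
    "sliding_windows",
    "window_starts",
    "build_dfcn",
    "static_network",
]


@dataclass(frozen=True)
class ConnMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray  # (N, N)
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_names", tuple(self.roi_names))
        n = v.shape[0]
        if v.ndim != 2 or v.shape[1] != n:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("diagonal must be exactly 1")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: length ``L``, step ``delta``, derived count ``K``.

    ``K`` counts the windows actually enumerated: start positions
    ``1, 1 + delta, ...`` (1-based) whose window fits inside the series, i.e.
    ``K = floor((M - L) / delta) + 1``.  See :func:`window_count` for the
    published ceiling formula, which agrees whenever ``delta`` divides
    ``M - L`` (always for the default ``delta = 1``).
    """

    L: int
    M: int
    delta: int = 1

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("window length L must be at least 2")
        if self.L > self.M:
            raise ValueError(f"window length {self.L} exceeds series length {self.M}")
        if self.delta < 1:
            raise ValueError("step delta must be >= 1")

    @property
    def K(self) -> int:
        return (self.M - self.L) // self.delta + 1


@dataclass(frozen=True)
class DfcnStack:
    """Ordered sliding-window correlation matrices for one subject."""

    subject_id: str
    windows: tuple[ConnMatrix, ...]
    spec: WindowSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        if len(self.windows) != self.spec.K:
            raise ValueError(
                f"{len(self.windows)} window matrices for K={self.spec.K}"
            )

    @property
    def K(self) -> int:
        return len(self.windows)

    @property
    def n_rois(self) -> int:
        return self.windows[0].n_rois

    @property
    def roi_names(self) -> tuple[str, ...]:
        return self.windows[0].roi_names

    def as_array(self) -> np.ndarray:
        """Stack as a (K, N, N) array."""
        return np.stack([w.values for w in self.windows])


def pearson_matrix(
    segment: np.ndarray,
    roi_names: tuple[str, ...] | None = None,
    policy: str = "strict",
) -> ConnMatrix:
    """Pearson correlation matrix of the columns of a T-by-N segment.

    ``policy`` controls constant columns (flat signal within the window):
    ``"strict"`` raises, ``"tolerant"`` zeroes that row/column (diagonal
    stays 1) and warns.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ValueError("segment must be a T-by-N matrix with T >= 2")
    n = segment.shape[1]
    if roi_names is None:
        roi_names = tuple(f"ROI_{i + 1}" for i in range(n))
    sd = segment.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        if policy == "strict":
            raise ValueError(
                f"column {flat[0] + 1} ({roi_names[flat[0]]!r}) is constant "
                "within the window"
            )
        if policy != "tolerant":
            raise ValueError(f"unknown constant-column policy {policy!r}")
        warnings.warn(
            f"{flat.size} constant column(s) in window; correlations set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = sd > 0
    w = np.zeros((n, n))
    if ok.sum() >= 2:
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(segment[:, ok], rowvar=False)
        idx = np.nonzero(ok)[0]
        w[np.ix_(idx, idx)] = sub
    elif ok.sum() == 1:
        pass  # single live column: no off-diagonal correlation defined
    w = np.clip(w, -1.0, 1.0)
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return ConnMatrix(values=w, roi_names=roi_names)


def window_count(M: int, L: int, delta: int = 1) -> int:
    """Window count by the ceiling formula ``K = ceil((M - L) / delta) + 1``.

    For ``delta = 1`` this equals the number of contiguous length-``L``
    windows, ``M - L + 1``.  For ``delta > 1`` with ``delta`` not dividing
    ``M - L`` the formula counts one window whose end would fall past the
    series; :func:`sliding_windows` enumerates only windows that fit and
    warns about the discrepancy.
    """
    if L < 1 or L > M:
        raise ValueError(f"need 1 <= L <= M, got L={L}, M={M}")
    if delta < 1:
        raise ValueError("delta must be >= 1")
    return -((M - L) // -delta) + 1  # ceil division


def window_starts(M: int, L: int, delta: int = 1) -> np.ndarray:
    """0-based start indices of all windows that fit inside the series."""
    starts = np.arange(0, M - L + 1, delta)
    if window_count(M, L, delta) != starts.size:
        warnings.warn(
            f"ceiling window-count formula gives {window_count(M, L, delta)} "
            f"windows but only {starts.size} fit (M={M}, L={L}, delta={delta}); "
            "enumerating the windows that fit",
            RuntimeWarning,
            stacklevel=2,
        )
    return starts


def sliding_windows(ts: RoiTimeSeries, spec: WindowSpec) -> list[np.ndarray]:
    """Contiguous boxcar segments (no taper), each L-by-N, ordered in time."""
    if spec.M != ts.n_timepoints:
        raise ValueError(
            f"spec is for M={spec.M} but series has {ts.n_timepoints} time points"
        )
    starts = window_starts(spec.M, spec.L, spec.delta)
    return [ts.data[s : s + spec.L] for s in starts]


def build_dfcn(
    ts: RoiTimeSeries, spec: WindowSpec, policy: str = "strict"
) -> DfcnStack:
    """Dynamic FC network: one Pearson matrix per sliding window."""
    windows = tuple(
        pearson_matrix(seg, roi_names=ts.roi_names, policy=policy)
        for seg in sliding_windows(ts, spec)
    )
    return DfcnStack(subject_id=ts.subject_id, windows=windows, spec=spec)


def static_network(ts: RoiTimeSeries, policy: str = "strict") -> ConnMatrix:
    """Static FC network: full-series Pearson matrix (the single-window limit)."""
    return pearson_matrix(ts.data, roi_names=ts.roi_names, policy=policy)
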