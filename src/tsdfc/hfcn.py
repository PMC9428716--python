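"""High-order functional connectivity via correlation of clustered FC series.

Each ROI pair traces a length-``K`` trajectory of its windowed correlation
("FC series").  The cohort's ``P = N(N-1)/2`` FC series (each concatenated
across subjects to length ``K*S``) are grouped into ``U`` clusters by
k-means; correlating cluster-mean series against each other yields a
``U``-by-``U`` high-order network whose entries couple up to four ROIs.
The network is then sparsified by keeping only the strongest fraction of
edges (proportional thresholding by absolute correlation; retained edges
keep their sign).

Cluster assignments are indexed by ROI pair, so a clustering fitted on
training subjects transfers to a held-out subject without refitting — the
basis of the leakage-free cross-validation mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .lofcn import DfcnStack, pearson_matrix

__all__ = [
    "FcSeriesClustering",
    "HfcnMatrix",
    "pair_index",
    "extract_fc_series",
    "stack_cohort",
    "cluster_fc_series",
    "subject_cluster_series",
    "build_hfcn",
    "threshold_network",
]


def pair_index(n: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j), i < j, 0-based: the canonical edge ordering.

    This ordering is part of the on-disk clustering format and of every
    P-row matrix in this module.
    """
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass(frozen=True)
class FcSeriesClustering:
    """Partition of the N(N-1)/2 FC series into U clusters with cohort means."""

    n_rois: int
    assignment: np.ndarray  # (P,), cluster id in 0..U-1 per pair
    cohort_means: np.ndarray  # (U, K*S)
    fitted_on: tuple[str, ...]  # subject ids, in stacking order

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        object.__setattr__(
            self, "cohort_means", np.asarray(self.cohort_means, dtype=float)
        )
        object.__setattr__(self, "fitted_on", tuple(self.fitted_on))
        p = self.n_rois * (self.n_rois - 1) // 2
        if a.shape != (p,):
            raise ValueError(f"assignment must have length P={p}")
        u = self.cohort_means.shape[0]
        sizes = np.bincount(a, minlength=u)
        if np.any(sizes == 0):
            raise ValueError("every cluster must contain at least one pair")

    @property
    def U(self) -> int:
        return self.cohort_means.shape[0]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.U)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pair_index(self.n_rois)


@dataclass(frozen=True)
class HfcnMatrix:
    """U-by-U high-order network, optionally proportionally thresholded."""

    values: np.ndarray
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("high-order network must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("high-order network must be symmetric")
        if not 0 < self.retained_fraction <= 1:
            raise ValueError("retained_fraction must lie in (0, 1]")

    @property
    def U(self) -> int:
        return self.values.shape[0]

    @property
    def edge_count_retained(self) -> int:
        iu = np.triu_indices(self.U, k=1)
        return int(np.count_nonzero(self.values[iu]))


def extract_fc_series(stack: DfcnStack) -> np.ndarray:
    """P-by-K matrix: row p is pair p's correlation trajectory across windows."""
    arr = stack.as_array()  # (K, N, N)
    iu = np.triu_indices(stack.n_rois, k=1)
    return arr[:, iu[0], iu[1]].T.copy()  # (P, K), pairs in lexicographic order


def stack_cohort(stacks: list[DfcnStack]) -> np.ndarray:
    """Concatenate per-subject FC series along time: P-by-(K*S), subject order kept."""
    if not stacks:
        raise ValueError("need at least one subject")
    n = stacks[0].n_rois
    k = stacks[0].K
    for s in stacks[1:]:
        if s.n_rois != n:
            raise ValueError(
                f"subject {s.subject_id!r} has N={s.n_rois}, expected {n}"
            )
        if s.K != k:
            raise ValueError(
                f"subject {s.subject_id!r} has K={s.K} windows, expected {k}"
            )
    return np.hstack([extract_fc_series(s) for s in stacks])


def cluster_fc_series(
    stacked: np.ndarray,
    U: int,
    seed: int,
    fitted_on: tuple[str, ...] = (),
    n_init: int = 10,
) -> FcSeriesClustering:
    """K-means (squared Euclidean, k-means++ init, seeded) over the P FC series.

    sklearn's k-means never returns an empty cluster — an emptied centroid is
    relocated to the point farthest from its centroid during Lloyd updates —
    so every cluster size is >= 1 by construction.
    """
    stacked = np.asarray(stacked, dtype=float)
    p = stacked.shape[0]
    if not 1 <= U <= p:
        raise ValueError(f"cluster count U={U} must be in 1..P={p}")
    n = int(round((1 + math.isqrt(1 + 8 * p)) / 2))
    if n * (n - 1) // 2 != p:
        raise ValueError(f"{p} rows is not N(N-1)/2 for any integer N")
    km = KMeans(
        n_clusters=U,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
        algorithm="lloyd",
    ).fit(stacked)
    assignment = km.labels_.astype(int)
    # exact member means (centroids can drift from them by the tol)
    means = np.vstack(
        [stacked[assignment == u].mean(axis=0) for u in range(U)]
    )
    return FcSeriesClustering(
        n_rois=n, assignment=assignment, cohort_means=means, fitted_on=fitted_on
    )


def subject_cluster_series(
    stack: DfcnStack, clustering: FcSeriesClustering
) -> np.ndarray:
    """U-by-K matrix: per cluster, the mean FC series of its member pairs
    for one subject."""
    if stack.n_rois != clustering.n_rois:
        raise ValueError(
            f"stack has N={stack.n_rois} but clustering was fit for "
            f"N={clustering.n_rois}"
        )
    series = extract_fc_series(stack)  # (P, K)
    u = clustering.U
    out = np.zeros((u, stack.K))
    counts = np.bincount(clustering.assignment, minlength=u).astype(float)
    np.add.at(out, clustering.assignment, series)
    return out / counts[:, None]


def build_hfcn(cluster_series: np.ndarray, policy: str = "strict") -> HfcnMatrix:
    """Correlation's correlation: Pearson matrix of the U cluster-mean series."""
    cluster_series = np.asarray(cluster_series, dtype=float)
    if cluster_series.shape[1] < 2:
        raise ValueError("need at least 2 windows to correlate FC series")
    conn = pearson_matrix(cluster_series.T, policy=policy)
    return HfcnMatrix(values=conn.values, retained_fraction=1.0)


def threshold_network(matrix: HfcnMatrix, rho: float) -> HfcnMatrix:
    """Keep the top ``ceil(rho * U(U-1)/2)`` edges by absolute weight.

    Retained edges keep their signed values; ties at the cutoff magnitude are
    broken in favour of the lexicographically smaller pair index, so the
    result is deterministic.  The diagonal is preserved.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"retained fraction must lie in (0, 1], got {rho}")
    u = matrix.U
    iu = np.triu_indices(u, k=1)
    vals = matrix.values[iu]
    n_edges = vals.size
    keep = math.ceil(rho * n_edges)
    # sort by |value| descending, then by pair position ascending
    order = np.lexsort((np.arange(n_edges), -np.abs(vals)))
    kept = order[:keep]
    out = np.zeros_like(matrix.values)
    out[iu[0][kept], iu[1][kept]] = vals[kept]
    out = out + out.T
    np.fill_diagonal(out, np.diag(matrix.values))
    return HfcnMatrix(values=out, retained_fraction=rho)
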