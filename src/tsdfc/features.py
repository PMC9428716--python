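"""Feature extraction: temporal variability and high-order graph topology.

Temporal variability of ROI ``i`` is one minus the mean Pearson correlation
between ROI ``i``'s connectivity profile (its row of the window matrix,
diagonal removed) across all unordered window pairs:

    V_i = 1 - mean_{k<l} corr(w_i(k), w_i(l)),   V_i in [0, 2].

V_i = 0 when the profile is perfectly stable; V_i = 2 requires perfectly
anti-correlated profiles.

From the (thresholded) high-order network we take node strength — the sum of
absolute retained edge weights per node — and the Onnela-style weighted local
clustering coefficient, computed on absolute weights rescaled by the global
maximum so all triangle products lie in [0, 1]:

    t_i = 1/2 * sum_{j,h} (w_ij w_ih w_jh)^(1/3),
    C_i = 2 t_i / (r_i (r_i - 1)),  C_i = 0 when the node has < 2 neighbours,

with r_i the number of retained neighbours.  Correlations can be negative
and a cube root of a negative product is ill-defined, hence the absolute
values; the rescaling makes C_i coincide with the binary clustering
coefficient when all retained weights are equal.

The per-subject feature vector concatenates variability (N), strength (U)
and clustering (U) in that fixed order: m = N + 2U columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hfcn import HfcnMatrix
from .lofcn import DfcnStack

__all__ = [
    "TemporalVariabilityVector",
    "FeatureTable",
    "temporal_variability",
    "node_strength",
    "local_clustering_coefficient",
    "assemble_features",
]


@dataclass(frozen=True)
class TemporalVariabilityVector:
    subject_id: str
    values: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if np.any(v < -1e-9) or np.any(v > 2 + 1e-9):
            raise ValueError("temporal variability must lie in [0, 2]")


def _profile_correlations(profiles: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of the K window profiles (rows).

    A constant profile has no defined correlation; its pairs contribute 0
    with a warning (tolerant policy).
    """
    k = profiles.shape[0]
    sd = profiles.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            "constant connectivity profile in some window; "
            "affected correlations set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    c = np.zeros((k, k))
    ok = np.nonzero(~flat)[0]
    if ok.size >= 2:
        with np.errstate(invalid="ignore"):
            c[np.ix_(ok, ok)] = np.corrcoef(profiles[ok])
    return c


def temporal_variability(stack: DfcnStack) -> TemporalVariabilityVector:
    """V_i = 1 - mean over unordered window pairs of corr(w_i(k), w_i(l))."""
    if stack.K < 2:
        raise ValueError("temporal variability needs at least 2 windows")
    arr = stack.as_array()  # (K, N, N)
    k, n, _ = arr.shape
    off = ~np.eye(n, dtype=bool)
    v = np.empty(n)
    iu = np.triu_indices(k, 1)
    for i in range(n):
        profiles = arr[:, i, :][:, off[i]]  # (K, N-1): profile per window
        c = _profile_correlations(profiles)
        v[i] = 1.0 - c[iu].mean()
    v = np.clip(v, 0.0, 2.0)
    return TemporalVariabilityVector(subject_id=stack.subject_id, values=v)


def node_strength(matrix: HfcnMatrix, signed: bool = False) -> np.ndarray:
    """Per-node sum of retained edge weights (absolute by default).

    With ``signed=True`` the raw signed weights are summed instead; isolated
    nodes score 0 either way.
    """
    w = matrix.values.copy()
    np.fill_diagonal(w, 0.0)
    if not signed:
        w = np.abs(w)
    return w.sum(axis=1)


def local_clustering_coefficient(
    matrix: HfcnMatrix, return_global: bool = False
) -> np.ndarray | tuple[np.ndarray, float]:
    """Onnela weighted local clustering coefficient per node, in [0, 1].

    Weights are |W| rescaled by the maximum absolute off-diagonal weight.
    ``return_global`` additionally returns the mean over all nodes.
    """
    w = np.abs(matrix.values.copy())
    np.fill_diagonal(w, 0.0)
    wmax = w.max()
    if wmax > 0:
        w = w / wmax
    adj = w > 0
    r = adj.sum(axis=1)  # neighbour counts
    cw = np.cbrt(w)
    # t_i = 1/2 * sum_{j,h} cw_ij cw_ih cw_jh = 1/2 * (cw^3)_ii
    t = np.diag(cw @ cw @ cw) / 2.0
    denom = r * (r - 1)
    c = np.zeros_like(t)
    mask = denom > 0
    c[mask] = 2.0 * t[mask] / denom[mask]
    c = np.clip(c, 0.0, 1.0)
    if return_global:
        return c, float(c.mean())
    return c


@dataclass(frozen=True)
class FeatureTable:
    """S-by-m feature matrix, m = N + 2U, with per-column metadata and labels."""

    matrix: np.ndarray  # (S, m)
    kinds: tuple[str, ...]  # per column: variability | strength | clustering
    indices: tuple[int, ...]  # per column: ROI or cluster index (0-based)
    labels: np.ndarray  # (S,), +1/-1
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        object.__setattr__(self, "kinds", tuple(self.kinds))
        object.__setattr__(self, "indices", tuple(self.indices))
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        if not np.all(np.isfinite(m)):
            raise ValueError("feature table contains non-finite values")
        s, cols = m.shape
        if len(self.kinds) != cols or len(self.indices) != cols:
            raise ValueError("column metadata does not match feature count")
        if self.labels.shape != (s,) or len(self.subject_ids) != s:
            raise ValueError("row metadata does not match subject count")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def assemble_features(
    variability: list[TemporalVariabilityVector],
    strength: list[np.ndarray],
    clustering: list[np.ndarray],
    labels: np.ndarray,
) -> FeatureTable:
    """Stack per-subject vectors into the fixed-order feature table.

    Column order is variability(1..N), strength(1..U), clustering(1..U);
    standardization is deliberately NOT applied here — under cross-validation
    the scaler must be fit on training rows only.
    """
    s = len(variability)
    if not (len(strength) == len(clustering) == s):
        raise ValueError("every subject needs all three feature vectors")
    if s == 0:
        raise ValueError("no subjects")
    n = variability[0].values.size
    u = np.asarray(strength[0]).size
    rows = []
    for tv, d, c in zip(variability, strength, clustering):
        d = np.asarray(d, dtype=float)
        c = np.asarray(c, dtype=float)
        if tv.values.size != n or d.size != u or c.size != u:
            raise ValueError(
                f"dimension mismatch for subject {tv.subject_id!r}: "
                f"expected N={n}, U={u}"
            )
        rows.append(np.concatenate([tv.values, d, c]))
    kinds = ("variability",) * n + ("strength",) * u + ("clustering",) * u
    indices = tuple(range(n)) + tuple(range(u)) + tuple(range(u))
    return FeatureTable(
        matrix=np.vstack(rows),
        kinds=kinds,
        indices=indices,
        labels=labels,
        subject_ids=tuple(tv.subject_id for tv in variability),
    )
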