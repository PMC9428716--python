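"""Synthetic cohorts with planted dynamic-connectivity structure.

Each subject's signal follows a hidden Markov chain over a small set of
latent correlation states: the chain dwells in a state for a geometric
number of scans (expected dwell length is the group's ``dwell`` parameter),
and at each scan the N-dimensional observation is drawn from a zero-mean
multivariate normal with the active state's correlation matrix, plus
independent Gaussian observation noise.  Group +1 ("patients") can differ
from group -1 ("controls") in two planted ways:

* ``group_edge_offset`` — an additive connectivity offset on a designated
  edge subset of every state, re-projected to a valid correlation matrix
  (eigenvalue clipping at 1e-6, then re-standardization to unit diagonal);
* a different ``dwell`` — faster or slower switching between states.

No hemodynamic convolution is applied: the downstream method consumes
windowed correlations only, and the Markov-switching covariance already
produces the window-to-window correlation changes the method targets.
Everything is reproducible from (spec, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CohortManifest, ManifestEntry, RoiTimeSeries

__all__ = [
    "CohortSpec",
    "default_states",
    "simulate_cohort",
    "simulate_subject",
]


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    n = state.shape[0]
    if state.ndim != 2 or state.shape[1] != n:
        raise ValueError("state matrix must be square")
    if not np.allclose(state, state.T, atol=1e-10):
        raise ValueError("state matrix must be symmetric")
    if not np.allclose(np.diag(state), 1.0, atol=1e-10):
        raise ValueError("state matrix must have unit diagonal")
    if np.linalg.eigvalsh(state).min() <= 0:
        raise ValueError("state matrix must be positive definite")
    return state


def _project_to_correlation(a: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Nearest-by-eigenvalue-clipping SPD repair, then unit-diagonal rescale."""
    a = (a + a.T) / 2.0
    vals, vecs = np.linalg.eigh(a)
    vals = np.clip(vals, min_eig, None)
    a = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def default_states(n: int, within: float = 0.7) -> list[np.ndarray]:
    """Two well-separated block states for an N-ROI system.

    State A correlates the first half of the ROIs with each other, state B
    the interleaved even/odd ROIs, both at strength ``within``; all other
    correlations are 0.  Both are SPD for ``within < 1``.
    """
    half = n // 2
    groups_a = [list(range(half)), list(range(half, n))]
    groups_b = [list(range(0, n, 2)), list(range(1, n, 2))]
    states = []
    for groups in (groups_a, groups_b):
        s = np.eye(n)
        for g in groups:
            for i in g:
                for j in g:
                    if i != j:
                        s[i, j] = within
        states.append(_project_to_correlation(s))
    return states


@dataclass(frozen=True)
class CohortSpec:
    """Generative settings for a two-group synthetic cohort.

    dwell
        Expected dwell length (in scans) of the latent state chain, one value
        per group ``(group +1, group -1)``; the per-scan stay probability is
        ``1 - 1/dwell``.
    group_edge_offset
        Added to the designated edges of every state for group +1 subjects,
        then the matrix is repaired to a correlation matrix.
    offset_edges
        0-based (i, j) ROI pairs receiving the offset; defaults to every pair
        within the first ``max(2, N // 3)`` ROIs.
    """

    S_per_group: int = 10
    N: int = 12
    M: int = 120
    states: tuple[np.ndarray, ...] | None = None
    dwell: tuple[float, float] = (20.0, 20.0)
    group_edge_offset: float = 0.0
    offset_edges: tuple[tuple[int, int], ...] | None = None
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.S_per_group < 4:
            raise ValueError("need at least 2 subjects per group")
        if self.N < 2 or self.M < 2:
            raise ValueError("need N >= 2 ROIs and M >= 2 time points")
        if min(self.dwell) < 1:
            raise ValueError("expected dwell must be >= 1 scan")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        states = self.states
        if states is None:
            states = tuple(default_states(self.N))
        states = tuple(_check_state(s) for s in states)
        if any(s.shape[0] != self.N for s in states):
            raise ValueError("state matrices must be N-by-N")
        object.__setattr__(self, "states", states)
        edges = self.offset_edges
        if edges is None:
            block = max(2, self.N // 3)
            edges = tuple(
                (i, j) for i in range(block) for j in range(i + 1, block)
            )
        for i, j in edges:
            if not (0 <= i < self.N and 0 <= j < self.N and i != j):
                raise ValueError(f"invalid offset edge ({i}, {j})")
        object.__setattr__(self, "offset_edges", tuple(edges))


def _group_states(spec: CohortSpec, group: int) -> list[np.ndarray]:
    """States seen by a group; group +1 gets the planted edge offset."""
    if group == -1 or spec.group_edge_offset == 0.0:
        return [s.copy() for s in spec.states]
    out = []
    for s in spec.states:
        a = s.copy()
        for i, j in spec.offset_edges:
            a[i, j] += spec.group_edge_offset
            a[j, i] = a[i, j]
        a = _project_to_correlation(a)
        if np.linalg.eigvalsh(a).min() < 1e-8:
            raise ValueError(
                "group_edge_offset destroys positive definiteness even after "
                "projection; use a smaller offset"
            )
        out.append(a)
    return out


def _state_sequence(
    n_states: int, m: int, dwell: float, rng: np.random.Generator
) -> np.ndarray:
    """First-order Markov chain with geometric dwell and symmetric switching."""
    stay = 1.0 - 1.0 / dwell
    seq = np.empty(m, dtype=int)
    seq[0] = rng.integers(n_states)
    for t in range(1, m):
        if n_states == 1 or rng.random() < stay:
            seq[t] = seq[t - 1]
        else:
            others = [s for s in range(n_states) if s != seq[t - 1]]
            seq[t] = others[rng.integers(len(others))]
    return seq


def simulate_subject(
    subject_id: str,
    states: list[np.ndarray],
    m: int,
    dwell: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> RoiTimeSeries:
    """Draw one subject: Markov state path, then per-scan Gaussian draws."""
    n = states[0].shape[0]
    chols = [np.linalg.cholesky(s) for s in states]
    seq = _state_sequence(len(states), m, dwell, rng)
    z = rng.standard_normal((m, n))
    data = np.empty((m, n))
    for t in range(m):
        data[t] = chols[seq[t]] @ z[t]
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((m, n))
    names = tuple(f"ROI_{i + 1}" for i in range(n))
    return RoiTimeSeries(subject_id=subject_id, data=data, roi_names=names)


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[RoiTimeSeries], CohortManifest]:
    """Generate the full two-group cohort, labels alternating +1/-1.

    ``seed`` overrides ``spec.seed`` when given.  Subject ids encode the
    group (``sz_*`` for +1, ``hc_*`` for -1); the manifest interleaves the
    groups so any prefix of it still contains both classes.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    states_pos = _group_states(spec, +1)
    states_neg = _group_states(spec, -1)
    series: list[RoiTimeSeries] = []
    entries: list[ManifestEntry] = []
    for k in range(spec.S_per_group):
        for group, states, dwell, tag in (
            (+1, states_pos, spec.dwell[0], "sz"),
            (-1, states_neg, spec.dwell[1], "hc"),
        ):
            sid = f"{tag}_{k + 1:03d}"
            ts = simulate_subject(sid, states, spec.M, dwell, spec.noise_sd, rng)
            series.append(ts)
            entries.append(ManifestEntry(sid, f"{sid}.tsv", group))
    return series, CohortManifest(entries=tuple(entries))
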