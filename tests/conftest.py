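import numpy as np
import pytest

from tsdfc.io import RoiTimeSeries, zscore_rois
from tsdfc.lofcn import DfcnStack, WindowSpec, build_dfcn
from tsdfc.simulate import CohortSpec, simulate_cohort


def random_timeseries(
    n: int, m: int, seed: int, subject_id: str = "subj"
) -> RoiTimeSeries:
    rng = np.random.default_rng(seed)
    return RoiTimeSeries(
        subject_id=subject_id,
        data=rng.standard_normal((m, n)),
        roi_names=tuple(f"ROI_{i + 1}" for i in range(n)),
    )


def random_stack(n: int, k: int, seed: int, L: int = 6) -> DfcnStack:
    """A valid DFCN stack with K windows, built from random data."""
    ts = random_timeseries(n, k + L - 1, seed)
    return build_dfcn(ts, WindowSpec(L=L, M=ts.n_timepoints))


@pytest.fixture(scope="session")
def strong_cohort():
    """Two groups separated by a planted connectivity offset and a
    fast-vs-slow state switching contrast (the 'strong effects' condition)."""
    spec = CohortSpec(
        S_per_group=10, N=12, M=120, dwell=(5.0, 600.0),
        group_edge_offset=0.8, noise_sd=0.05, seed=11,
    )
    series, manifest = simulate_cohort(spec)
    return [zscore_rois(t) for t in series], manifest


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small, quickly classifiable cohort for protocol-level tests."""
    spec = CohortSpec(
        S_per_group=4, N=8, M=80, dwell=(5.0, 300.0),
        group_edge_offset=0.9, noise_sd=0.02, seed=7,
        offset_edges=((0, 1), (0, 2), (1, 2)),
    )
    series, manifest = simulate_cohort(spec)
    return [zscore_rois(t) for t in series], manifest
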