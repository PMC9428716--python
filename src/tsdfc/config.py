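"""YAML pipeline configuration: paths, hyperparameter grids, seed, modes."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config"]

_DEFAULT_WINDOWS = (20, 30, 40, 50, 60, 70)
_DEFAULT_CLUSTERS = (300, 400, 500, 600, 700, 800)
_DEFAULT_RETAIN = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
_DEFAULT_LASSO = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclass(frozen=True)
class PipelineConfig:
    """Validated end-to-end run configuration.

    ``retain_fractions`` may be given in YAML as percentages (values > 1 are
    divided by 100); zero is rejected — it would retain no edges at all.
    """

    manifest: str = ""
    out_dir: str = "tsdfc_out"
    orientation: str = "time_by_roi"
    window_lengths: tuple[int, ...] = _DEFAULT_WINDOWS
    cluster_counts: tuple[int, ...] = _DEFAULT_CLUSTERS
    retain_fractions: tuple[float, ...] = _DEFAULT_RETAIN
    lasso_penalties: tuple[float, ...] = _DEFAULT_LASSO
    step: int = 1
    seed: int = 0
    pooled_clustering: bool = False
    policy: str = "tolerant"
    svm_C: float = 1.0

    def __post_init__(self) -> None:
        for name in ("window_lengths", "cluster_counts",
                     "retain_fractions", "lasso_penalties"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} grid must be non-empty")
            object.__setattr__(self, name, vals)
        rf = []
        for r in self.retain_fractions:
            r = float(r)
            if r > 1:
                r = r / 100.0
            if not 0 < r <= 1:
                raise ValueError(
                    f"retain fraction {r} invalid: must be in (0, 1] "
                    "(0 retains nothing)"
                )
            rf.append(r)
        object.__setattr__(self, "retain_fractions", tuple(rf))
        if any(l < 2 for l in self.window_lengths):
            raise ValueError("window lengths must be >= 2")
        if any(u < 1 for u in self.cluster_counts):
            raise ValueError("cluster counts must be >= 1")
        if any(lam <= 0 for lam in self.lasso_penalties):
            raise ValueError("lasso penalties must be > 0")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.policy not in ("strict", "tolerant"):
            raise ValueError("policy must be 'strict' or 'tolerant'")
        if self.orientation not in ("time_by_roi", "roi_by_time"):
            raise ValueError("orientation must be time_by_roi or roi_by_time")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for name in ("window_lengths", "cluster_counts",
                 "retain_fractions", "lasso_penalties"):
        if name in raw and isinstance(raw[name], (int, float)):
            raw[name] = [raw[name]]
    return PipelineConfig(**raw)
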