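"""Pipeline configuration: one structured file holding every tunable.

Defaults mirror the acquisition constants of the study design (50 mL/min
STP flow, 1 Hz sampling, mass exponent 0.856, RQ 1, 5-minute segments); the
resolved configuration is serialized next to every output so any artifact
can be regenerated from (inputs, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # conversion chain
    rq: float = 1.0
    mass_exponent: float = 0.856
    segment_s: int = 300
    drift_method: str = "window_means"
    # SMR estimator
    smr_window_s: int = 300
    smr_quantile: float = 0.2
    # inference
    alpha: float = 0.05
    correction_method: str = "bonferroni"
    max_lifespan_definition: str = "top_decile_mean"
    # simulation (synthetic study conditions)
    seed: int = 0
    sim_n_flies: int = 4
    sim_duration_s: int = 1800
    sim_flow_ml_min: float = 50.0
    sim_mass_mg: float = 1.2
    sim_smr_uW: float = 15.0
    sim_noise_sd_ppm: float = 0.05
    sim_couplings: dict = field(
        default_factory=lambda: {"control": 0.0, "csw_lof": 0.5}
    )
    sim_gompertz: dict = field(
        default_factory=lambda: {"control": [1.3e-3, 0.1], "csw_lof": [4.7e-4, 0.1]}
    )
    sim_cohort_n: int = 100
    sim_censor_prob: float = 0.02
    time_unit: str = "days"
    # climbing fixture
    sim_climbing_n_flies: int = 25
    sim_climbing_means: dict = field(
        default_factory=lambda: {"control": 0.6, "csw_lof": 0.6}
    )
    sim_climbing_sd: float = 0.1

    def with_overrides(self, overrides: Mapping[str, Any]) -> "PipelineConfig":
        known = {k: v for k, v in overrides.items() if v is not None and hasattr(self, k)}
        unknown = [k for k in overrides if not hasattr(self, k)]
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return replace(self, **known)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        from .io import atomic_write
        with atomic_write(path) as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls().with_overrides(data)
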