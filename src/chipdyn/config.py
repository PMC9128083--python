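"""Pipeline configuration: every stage threshold in one place.

All canonical thresholds of the analysis (caller alpha, coverage/alt/VAF call
filters, recurrent-artifact rule, CHIP and large-clone VAF cuts, trajectory
eligibility, VAF floor, classification P threshold) live here as defaults and
are never hard-coded in stage logic.  Configs serialize to YAML and round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .simulate import CohortSimConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0

    # variant_processing
    error_rate: float = 0.00045  # per-base substitution probability
    caller_alpha: float = 1e-6
    min_depth: int = 40
    min_alt: int = 5
    min_vaf: float = 0.001
    artifact_sample_fraction: float = 0.05
    artifact_vaf_window: tuple[float, float] = (0.01, 0.10)
    artifact_by_subject: bool = False

    # chip_calling
    chip_vaf: float = 0.02
    large_clone_vaf: float = 0.10
    age_bins: tuple = (50, 60, 70, 80, 100)

    # trajectory_dynamics
    traj_min_timepoints: int = 3
    traj_min_tracking_vaf: float = 0.01
    traj_min_depth: int = 200
    traj_min_alt: int = 2
    vaf_floor: float = 1e-4
    p_threshold: float = 0.5
    max_start_vaf: float = 0.10

    # simulator
    sim: CohortSimConfig = field(default_factory=CohortSimConfig)

    def validate(self) -> None:
        if not 0 < self.caller_alpha < 1:
            raise ValueError("caller_alpha must be in (0,1)")
        if not 0 < self.error_rate < 1:
            raise ValueError("error_rate must be in (0,1)")
        lo, hi = self.artifact_vaf_window
        if not 0 <= lo <= hi <= 1:
            raise ValueError("artifact_vaf_window must be an ordered pair in [0,1]")
        if self.vaf_floor <= 0:
            raise ValueError("vaf_floor must be positive")
        self.sim.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["artifact_vaf_window"] = list(self.artifact_vaf_window)
        d["age_bins"] = list(self.age_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = CohortSimConfig.from_dict(d["sim"])
        if "artifact_vaf_window" in d:
            d["artifact_vaf_window"] = tuple(d["artifact_vaf_window"])
        if "age_bins" in d:
            d["age_bins"] = tuple(d["age_bins"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
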