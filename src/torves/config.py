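"""Run configuration: a YAML-serializable tree of the pipeline parameters.

Every field has a default, every defaulted field is serialized back out
(round-trip yields an equivalent config), and unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["RunConfig", "PotentialConfig", "LangevinConfig", "VesConfig", "AnalysisConfig", "BootstrapConfig"]


def _from_dict(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            value = data[f.name]
            if f.name in _NESTED:
                value = _from_dict(_NESTED[f.name], value)
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class PotentialConfig:
    #: "four_state_test", "pr_like", "pfr_like", or "custom"
    preset: str = "four_state_test"
    #: for preset == "custom": rows (center_phi, center_psi, depth, concentration)
    wells: list = field(default_factory=list)


@dataclass
class LangevinConfig:
    temperature: float = 300.0
    diffusion: float = 0.1
    time_step: float = 0.01
    record_stride: int = 2
    n_steps: int = 200_000  # unbiased runs only; VES length is stride*iterations


@dataclass
class VesConfig:
    order: int = 10
    learning_rate: float = 0.1
    stride: int = 1000
    n_iterations: int = 3000
    #: frozen-bias production strides; the state-FE statistics are limited
    #: by independent basin visits, so production runs longer than optimisation
    production_iterations: int | None = 6000
    averaging: str = "suffix"


@dataclass
class AnalysisConfig:
    grid_bins: int = 100
    burn_in_fraction: float = 0.5
    #: weight sieve (kJ/mol above the weight maximum); must exceed the
    #: shallowest basin's free energy but stay below the barrier tops
    fe_cutoff: float = 100.0
    cluster_eps: float = 0.5
    cluster_min_members: int = 10
    merge_barrier: float = 1.25  # ~0.5 kT at 300 K
    n_checkpoints: int = 10
    convergence_window: int = 3
    slope_tol: float = 0.01
    variability_window: int = 4


@dataclass
class BootstrapConfig:
    n_boot: int = 2000
    ci_level: float = 0.95


_NESTED = {
    "potential_a": PotentialConfig,
    "potential_b": PotentialConfig,
    "langevin": LangevinConfig,
    "ves": VesConfig,
    "analysis": AnalysisConfig,
    "bootstrap": BootstrapConfig,
}


@dataclass
class RunConfig:
    """Full pipeline configuration (two landscapes A and B)."""

    potential_a: PotentialConfig = field(default_factory=lambda: PotentialConfig("pr_like"))
    potential_b: PotentialConfig = field(default_factory=lambda: PotentialConfig("pfr_like"))
    langevin: LangevinConfig = field(default_factory=LangevinConfig)
    ves: VesConfig = field(default_factory=VesConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    seed: int = 0
    output_dir: str = "torves_out"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the full (defaults included) configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
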