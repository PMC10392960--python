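"""Run configuration for the pipeline CLI.

All defaults match the method's standard choices: significance cutoff
p = 1/20, 100 shuffles, 100 tessellation realizations, data-fraction
threshold Phi* = 3/4. Everything is overridable from a YAML file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    # paths
    events_csv: str | None = None
    region_geojson: str | None = None
    output_dir: str = "runs/out"
    # scales
    a_days: float = 64.0
    b_km: float = 100.0
    a_list: list[float] = field(default_factory=lambda: [float(2**k) for k in range(10)])
    b_list: list[float] = field(default_factory=lambda: [10.0 * 10 ** (k / 3) for k in range(7)])
    # significance
    p_cut: float = 1 / 20
    n_shuffles: int = 100
    # ensemble
    n_realizations: int = 100
    master_seed: int = 0
    # mesoscale
    phi_star: float = 3 / 4
    contour_levels: list[float] = field(default_factory=lambda: [0.5, 0.9])
    # synthetic generator
    horizon_days: float = 1460.0
    background_rate: float = 2e-7
    branching_ratio: float = 0.8
    sigma_space_km: float = 40.0
    sigma_time_days: float = 15.0
    actor_rule: str = "cluster"
    # scaling
    n_bootstrap: int = 1000
    n_gof: int = 100
    # interaction zones
    levels: list[float] = field(default_factory=lambda: [0.1, 0.5, 0.9])
    reference_event: str | None = None
    core_quantile: float = 1.0
    # events filtering
    type_filter: str | None = None
    precision_caps: list[int] | None = None

    def validate(self) -> None:
        problems = []
        if not (0 < self.p_cut <= 1):
            problems.append(f"p_cut must be in (0, 1], got {self.p_cut}")
        for name in ("a_days", "b_km", "horizon_days", "sigma_space_km",
                     "sigma_time_days"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if any(v <= 0 for v in self.a_list) or any(v <= 0 for v in self.b_list):
            problems.append("all scan scales must be positive")
        if not isinstance(self.master_seed, int):
            problems.append("master_seed must be an integer")
        if self.n_realizations < 1:
            problems.append("n_realizations must be >= 1")
        if not (0 <= self.branching_ratio < 1):
            problems.append("branching_ratio must be in [0, 1)")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        cfg.validate()
        return cfg
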