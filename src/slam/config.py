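"""Run configuration: one dataclass holding every tunable, with YAML I/O and
field validation. All thresholds default to the published operating point."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class SlamConfig:
    # neighborhood construction
    k: int = 7                        # atoms per linear sequence (7–11)
    # substitution scoring
    gap_open: float = -4.0
    gap_extend: float = -1.0
    chem_weight: float = 1.0
    contact_tolerance: float = 0.0    # Å beyond vdW radius sum
    # evidence accumulation
    quality_gate_fraction: float = 0.9  # of the smaller self-alignment score
    include_center_pair: bool = True
    # candidate-pair selection
    candidate_policy: str = "robust"  # robust | mean_sd | quantile | fixed
    candidate_c: float = 2.0
    candidate_quantile: float = 0.05
    candidate_fixed: float | None = None
    # clustering
    r_min: float = 0.85
    min_cluster_pairs: int = 4
    bootstrap_distance_tol: float = 1.0  # Å, for the first singleton merges
    cluster_seed_limit: int = 50        # candidate pairs tried as cluster seeds
    expansion_pool_limit: int = 500     # evidence pairs available for accretion
    # extraction
    cavity_radius: float = 7.0
    cavity_min_atoms: int = 40
    sasa_probe: float = 1.4
    sasa_points: int = 960
    sasa_min_area: float = 2.0
    # scoring thresholds
    ncorr5_min: float = 25.0          # 30 stringent, 35 surface screens
    fe_threshold: float = -1.5
    # docking
    engine: str = "stub"              # stub | vina
    shift_mode: str = "rmsd"          # rmsd | centroid
    # orchestration
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 7 <= self.k <= 11:
            raise ConfigError(f"k: must be in [7, 11], got {self.k}")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ConfigError("gap_open/gap_extend: penalties must be ≤ 0")
        if not 0 < self.quality_gate_fraction <= 1:
            raise ConfigError("quality_gate_fraction: must be in (0, 1]")
        if self.candidate_policy not in {"robust", "mean_sd", "quantile", "fixed"}:
            raise ConfigError(f"candidate_policy: unknown {self.candidate_policy!r}")
        if self.candidate_policy == "fixed" and self.candidate_fixed is None:
            raise ConfigError("candidate_fixed: required for the fixed policy")
        if not -1.0 <= self.r_min <= 1.0:
            raise ConfigError("r_min: must be in [-1, 1]")
        if self.min_cluster_pairs < 4:
            raise ConfigError("min_cluster_pairs: must be ≥ 4 (r needs ≥ 3 pairs)")
        if self.engine not in {"stub", "vina"}:
            raise ConfigError(f"engine: unknown {self.engine!r}")
        if self.shift_mode not in {"rmsd", "centroid"}:
            raise ConfigError(f"shift_mode: unknown {self.shift_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SlamConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SlamConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
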