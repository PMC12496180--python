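"""Pipeline configuration with defaults matching the published analysis."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All thresholds and toggles, round-trippable through YAML."""

    # stage toggles
    run_variants: bool = True
    run_conservation: bool = True
    run_trajectories: bool = True
    run_compare: bool = True
    run_pca: bool = True
    run_scan: bool = True

    # statistics
    alpha: float = 0.05
    bh_correction: bool = True
    resolution: float = 2.5  # Å, starting-model resolution filter
    window: int = 3
    step: int = 1
    burn_in_ns: float = 400.0

    # conservation
    conservation_tau: float = 0.70
    dops_diversity_cut: float = 0.80
    identity_threshold: float = 0.70
    length_max_rel_diff: float = 0.2

    # scan
    scan_window: int = 3
    delta_flag: float = -0.3

    seed: int = 0
    outdir: str = "indelflex_out"

    # synthetic demo sizing (frames kept modest so the demo runs in minutes)
    demo_n_residues: int = 40
    demo_n_frames: int = 400
    demo_n_replicates: int = 3
    demo_systems: tuple = ("wt", "del", "wtg", "delg")
    demo_deleted_residues: tuple = (153, 154, 155)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.window < 1 or self.step < 1:
            raise ValueError("window and step must be >= 1")
        if self.burn_in_ns < 0:
            raise ValueError("burn_in_ns must be non-negative")
        if not 0 <= self.conservation_tau <= 1:
            raise ValueError("conservation_tau must lie in [0, 1]")
        if not 0 <= self.identity_threshold <= 1:
            raise ValueError("identity_threshold must lie in [0, 1]")
        if self.length_max_rel_diff < 0:
            raise ValueError("length_max_rel_diff must be non-negative")
        if self.scan_window < 1:
            raise ValueError("scan_window must be >= 1")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["demo_systems"] = list(self.demo_systems)
        d["demo_deleted_residues"] = list(self.demo_deleted_residues)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        if "demo_systems" in data:
            data["demo_systems"] = tuple(data["demo_systems"])
        if "demo_deleted_residues" in data:
            data["demo_deleted_residues"] = tuple(data["demo_deleted_residues"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Hash of the analytic parameters (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        d["demo_systems"] = list(self.demo_systems)
        d["demo_deleted_residues"] = list(self.demo_deleted_residues)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
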