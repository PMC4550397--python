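"""Run configuration: one serializable object holding every threshold and
convention the pipeline uses, so outputs are self-describing."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline settings.

    Thresholds have the study defaults: within-run significance alpha
    0.05; chamber-locked artifact screen at >= 180 deg rotation and
    r_chamber - r_card > 0.17; QC rejection above 3 nearby vessels;
    across-run inclusion at >= 30 individuals per species. Convention flags
    (mirror, compose, wind_toward) record the sign conventions used and are
    echoed into every output table.
    """

    tracks: str = "tracks.csv"
    deployments: str = "deployments.csv"
    coastline: str = "coastline.csv"
    outdir: str = "out"
    alpha: float = 0.05
    rotation_min: float = 180.0
    delta_threshold: float = 0.17
    max_vessels: int = 3
    min_n: int = 30
    basis: str = "tested"  # inclusion-count basis: tested | directional
    mirror: bool = True
    compose: str = "add"  # chamber angle +/- image-top heading
    wind_toward: bool = False  # station "from" convention by default
    sunrise_zenith: float = 90.833  # apparent; 90.0 for geometric
    acclimation_s: float = 0.0
    rayleigh_method: str = "analytic"
    center_x: float = 1296.0
    center_y: float = 972.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.delta_threshold < 0 or self.rotation_min < 0:
            raise ValueError("artifact thresholds must be non-negative")
        if self.min_n < 1 or self.max_vessels < 0:
            raise ValueError("min_n must be >= 1 and max_vessels >= 0")
        if self.compose not in ("add", "subtract"):
            raise ValueError("compose must be 'add' or 'subtract'")
        if self.basis not in ("tested", "directional"):
            raise ValueError("basis must be 'tested' or 'directional'")
        if self.rayleigh_method not in ("analytic", "permutation"):
            raise ValueError("rayleigh_method must be 'analytic' or 'permutation'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def convention_flags(self) -> dict:
        """The sign/convention settings stamped onto output tables."""
        return {
            "mirror": self.mirror,
            "compose": self.compose,
            "wind_toward": self.wind_toward,
            "sunrise_zenith": self.sunrise_zenith,
            "rayleigh_method": self.rayleigh_method,
        }
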