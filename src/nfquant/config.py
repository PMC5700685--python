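"""Run configuration: every tunable parameter of every stage, with
documented defaults, lossless TOML round-trip, and a dict form that is
embedded verbatim into every run's output for provenance."""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path
from typing import Any


@dataclasses.dataclass
class TissueParams:
    downscale_factor: float = 0.125  # working resolution = 12.5% of full
    homogeneity_sd: float = 5.0  # quadtree split criterion, 8-bit brightness SD
    min_block_side: int = 4  # px at working resolution
    enclosed_max_fraction: float = 0.001  # enclosed-speck absorption limit
    grow_iterations: int = 3
    grow_radius: int = 2
    white_cutoff: float = 250.0  # near-white exclusion inside tissue


@dataclasses.dataclass
class DetectionParams:
    blue_threshold: str | float = "auto"  # "auto" = guarded Otsu
    min_class_separation: float = 50.0
    expand_radius: int = 2
    rb_diff_threshold: float = 30.0
    close_radius: int = 1
    open_radius: int = 1
    merge_gap: float = 3.0  # px, neighbourhood merge criterion
    min_size: int = 4  # px^2
    max_size: int = 5000  # px^2


@dataclasses.dataclass
class StatsParams:
    alpha: float = 0.05
    adjust: str = "bonferroni"  # or "holm"
    reference_roi: int = 1


@dataclasses.dataclass
class SimulationParams:
    profile: str = "paper2017"
    width: int = 1024
    height: int = 768


@dataclasses.dataclass
class RunConfig:
    tissue: TissueParams = dataclasses.field(default_factory=TissueParams)
    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    stats: StatsParams = dataclasses.field(default_factory=StatsParams)
    simulation: SimulationParams = dataclasses.field(default_factory=SimulationParams)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        return cls(
            tissue=TissueParams(**d.get("tissue", {})),
            detection=DetectionParams(**d.get("detection", {})),
            stats=StatsParams(**d.get("stats", {})),
            simulation=SimulationParams(**d.get("simulation", {})),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def dump(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(dumps_toml(self.to_dict()))
        return path


def _toml_value(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def dumps_toml(d: dict[str, dict[str, Any]]) -> str:
    """Serialize a two-level dict of scalars as TOML (all this config needs)."""
    lines: list[str] = []
    for section, values in d.items():
        lines.append(f"[{section}]")
        for key, val in values.items():
            lines.append(f"{key} = {_toml_value(val)}")
        lines.append("")
    return "\n".join(lines)
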