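"""Pipeline configuration: every cutoff the analysis uses, in one place.

Defaults are the headline analysis settings: TSS >= 0.5 model filter,
30%-of-area protection cutoff, 20%/90% gap-class boundaries, 0.1/0.4 HMI
class boundaries, CSH > 0.8 great-expansion threshold, 200 km buffer,
20-occurrence floor, top 30%/50% priority fractions and +15%/+35% PA
expansion fractions. Unknown keys are rejected up front.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import SimulationConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    outdir: str = "phyloprior_out"
    seed: int = 0

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    # suitability modelling
    n_repeats: int = 10
    train_frac: float = 0.8
    tss_min: float = 0.5
    absence_ratio: float = 1.0
    buffer_km: float = 200.0
    min_occ: int = 20
    dispersal: str = "full"

    # prioritization
    rule: str = "caz"
    top_fractions: tuple[float, ...] = (0.3, 0.5)

    # assessment
    pa_cutoff: float = 0.3
    gap_bounds: tuple[float, float] = (0.2, 0.9)
    hmi_bounds: tuple[float, float] = (0.1, 0.4)
    csh_expand: float = 0.8
    add_fractions: tuple[float, ...] = (0.15, 0.35)
    target_lower_km2: float = 1_000.0
    target_upper_km2: float = 250_000.0
    target_floor: float = 0.1
    aoa_quantile: float = 0.95

    def __post_init__(self) -> None:
        if self.rule not in ("caz", "abf"):
            raise ValueError("rule must be 'caz' or 'abf'")
        if self.dispersal not in ("full", "limited", "none"):
            raise ValueError("dispersal must be full, limited or none")
        # a single top-level seed drives every stage
        self.simulation.seed = self.seed

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("simulation", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
        for key in ("top_fractions", "add_fractions", "gap_bounds", "hmi_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        if "climate_shift" in sim_data and isinstance(sim_data["climate_shift"], list):
            sim_data["climate_shift"] = tuple(sim_data["climate_shift"])
        return cls(simulation=SimulationConfig(**sim_data), **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("top_fractions", "add_fractions", "gap_bounds", "hmi_bounds"):
            d[key] = list(d[key])
        if isinstance(d["simulation"].get("climate_shift"), tuple):
            d["simulation"]["climate_shift"] = list(d["simulation"]["climate_shift"])
        return d


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)
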