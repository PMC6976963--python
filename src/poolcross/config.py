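"""Pipeline configuration: every stage's thresholds with their defaults,
serialized losslessly to a flat YAML document."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .cnv import CnvFilterSpec, RegionQcSpec
from .freq import VariantQcSpec
from .fst import ScanConfig
from .scenarios import ScenarioSpec
from .simulate import SimConfig


@dataclass
class PipelineConfig:
    """All tunable thresholds and settings of the pipeline.

    Nested sections mirror the stages; the YAML file is flat within each
    section. Defaults are the published values of each decision rule.
    """

    seed: int = 0
    q_threshold: float = 0.05
    region_window: int = 50_000
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    region_qc: RegionQcSpec = field(default_factory=RegionQcSpec)
    cnv_filter: CnvFilterSpec = field(default_factory=CnvFilterSpec)
    variant_qc: VariantQcSpec = field(default_factory=VariantQcSpec)
    scan: ScanConfig = field(default_factory=lambda: ScanConfig.desk())

    def __post_init__(self) -> None:
        if self.q_threshold <= 0 or self.region_window <= 0:
            raise ValueError("q_threshold and region_window must be positive")

    def with_seed(self, seed: int) -> "PipelineConfig":
        cfg = PipelineConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.sim.seed = seed
        cfg.scan.seed = seed
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sections = {
            "scenario": ScenarioSpec,
            "sim": SimConfig,
            "region_qc": RegionQcSpec,
            "cnv_filter": CnvFilterSpec,
            "variant_qc": VariantQcSpec,
            "scan": ScanConfig,
        }
        kwargs = {}
        for name, typ in sections.items():
            if name in data:
                kwargs[name] = typ(**data.pop(name))
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**kwargs, **data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
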