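"""Run configuration: every tunable of the pipeline in one schema-validated
namespace, round-tripping losslessly through YAML.

The ``simulate`` block mirrors :class:`ltrscout.simulate.SimulationConfig`;
everything else is flat. Unknown keys are rejected, listing the offenders.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any, Dict

import yaml

from .ltr_detect import DetectionParams
from .simulate import SimulationConfig
from .struct_annot import AnnotationParams


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Defaults for every stage; CLI flags override file values."""

    seed: int = 1
    log_level: str = "INFO"

    # ltr_detect
    min_len: int = 100
    max_len: int = 5000
    min_similarity: float = 0.80
    min_element_len: int = 1000
    max_element_len: int = 25000
    seed_k: int = 20

    # struct_annot
    tsd_len: int = 5
    tsd_min_homology: float = 0.60
    pbs_min: int = 8
    pbs_max: int = 40
    pbs_max_offset: int = 10
    pbs_min_complementarity: float = 0.90
    ppt_min: int = 8
    ppt_max: int = 40
    ppt_min_purine: float = 0.94
    ppt_window: int = 30
    domain_min_identity: float = 0.35
    domain_min_len: int = 50

    # age
    substitution_rate: float = 1.3e-8

    # io / aleseq
    mapq_unique: int = 10
    strong_rpm: float = 4000.0
    moderate_rpm: float = 3000.0
    min_junction: int = 50
    junction_window_up: int = 50
    junction_window_down: int = 30

    # simulator block (keys of SimulationConfig, minus the shared seed)
    simulate: Dict[str, Any] = field(default_factory=dict)

    # ------------------------------------------------------------------

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            min_len=self.min_len,
            max_len=self.max_len,
            min_similarity=self.min_similarity,
            min_element_len=self.min_element_len,
            max_element_len=self.max_element_len,
            seed_k=self.seed_k,
        )

    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(
            tsd_len=self.tsd_len,
            tsd_min_homology=self.tsd_min_homology,
            pbs_min=self.pbs_min,
            pbs_max=self.pbs_max,
            pbs_max_offset=self.pbs_max_offset,
            pbs_min_complementarity=self.pbs_min_complementarity,
            ppt_min=self.ppt_min,
            ppt_max=self.ppt_max,
            ppt_min_purine=self.ppt_min_purine,
            ppt_window=self.ppt_window,
            domain_min_identity=self.domain_min_identity,
            domain_min_len=self.domain_min_len,
            min_ltr_similarity=self.min_similarity,
        )

    def simulation_config(self) -> SimulationConfig:
        allowed = {f.name for f in fields(SimulationConfig)}
        unknown = set(self.simulate) - allowed
        if unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        # YAML lists arrive as lists; SimulationConfig wants tuples
        for key in ("chrom_lengths", "family_mix", "ltr_len_range",
                    "divergence_levels", "active_ids"):
            if key in kwargs and kwargs[key] is not None:
                val = kwargs[key]
                if key == "chrom_lengths":
                    val = tuple((str(n), int(l)) for n, l in val)
                else:
                    val = tuple(val)
                kwargs[key] = val
        return SimulationConfig(**kwargs)

    # ------------------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data)}")
        return cls.from_dict(data)

    def to_dict(self) -> Dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_overrides(self, **overrides) -> "RunConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        unknown = set(clean) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **clean)
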