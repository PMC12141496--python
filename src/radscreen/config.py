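"""Pipeline configuration: one flat YAML file drives every stage."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "load_config", "resolved_yaml", "config_hash"]

ALL_STAGES = ("simulate", "pca", "screen", "contrast", "tf", "ora")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, with study-scale defaults.

    Paths left as ``None`` fall back to simulation (counts/meta) or to
    the small synthetic network / gene-set fixtures bundled for tests.
    """

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # inputs (None -> simulate / bundled toys)
    counts_path: str | None = None
    meta_path: str | None = None
    network_path: str | None = None
    gmt_path: str | None = None
    # simulation
    n_genes: int = 2000
    # preprocessing / screening
    min_mean: float = 10.0
    pseudocount: float = 1.0
    n_top: int = 500
    screen_time_h: float = 6.0
    alpha: float = 0.05
    conf: float = 0.95
    include_between: bool = False
    # contrast
    contrast_num: tuple[float, float] = (4.0, 6.0)
    contrast_den: tuple[float, float] = (0.0, 6.0)
    moderation: str = "shrink"
    prior_df: float = 4.0
    # TF / ORA
    min_targets: int = 5
    ora_min_k: int = 1
    ora_set_size_bounds: tuple[int, int] = (5, 500)

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}; valid: {ALL_STAGES}")
        self.stages = tuple(self.stages)
        self.contrast_num = tuple(self.contrast_num)
        self.contrast_den = tuple(self.contrast_den)
        self.ora_set_size_bounds = tuple(self.ora_set_size_bounds)


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load YAML config; unknown keys are rejected, overrides win."""
    data: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return PipelineConfig(**data)


def resolved_yaml(config: PipelineConfig) -> str:
    """Canonical YAML text of the fully resolved configuration."""
    d = dataclasses.asdict(config)
    d["stages"] = list(config.stages)
    d["contrast_num"] = list(config.contrast_num)
    d["contrast_den"] = list(config.contrast_den)
    d["ora_set_size_bounds"] = list(config.ora_set_size_bounds)
    return yaml.safe_dump(d, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(resolved_yaml(config).encode()).hexdigest()[:12]
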