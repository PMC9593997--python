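"""YAML run configuration with strict key checking and echoed defaults."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .ld import DEFAULT_C, DEFAULT_M, DEFAULT_N_E
from .sim import BlockLdModel, SimulationConfig
from .train import TrainingConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PathsConfig", "AssocConfig", "LdConfig", "FilterConfig", "validate_config"]


@dataclass
class PathsConfig:
    eqtl: Optional[str] = None
    gwas: Optional[str] = None
    panel: Optional[str] = None  # PLINK prefix or VCF path
    map: Optional[str] = None
    annotation: Optional[str] = None
    tuning_expr: Optional[str] = None
    testing_expr: Optional[str] = None
    weights: Optional[str] = None
    out: str = "sumtwas_out"


@dataclass
class LdConfig:
    n_e: float = DEFAULT_N_E
    m: float = DEFAULT_M
    c: float = DEFAULT_C


@dataclass
class FilterConfig:
    window_bp: int = 1_000_000
    maf_min: float = 0.01
    hwe_min: float = 0.0  # e.g. 1e-6 to drop Hardy-Weinberg violations
    hapmap3: Optional[str] = None  # optional file with one SNP id per line


@dataclass
class AssocConfig:
    alpha: float = 0.05
    v_mode: str = "shrunk"  # or "raw"


@dataclass
class RunConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    ld: LdConfig = field(default_factory=LdConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    association: AssocConfig = field(default_factory=AssocConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    scenario: str = "accuracy"  # simulate stage: accuracy | power | type1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")


_NESTED = {
    "paths": PathsConfig,
    "filters": FilterConfig,
    "ld": LdConfig,
    "training": TrainingConfig,
    "association": AssocConfig,
    "simulation": SimulationConfig,
}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) under {context}: {', '.join(sorted(unknown))}")
    kwargs = {}
    for k, v in data.items():
        if cls is SimulationConfig and k == "ld_model" and isinstance(v, dict):
            v = _build(BlockLdModel, v, f"{context}.ld_model")
        if cls is SimulationConfig and k == "training" and isinstance(v, dict):
            v = _build(TrainingConfig, v, f"{context}.training")
        if isinstance(v, list):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def validate_config(path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are errors.

    An empty file yields all defaults.  All referenced input paths are
    checked for existence, with every missing path listed at once.  The
    resolved values are echoed to the log.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for k, v in raw.items():
        if k in _NESTED:
            if not isinstance(v, dict):
                raise ValueError(f"{path}: section {k!r} must be a mapping")
            kwargs[k] = _build(_NESTED[k], v, k)
        else:
            kwargs[k] = v
    cfg = RunConfig(**kwargs)

    missing = []
    for name in ("eqtl", "gwas", "map", "annotation", "tuning_expr", "testing_expr", "weights"):
        p = getattr(cfg.paths, name)
        if p is not None and not Path(p).exists():
            missing.append(f"{name}: {p}")
    if cfg.paths.panel is not None:
        panel = Path(cfg.paths.panel)
        if not (panel.exists() or panel.with_suffix(".bed").exists()):
            missing.append(f"panel: {cfg.paths.panel}")
    if missing:
        raise FileNotFoundError("missing input file(s):\n  " + "\n  ".join(missing))

    logger.info(
        "resolved config: window_bp=%d maf_min=%g r2_min=%g N_e=%g m=%g c=%g alpha=%g seed=%d",
        cfg.filters.window_bp, cfg.filters.maf_min, cfg.training.r2_min,
        cfg.ld.n_e, cfg.ld.m, cfg.ld.c, cfg.association.alpha, cfg.seed,
    )
    return cfg
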