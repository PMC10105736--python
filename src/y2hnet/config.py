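"""Pipeline configuration: one YAML document, one root seed.

The configuration is a nested dataclass tree validated up front —
unknown keys are rejected so a typo cannot silently fall back to a
default.  Every stage derives its randomness from the single root seed
via independent substreams, so runs are reproducible and stages are
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "load_config"]


def _from_dict(cls, data: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown keys for {cls.__name__}: {sorted(unknown)}; "
            f"allowed: {sorted(known)}"
        )
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        sub = _SECTION_TYPES.get((cls, f.name))
        kwargs[f.name] = _from_dict(sub, v) if sub is not None else v
    return cls(**kwargs)


@dataclass
class StageToggles:
    screen: bool = True
    l3: bool = True
    validation: bool = True
    integrate: bool = True
    enrich: bool = True
    expand: bool = True


@dataclass
class InteractomeConfig:
    n_genes: int = 300
    mean_degree: float = 4.0
    gamma: float = 2.5       # power-law degree exponent
    module_count: int = 5
    mixing: float = 0.2      # fraction of inter-module edges


@dataclass
class ScreenConfig:
    pool_size: int = 100
    aa_fraction: float = 0.05
    sensitivity: dict = field(default_factory=lambda: {"v1": 0.8, "v3": 0.8})
    replicates_per_version: int = 2
    lam_sig: float = 50.0
    lam_bg: float = 0.5
    M: float = 10.0
    N: float = 10.0
    depth: float = 1.0
    fipp_quantile: float = 0.95


@dataclass
class RetestConfig:
    delta: int = 2
    g_min: int = 2
    c_max: int = 3
    sensitivity: float = 0.9
    false_rate: float = 0.0005
    unscorable_rate: float = 0.01


@dataclass
class L3Config:
    top_k: int = 200


@dataclass
class ValidationConfig:
    mu0: float = 0.0
    mu1: float = 1.5
    sigma: float = 0.5
    n_rrs: int = 216
    n_prs: int = 150
    n_batches: int = 2
    n_screen_pairs: int = 200
    quantile: float = 99.0


@dataclass
class IntegrateConfig:
    legacy_cutoff: float = 0.7
    n_legacy: int = 300          # simulated legacy pairs
    legacy_true_fraction: float = 0.5
    n_lit_pairs: int = 150       # simulated literature evidence pairs


@dataclass
class EnrichConfig:
    n_null: int = 200
    max_term_size: int = 30
    max_genes_per_pub: int = 100
    n_bins: int = 5


@dataclass
class ExpandConfig:
    n_seeds: int = 10
    n_random: int = 50
    n_repeats: int = 5
    lines_per_gene_max: int = 5
    p_net: float = 0.5
    p_rand: float = 0.25


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/demo"
    stages: StageToggles = field(default_factory=StageToggles)
    interactome: InteractomeConfig = field(default_factory=InteractomeConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    retest: RetestConfig = field(default_factory=RetestConfig)
    l3: L3Config = field(default_factory=L3Config)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    integrate: IntegrateConfig = field(default_factory=IntegrateConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    expand: ExpandConfig = field(default_factory=ExpandConfig)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        return _from_dict(cls, data)


_SECTION_TYPES = {
    (PipelineConfig, "stages"): StageToggles,
    (PipelineConfig, "interactome"): InteractomeConfig,
    (PipelineConfig, "screen"): ScreenConfig,
    (PipelineConfig, "retest"): RetestConfig,
    (PipelineConfig, "l3"): L3Config,
    (PipelineConfig, "validation"): ValidationConfig,
    (PipelineConfig, "integrate"): IntegrateConfig,
    (PipelineConfig, "enrich"): EnrichConfig,
    (PipelineConfig, "expand"): ExpandConfig,
}


def load_config(path: str | Path | None = None, **overrides: Any) -> PipelineConfig:
    """Load a YAML config file (or defaults) with keyword overrides."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return PipelineConfig.from_dict(data)
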