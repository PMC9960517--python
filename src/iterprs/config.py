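"""Pipeline configuration: YAML parsing with a strict schema.

A config file is a nested mapping of stage sections; every key has a
default mirroring the pipeline's standard thresholds (INFO 0.9, SNP call
rate 0.95, MAF 0.05, HWE 1e-9, sample call rate 0.90, 100 iterations, 80/20
split, minimum appearance frequency 5). Unknown keys are rejected with the
offending field path.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "parse_config", "dump_config"]


@dataclasses.dataclass
class SimulateConfig:
    n_samples: int = 2000
    n_snps: int = 5000
    n_causal: int = 50
    heritability: float = 0.3
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.0
    n_pops: int = 1
    fst: float = 0.0
    ld_rho: float = 0.3


@dataclasses.dataclass
class MergeConfig:
    window_snps: int = 10
    r2_min: float = 0.8
    max_rounds: int = 10
    knn_k: int = 10
    allele_map: str | None = None


@dataclasses.dataclass
class QCConfig:
    info_min: float = 0.9
    variant_call_min: float = 0.95
    maf_min: float = 0.05
    hwe_min: float = 1e-9
    sample_call_min: float = 0.90


@dataclasses.dataclass
class StratConfig:
    max_pcs: int = 20
    tw_alpha: float = 0.05
    pca_mode: str = "per_split"


@dataclasses.dataclass
class PRSConfig:
    engines: tuple[str, ...] = ("wald_ols", "score_test")
    n_iter: int = 100
    train_frac: float = 0.8
    min_freq: int = 5
    thresholds: tuple[float, ...] = (5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    denominator_mode: str = "allele_count"
    log_base: float = 2.718281828459045
    select_alpha: float = 0.05
    phenotype: str = "phenotype"
    covariates: tuple[str, ...] = ("sex", "age", "status1", "status2")


@dataclasses.dataclass
class EvaluateConfig:
    reps_per_frac: int = 10
    frac_step: float = 0.05
    frac_max: float = 0.5


@dataclasses.dataclass
class PipelineConfig:
    master_seed: int = 0
    out_dir: str = "iterprs_out"
    simulate: SimulateConfig = dataclasses.field(default_factory=SimulateConfig)
    merge: MergeConfig = dataclasses.field(default_factory=MergeConfig)
    qc: QCConfig = dataclasses.field(default_factory=QCConfig)
    strat: StratConfig = dataclasses.field(default_factory=StratConfig)
    prs: PRSConfig = dataclasses.field(default_factory=PRSConfig)
    evaluate: EvaluateConfig = dataclasses.field(default_factory=EvaluateConfig)




def _build(cls: type, data: Mapping[str, Any], path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key: {path}{key}")
        default = fields[key].default
        factory = fields[key].default_factory
        if factory is not dataclasses.MISSING and dataclasses.is_dataclass(factory()):
            if not isinstance(value, Mapping):
                raise ValueError(f"config section {path}{key} must be a mapping")
            kwargs[key] = _build(type(factory()), value, f"{path}{key}.")
        else:
            if isinstance(default, tuple) or (
                factory is not dataclasses.MISSING and isinstance(factory(), tuple)
            ):
                value = tuple(value)
            kwargs[key] = value
    return cls(**kwargs)


def parse_config(path: str | Path | None = None, overrides: Mapping[str, Any] | None = None) -> PipelineConfig:
    """Load a YAML config, filling defaults; unknown keys raise ValueError."""
    data: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"{path}: config root must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    return _build(PipelineConfig, data, "")


def dump_config(config: PipelineConfig, path: str | Path | None = None) -> str:
    """Serialize a config to YAML (round-trips through parse_config)."""
    def to_plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    text = yaml.safe_dump(to_plain(config), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
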