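"""Pipeline configuration: defaults, YAML loading, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised with the offending key path on invalid configuration."""


@dataclass
class DemuxParams:
    trim_remnant: bool = False
    check_read2_remnant: bool = False


@dataclass
class QCParams:
    q_threshold: int = 20
    min_length: int = 50


@dataclass
class ReferenceParams:
    cluster_radius: int = 2
    min_cluster_depth: int = 4
    max_mismatches: int = 2
    repeat_hit_limit: int = 50


@dataclass
class VariantParams:
    min_allele_depth: int = 4
    genotype_error_rate: float = 0.01
    prior: str = "uniform"          # uniform | f9
    het_policy: str = "mask"        # mask | keep | strict
    het_locus_threshold: float = 0.1
    third_allele_fraction: float = 0.2
    mmd: float = 0.25
    min_allele_individuals: int = 30


@dataclass
class LinkageParams:
    max_rf: float = 0.45
    min_lod: float | str = 2.0      # LOD threshold, or "auto" (Bonferroni)
    min_informative: int = 20
    min_shared: int = 20
    alpha: float = 0.05
    min_sdr_markers: int = 3


@dataclass
class PipelineConfig:
    mode: str = "simulate"          # simulate | fastq
    outdir: str = "ddradmap_run"
    seed: int = 0
    # fastq-mode inputs
    pools: list = field(default_factory=list)    # [[R1, R2], ...]
    sample_sheet: str = ""
    # stage parameters
    sim: dict = field(default_factory=dict)      # SimConfig overrides
    demux: DemuxParams = field(default_factory=DemuxParams)
    qc: QCParams = field(default_factory=QCParams)
    reference: ReferenceParams = field(default_factory=ReferenceParams)
    variants: VariantParams = field(default_factory=VariantParams)
    linkage: LinkageParams = field(default_factory=LinkageParams)


_RANGES = {
    "variants.mmd": (0.0, 1.0),
    "variants.genotype_error_rate": (0.0, 0.5),
    "variants.het_locus_threshold": (0.0, 1.0),
    "variants.third_allele_fraction": (0.0, 1.0),
    "linkage.max_rf": (0.0, 0.5),
    "linkage.alpha": (0.0, 1.0),
    "qc.q_threshold": (0, 60),
}
_POSITIVE = {
    "reference.min_cluster_depth", "reference.repeat_hit_limit",
    "variants.min_allele_depth", "linkage.min_sdr_markers",
    "qc.min_length",
}
_NONNEG = {"reference.cluster_radius", "reference.max_mismatches",
           "linkage.min_informative", "linkage.min_shared",
           "variants.min_allele_individuals"}
_CHOICES = {
    "mode": ("simulate", "fastq"),
    "variants.prior": ("uniform", "f9"),
    "variants.het_policy": ("mask", "keep", "strict"),
}


def _apply_section(obj, section: str, values: dict):
    valid = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in valid:
            raise ConfigError(f"unknown key: {section}.{key}")
        setattr(obj, key, val)


def config_from_dict(data: dict | None) -> PipelineConfig:
    cfg = PipelineConfig()
    data = dict(data or {})
    sections = {"demux": cfg.demux, "qc": cfg.qc,
                "reference": cfg.reference, "variants": cfg.variants,
                "linkage": cfg.linkage}
    top = {f.name for f in dataclasses.fields(PipelineConfig)}
    for key, val in data.items():
        if key in sections:
            if not isinstance(val, dict):
                raise ConfigError(f"section {key} must be a mapping")
            _apply_section(sections[key], key, val)
        elif key == "sim":
            if not isinstance(val, dict):
                raise ConfigError("section sim must be a mapping")
            from .simulate import SimConfig
            valid = {f.name for f in dataclasses.fields(SimConfig)}
            bad = set(val) - valid
            if bad:
                raise ConfigError(f"unknown key: sim.{sorted(bad)[0]}")
            cfg.sim = dict(val)
        elif key in top:
            setattr(cfg, key, val)
        else:
            raise ConfigError(f"unknown key: {key}")
    validate(cfg)
    return cfg


def validate(cfg: PipelineConfig) -> None:
    def get(path):
        section, _, name = path.partition(".")
        if not name:
            return getattr(cfg, section)
        return getattr(getattr(cfg, section), name)

    for path, (lo, hi) in _RANGES.items():
        v = get(path)
        if not lo <= v <= hi:
            raise ConfigError(f"{path}={v} outside [{lo}, {hi}]")
    for path in _POSITIVE:
        if get(path) <= 0:
            raise ConfigError(f"{path} must be positive")
    for path in _NONNEG:
        if get(path) < 0:
            raise ConfigError(f"{path} must be non-negative")
    for path, choices in _CHOICES.items():
        if get(path) not in choices:
            raise ConfigError(f"{path} must be one of {choices}")
    lod = cfg.linkage.min_lod
    if not (lod == "auto" or (isinstance(lod, (int, float)) and lod >= 0)):
        raise ConfigError("linkage.min_lod must be a non-negative number "
                          "or 'auto'")
    if cfg.mode == "fastq":
        if not cfg.pools or not cfg.sample_sheet:
            raise ConfigError("fastq mode requires pools and sample_sheet")


def load_config(path) -> PipelineConfig:
    """Load a YAML config; absent keys take defaults, unknown keys fail."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = dataclasses.asdict(cfg)
    return out


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
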