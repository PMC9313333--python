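"""Pipeline configuration: nested sections, YAML loading, full defaulting.

Every defaulted value matches the method's stated settings (3 SD outlier
rule, 8 Hz resampling, PE m=4 with tau in 1..4, SampEn m=2 / r=0.2*SD,
LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, 1/2/3-min windows); everything the
method leaves open (sifting controls, Relief-F k, SVM C) is exposed
here.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .classify import SVMConfig
from .emd import SiftConfig
from .errors import ConfigError
from .features import EntropyParams
from .segmentation import SegmentSpec
from .simulate import CohortSpec, IPFMParams

__all__ = ["PipelineConfig", "load_config", "config_hash", "with_seed"]


@dataclass(frozen=True)
class PreprocessConfig:
    sd_multiplier: float = 3.0
    fs: float = 8.0


@dataclass(frozen=True)
class GpnnxConfig:
    alpha: float = 0.05


@dataclass(frozen=True)
class ReliefConfig:
    k: int = 10
    ranking_mode: str = "per_fold"  # or "global"


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    sift: SiftConfig = field(default_factory=SiftConfig)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    gpnnx: GpnnxConfig = field(default_factory=GpnnxConfig)
    segment: SegmentSpec = field(default_factory=SegmentSpec)
    relief: ReliefConfig = field(default_factory=ReliefConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    seed: int = 0


_SECTION_TYPES = {
    "cohort": CohortSpec,
    "preprocess": PreprocessConfig,
    "sift": SiftConfig,
    "entropy": EntropyParams,
    "gpnnx": GpnnxConfig,
    "segment": SegmentSpec,
    "relief": ReliefConfig,
    "svm": SVMConfig,
}


def _build_section(cls, data, section):
    allowed = {f.name for f in fields(cls)}
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ConfigError(f"section '{section}': unknown keys {unknown}")
    nested = {}
    for f in fields(cls):
        if f.name in data and f.type in ("IPFMParams",) and isinstance(data[f.name], dict):
            nested[f.name] = _build_section(IPFMParams, data[f.name],
                                            f"{section}.{f.name}")
    try:
        return cls(**{**data, **nested})
    except TypeError as exc:
        raise ConfigError(f"section '{section}': {exc}") from None


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides.

    Unknown sections or keys raise :class:`ConfigError` listing the
    offending names; omitted values take the defaults above.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(data) - set(_SECTION_TYPES) - {"seed"})
    if unknown:
        raise ConfigError(f"unknown config sections: {unknown}")
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            if not isinstance(data[name], dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            sections[name] = _build_section(cls, data[name], name)
    seed = data.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed must be an integer")
    # the top-level seed is the master: it reaches the cohort generator
    # unless the cohort section pins its own
    if "seed" not in data.get("cohort", {}):
        cohort = sections.get("cohort", CohortSpec())
        sections["cohort"] = replace(cohort, seed=seed)
    return PipelineConfig(seed=seed, **sections)


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the full configuration, for provenance."""
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def with_seed(config: PipelineConfig, seed: int | None) -> PipelineConfig:
    if seed is None:
        return config
    return replace(config, seed=seed,
                   cohort=replace(config.cohort, seed=seed))
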