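"""Run configuration: nested dataclasses, YAML round-trip, strict keys.

Unknown keys are rejected rather than ignored so a typo cannot silently
fall back to a default, and every pipeline run writes its fully resolved
configuration next to its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .exceptions import ValidationError


@dataclass(frozen=True)
class DetectionConfig:
    min_height_fu: float = 20.0
    min_prominence_fu: float = 5.0
    min_separation_s: float = 0.2


@dataclass(frozen=True)
class StandardsConfig:
    lower_kda: float = 1.6
    upper_kda: float = 95.0
    #: fraction of the trace span searched for each standard (from each end)
    window_fraction: float = 0.25
    #: reference apex times; None = use the first sample with located standards
    reference_lower_s: float | None = None
    reference_upper_s: float | None = None


@dataclass(frozen=True)
class BinningConfig:
    k_sd: float = 3.0
    min_half_width_s: float = 0.15
    max_half_width_s: float = 0.5
    gap_s: float = 0.5
    min_support: int = 2
    #: "group": cluster replicate peaks across all runs of a group
    #: (the per-species flow); "individual": per-individual duplicates only
    granularity: str = "group"

    def __post_init__(self) -> None:
        if self.granularity not in ("group", "individual"):
            raise ValidationError(f"unknown binning granularity {self.granularity!r}")


@dataclass(frozen=True)
class QcConfig:
    mismatch_threshold: int = 3


@dataclass(frozen=True)
class OrdinationConfig:
    dimensions: int = 2
    n_starts: int = 20
    max_iter: int = 300
    tol: float = 1e-7
    permutations: int = 999


@dataclass(frozen=True)
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    standards: StandardsConfig = field(default_factory=StandardsConfig)
    binning: BinningConfig = field(default_factory=BinningConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    ordination: OrdinationConfig = field(default_factory=OrdinationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())


_SECTIONS = {
    "detection": DetectionConfig,
    "standards": StandardsConfig,
    "binning": BinningConfig,
    "qc": QcConfig,
    "ordination": OrdinationConfig,
}


def _build_section(cls, data: dict, where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from nested dicts, rejecting unknown keys."""
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if not isinstance(section, dict):
            raise ValidationError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    seed = data.pop("seed", 0)
    if data:
        raise ValidationError(f"unknown top-level config key(s): {sorted(data)}")
    return RunConfig(seed=int(seed), **kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})


def with_overrides(cfg: RunConfig, **dotted) -> RunConfig:
    """Apply `section__key=value` overrides (used by CLI flags)."""
    for key, value in dotted.items():
        if value is None:
            continue
        section, _, leaf = key.partition("__")
        if not leaf:
            cfg = replace(cfg, **{section: value})
        else:
            sub = replace(getattr(cfg, section), **{leaf: value})
            cfg = replace(cfg, **{section: sub})
    return cfg
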