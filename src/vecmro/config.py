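"""Declarative run configuration.

One YAML file (sections ``davis``, ``pipeline``, ``gas``,
``classification`` plus a top-level ``seed``) overrides the defaults;
command-line flags override the file.  Unknown keys are rejected so
typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

from .davis import DavisParams
from .evoked import GasProtocol
from .classify import ClassificationConfig

__all__ = ["PipelineConfig", "RunConfig", "load_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Preprocessing and ROI-selection settings (units in comments)."""

    gm_threshold: float = 0.80  # grey-matter partial-volume cut (fraction)
    task_top_fraction: float = 0.05  # task functional ROI quantile
    gas_top_fraction: float = 0.15
    gas_fallback_fraction: float = 0.20
    gas_min_voxels: int = 10
    fwhm_mm: float = 8.0  # spatial smoothing kernel
    highpass_hz: float = 0.0039  # temporal high-pass cutoff
    despike_k: float = 3.0  # spike threshold in robust SDs
    averaging_mode: str = "voxelwise"  # or "roi_mean"

    def __post_init__(self) -> None:
        for name in ("gm_threshold", "task_top_fraction", "gas_top_fraction",
                     "gas_fallback_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.fwhm_mm < 0 or self.highpass_hz <= 0 or self.despike_k <= 0:
            raise ValueError("fwhm_mm >= 0, highpass_hz > 0, despike_k > 0 required")
        if self.averaging_mode not in ("voxelwise", "roi_mean"):
            raise ValueError(f"unknown averaging_mode {self.averaging_mode!r}")


@dataclass(frozen=True)
class RunConfig:
    davis: DavisParams = field(default_factory=DavisParams)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    gas: GasProtocol = field(default_factory=GasProtocol)
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "davis": DavisParams,
    "pipeline": PipelineConfig,
    "gas": GasProtocol,
    "classification": ClassificationConfig,
}


def _build(cls, values: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**values)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    ``overrides`` maps section name -> {key: value} (or ``seed`` -> int)
    and wins over the file, which wins over the defaults.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(open(path)) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config file must hold a mapping")
        raw.update(loaded)
    for section, vals in (overrides or {}).items():
        if section == "seed":
            raw["seed"] = vals
        else:
            raw.setdefault(section, {})
            raw[section] = {**raw.get(section, {}), **vals}

    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ValueError("seed must be an integer")
    return RunConfig(seed=seed, **kwargs)
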