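"""Run configuration: YAML round trip with strict key checking.

Every tunable of the pipeline lives in one nested mapping whose defaults are
the method's published operating point.  Unknown keys are rejected so that a
typo in a config file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detect import DetectionParams
from .simulate import SimConfig

__all__ = ["RunConfig", "load_config", "save_config", "default_config_yaml"]


@dataclass
class NparcSettings:
    min_cell_lines: int = 10
    s_res_max: float = 0.1
    f_variant: str = "as_published"
    percentile: float = 90.0


@dataclass
class CoaggregationSettings:
    min_score: float = 950.0
    n_null: int = 10000
    alpha: float = 0.1
    top_fraction: float = 0.10
    min_lines: int = 4


@dataclass
class DrugSettings:
    min_max_sdss: float = 6.0
    alpha: float = 0.1
    min_lines: int = 3
    exclude_cell_lines: list[str] = field(default_factory=list)


@dataclass
class DataSettings:
    min_cell_lines: int = 2
    normalization_enabled: bool = True
    reference: str = "lowest_temperature"


@dataclass
class RunConfig:
    """Top-level configuration of a pipeline run."""

    peptides: str | None = None  # long-format peptide TSV
    ppi: str | None = None  # gene_a, gene_b, combined_score TSV
    sdss: str | None = None  # cell line x drug TSV
    out_dir: str = "meltforms_out"
    seed: int = 0
    log_level: str = "INFO"
    data: DataSettings = field(default_factory=DataSettings)
    detection: DetectionParams = field(default_factory=DetectionParams)
    nparc: NparcSettings = field(default_factory=NparcSettings)
    coaggregation: CoaggregationSettings = field(default_factory=CoaggregationSettings)
    drugs: DrugSettings = field(default_factory=DrugSettings)
    simulation: SimConfig = field(default_factory=SimConfig)


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or cls.__name__!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path or 'top level'}: "
                         f"{sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type)
            and dataclasses.is_dataclass(f.default_factory)
        ):
            sub_cls = f.default_factory if f.default_factory is not dataclasses.MISSING else f.type
            kwargs[key] = _from_dict(sub_cls, value, path=f"{path}{key}.")
        elif key in ("delta_tm_levels", "temperatures", "tm_range") and value is not None:
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, raw)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def default_config_yaml() -> str:
    """YAML text of the full default configuration block."""
    return yaml.safe_dump(_to_plain(RunConfig()), sort_keys=False)
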