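"""Run configuration: a YAML document with one block per pipeline stage.

Blocks (all optional, defaults shown in ``RunConfig``): ``geometry``,
``emission``/``scenario``, ``selection``, ``reconstruction``, ``metrics``,
``sensitivity``, plus a master ``seed`` and an ``output`` directory.
Unknown keys raise a schema error naming the offending field path; a config
round-trips (write -> read -> identical).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .generate import ScenarioConfig
from .selection import SelectionConfig
from .transport import DetectorResponse

__all__ = ["RunConfig", "SchemaError", "load_config", "save_config"]


class SchemaError(ValueError):
    pass


@dataclass(frozen=True)
class ReconstructionConfig:
    pgi_nx: int = 1200
    pgi_ny: int = 1200
    pgi_half_size_mm: float = 250.0
    pet_nx: int = 700
    pet_ny: int = 700
    pet_half_size_mm: float = 150.0
    method: str = "backproject"   # backproject | analytic
    ring_sigma_mm: float = 3.0
    l_max: int = 40
    filter_floor: float = 1e-3
    use_fov_weights: bool = False


@dataclass(frozen=True)
class MetricsConfig:
    beam_dir: int = -1
    contour_band: float = 0.02
    clip_negative: bool = True


@dataclass(frozen=True)
class SensitivityConfig:
    levels: tuple = (1000, 10000)
    m_per_level: int = 50
    mode: str = "disjoint"


@dataclass(frozen=True)
class RunConfig:
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    reconstruction: ReconstructionConfig = field(
        default_factory=ReconstructionConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    sensitivity: SensitivityConfig = field(default_factory=SensitivityConfig)
    seed: int = 0
    output_dir: str = "results"


_BLOCKS = {
    "scenario": ScenarioConfig,
    "selection": SelectionConfig,
    "reconstruction": ReconstructionConfig,
    "metrics": MetricsConfig,
    "sensitivity": SensitivityConfig,
}


def _build_block(name, cls, data):
    if not isinstance(data, dict):
        raise SchemaError(f"{name}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    for key in data:
        if key not in allowed:
            raise SchemaError(f"{name}.{key}: unknown field")
    kwargs = dict(data)
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    if cls is ScenarioConfig and "response" in kwargs \
            and isinstance(kwargs["response"], dict):
        kwargs["response"] = DetectorResponse(**kwargs["response"])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as err:
        raise SchemaError(f"{name}: {err}") from err


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    kwargs = {}
    for key, val in data.items():
        if key in _BLOCKS:
            kwargs[key] = _build_block(key, _BLOCKS[key], val)
        elif key == "seed":
            kwargs["seed"] = int(val)
        elif key == "output_dir":
            kwargs["output_dir"] = str(val)
        else:
            raise SchemaError(f"{key}: unknown config block")
    return RunConfig(**kwargs)


def save_config(path, config: RunConfig) -> None:
    doc = {name: asdict(getattr(config, name)) for name in _BLOCKS}
    doc["seed"] = config.seed
    doc["output_dir"] = config.output_dir
    for block in doc.values():
        if isinstance(block, dict):
            for k, v in block.items():
                if isinstance(v, tuple):
                    block[k] = list(v)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
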