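"""YAML mirrors of the pipeline's configuration dataclasses.

A config file maps section names to keyword arguments of the corresponding
dataclass, e.g.::

    paste:
      copies_per_image: 10
      max_attempts: 100
      seed: 1
    scales:
      scales: [[1500, 1000], [1333, 800]]
    cascade:
      stage_iou_thresholds: [0.5, 0.6, 0.7]

Unknown keys raise immediately rather than being silently ignored.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Type, TypeVar, Union

import yaml

from .augment import PasteConfig
from .model import AsppConfig, BackboneConfig, CascadeConfig, DetectorConfig
from .preprocess import ScaleSpec, TileGrid
from .synthetic import SceneConfig

T = TypeVar("T")

SECTIONS: Dict[str, type] = {
    "paste": PasteConfig,
    "scales": ScaleSpec,
    "grid": TileGrid,
    "scene": SceneConfig,
    "backbone": BackboneConfig,
    "aspp": AsppConfig,
    "cascade": CascadeConfig,
    "detector": DetectorConfig,
}


def _coerce(cls: Type[T], payload: Dict[str, Any]) -> T:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    # YAML has no tuple type; convert lists where the dataclass expects tuples
    kwargs = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    """Parse a YAML pipeline config into instantiated dataclasses by section."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping of section names")
    out: Dict[str, Any] = {}
    for section, payload in doc.items():
        if section not in SECTIONS:
            raise ValueError(
                f"unknown config section {section!r}; expected one of {sorted(SECTIONS)}"
            )
        out[section] = _coerce(SECTIONS[section], payload or {})
    return out
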