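"""Lens-model registry.

The two study lenses are pre-registered: a 0.25 D-interval lens with a
reported power-labeling SD of ±0.11 D (Softec HD) and a 0.50 D-interval
lens carrying the ISO-style ±0.40 D tolerance treated as an SD
(Akreos AO), both over the 15.5–25.0 D range, with their data-adjusted
SRK/T A-constants and Haigis triples. Additional lenses can be loaded
from a YAML or JSON file with the same field names.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Union

import yaml

from .types import IOLModel

SOFTEC_HD = IOLModel(
    name="Softec HD",
    interval=0.25,
    tolerance_sd=0.11,
    a_constant=118.17,
    haigis_a0=0.565,
    haigis_a1=0.240,
    haigis_a2=0.138,
    power_min=15.5,
    power_max=25.0,
)

AKREOS_AO = IOLModel(
    name="Akreos AO",
    interval=0.50,
    tolerance_sd=0.40,
    a_constant=118.24,
    haigis_a0=1.706,
    haigis_a1=0.279,
    haigis_a2=0.087,
    power_min=15.5,
    power_max=25.0,
)


def builtin_registry() -> Dict[str, IOLModel]:
    """Return the built-in registry keyed by lens name."""
    return {lens.name: lens for lens in (SOFTEC_HD, AKREOS_AO)}


def load_registry(path: Union[str, Path]) -> Dict[str, IOLModel]:
    """Load a lens registry from a YAML or JSON file.

    The file maps lens names to field dicts; a missing ``name`` field is
    filled from the key.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    registry: Dict[str, IOLModel] = {}
    for name, fields in raw.items():
        fields = dict(fields)
        fields.setdefault("name", name)
        registry[name] = IOLModel(**fields)
    return registry


def save_registry(registry: Dict[str, IOLModel], path: Union[str, Path]) -> None:
    """Write a registry to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    raw = {name: asdict(lens) for name, lens in registry.items()}
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))
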