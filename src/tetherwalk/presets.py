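"""Shipped parameter presets (TOML) for MAP and motor constructs.

The package's calibration lives in ``data/presets.toml``; these helpers
turn the named sections into the parameter dataclasses.  Users can load a
modified copy of the file via :func:`load_presets`.
"""

from __future__ import annotations

import tomllib
from functools import lru_cache
from importlib import resources

from .decoration import MAPParams
from .motors import MotorParams, TetherParams
from .synthetic import NoiseModel

__all__ = [
    "load_presets",
    "map_preset",
    "motor_preset",
    "tether_defaults",
    "noise_defaults",
    "high_decoration_nM",
    "available_presets",
]


@lru_cache(maxsize=None)
def _shipped() -> dict:
    with resources.files("tetherwalk.data").joinpath("presets.toml").open("rb") as fh:
        return tomllib.load(fh)


def load_presets(path=None) -> dict:
    """Raw preset dictionary, from the shipped file or a user TOML."""
    if path is None:
        return _shipped()
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def map_preset(name: str, presets: dict | None = None) -> MAPParams:
    """MAP construct preset by name (FL_MAP7, MTBD_only, dMTBD, ...)."""
    table = (presets or _shipped())["map"]
    if name not in table:
        raise KeyError(f"unknown MAP preset {name!r}; available: {sorted(table)}")
    return MAPParams(name=name, **table[name])


def motor_preset(name: str, presets: dict | None = None) -> MotorParams:
    """Motor construct preset by name (K560, K560_limiting_ATP, K490, FL_kinesin, DDR)."""
    table = (presets or _shipped())["motor"]
    if name not in table:
        raise KeyError(f"unknown motor preset {name!r}; available: {sorted(table)}")
    return MotorParams(name=name, **table[name])


def tether_defaults(presets: dict | None = None) -> TetherParams:
    return TetherParams(**(presets or _shipped())["tether"])


def noise_defaults(presets: dict | None = None) -> NoiseModel:
    return NoiseModel(**(presets or _shipped())["noise"])


def high_decoration_nM(presets: dict | None = None) -> float:
    """Shipped near-saturating MAP7 concentration (theta ~ 0.9)."""
    return float((presets or _shipped())["conditions"]["high_decoration_nM"])


def available_presets() -> dict[str, list[str]]:
    data = _shipped()
    return {"map": sorted(data["map"]), "motor": sorted(data["motor"])}
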