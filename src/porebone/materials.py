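"""Acoustic material properties for the two-component bone phantoms.

The default table holds the constituent properties used throughout:
water, red marrow and cortical bone, each with a speed of sound (m/s),
an attenuation coefficient (Np/m, quoted at the 1 MHz reference
frequency) and a density (kg/m^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

#: Integer labels used in voxel phantoms.
LABEL_WATER = 0
LABEL_MARROW = 1
LABEL_CORTICAL = 2

REFERENCE_FREQUENCY_HZ = 1.0e6


@dataclass(frozen=True)
class Material:
    """One constituent material.

    Attributes
    ----------
    name:
        Human-readable identifier.
    speed_of_sound:
        Longitudinal sound speed in m/s.
    attenuation_ref:
        Amplitude attenuation coefficient in Np/m at the 1 MHz
        reference frequency.
    density:
        Mass density in kg/m^3.
    """

    name: str
    speed_of_sound: float
    attenuation_ref: float
    density: float

    def __post_init__(self) -> None:
        if self.speed_of_sound <= 0:
            raise ValueError(f"{self.name}: speed of sound must be positive")
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.attenuation_ref < 0:
            raise ValueError(f"{self.name}: attenuation must be non-negative")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*c in Rayl (kg/m^2/s)."""
        return self.speed_of_sound * self.density


WATER = Material("water", speed_of_sound=1500.0, attenuation_ref=0.0, density=1000.0)
RED_MARROW = Material("red_marrow", speed_of_sound=1450.0, attenuation_ref=12.55, density=1029.0)
CORTICAL_BONE = Material("cortical_bone", speed_of_sound=3514.0, attenuation_ref=54.55, density=1908.0)


@dataclass(frozen=True)
class MaterialTable:
    """Water / marrow / cortical property set keyed by voxel label."""

    water: Material = WATER
    marrow: Material = RED_MARROW
    cortical: Material = CORTICAL_BONE

    def __post_init__(self) -> None:
        if not self.cortical.speed_of_sound > self.marrow.speed_of_sound:
            raise ValueError("cortical speed of sound must exceed marrow's")
        if not self.cortical.density > self.marrow.density:
            raise ValueError("cortical density must exceed marrow's")
        if self.water.attenuation_ref != 0.0:
            raise ValueError("water attenuation must be zero")

    def by_label(self, label: int) -> Material:
        try:
            return (self.water, self.marrow, self.cortical)[label]
        except (IndexError, TypeError) as exc:
            raise KeyError(f"unknown material label {label!r}") from exc

    @property
    def materials(self) -> tuple[Material, Material, Material]:
        return (self.water, self.marrow, self.cortical)

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            role: {
                "speed_of_sound": m.speed_of_sound,
                "attenuation_ref": m.attenuation_ref,
                "density": m.density,
            }
            for role, m in zip(("water", "marrow", "cortical"), self.materials)
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "MaterialTable":
        defaults = {"water": WATER, "marrow": RED_MARROW, "cortical": CORTICAL_BONE}
        mats = {}
        for role, default in defaults.items():
            entry = data.get(role)
            if entry is None:
                mats[role] = default
            else:
                mats[role] = Material(
                    name=str(entry.get("name", default.name)),
                    speed_of_sound=float(entry["speed_of_sound"]),
                    attenuation_ref=float(entry["attenuation_ref"]),
                    density=float(entry["density"]),
                )
        return cls(**mats)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MaterialTable":
        """Read a material table from a YAML config; missing entries fall
        back to the built-in defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("materials", data))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"materials": self.to_dict()}, fh, sort_keys=False)


DEFAULT_MATERIALS = MaterialTable()
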