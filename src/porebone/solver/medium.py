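"""Per-voxel acoustic material fields on the simulation grid."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from porebone.materials import (
    LABEL_CORTICAL,
    LABEL_MARROW,
    LABEL_WATER,
    REFERENCE_FREQUENCY_HZ,
    MaterialTable,
)
from porebone.phantoms import LabelVolume
from porebone.solver.grid import SimGrid

__all__ = [
    "MediumFields",
    "assign_materials",
    "fields_to_labels",
    "water_medium",
    "homogeneous_slab_labels",
    "embed_labels",
    "effective_attenuation",
]


def effective_attenuation(attenuation_ref: float, frequency: float, scale_up: bool = True) -> float:
    """Absorption pre-factor (Np/m) at the simulated frequency.

    The reference Np/m value (quoted at 1 MHz) is scaled by
    ``sqrt(f / 1 MHz)``, and the result is used with a power-law
    exponent fixed at 2 so no dispersion correction arises.
    ``scale_up=False`` applies the reciprocal ``sqrt(1 MHz / f)``
    scaling instead (config override; the literal rule is the default).
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    ratio = frequency / REFERENCE_FREQUENCY_HZ
    return attenuation_ref * (ratio**0.5 if scale_up else ratio**-0.5)


@dataclass
class MediumFields:
    """Speed of sound, density and absorption pre-factor per voxel.

    Fields are unsmoothed: material boundaries stay sharp.  The
    absorption pre-factor is the effective Np/m value at ``frequency``
    (zero everywhere for nonabsorbing media) with the power-law exponent
    fixed at 2 (dispersion-free).
    """

    c: np.ndarray  # m/s
    rho: np.ndarray  # kg/m^3
    alpha: np.ndarray  # Np/m at the simulated frequency
    frequency: float | None = None

    def __post_init__(self) -> None:
        self.c = np.ascontiguousarray(self.c, dtype=np.float64)
        self.rho = np.ascontiguousarray(self.rho, dtype=np.float64)
        self.alpha = np.ascontiguousarray(self.alpha, dtype=np.float64)
        if not (self.c.shape == self.rho.shape == self.alpha.shape):
            raise ValueError("c, rho and alpha must share a shape")
        if np.any(self.c <= 0) or np.any(self.rho <= 0):
            raise ValueError("c and rho must be strictly positive")
        if np.any(self.alpha < 0):
            raise ValueError("alpha must be non-negative")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.c.shape

    @property
    def ndim(self) -> int:
        return self.c.ndim

    @property
    def c_max(self) -> float:
        return float(self.c.max())

    @property
    def c_min(self) -> float:
        return float(self.c.min())

    @property
    def absorbing(self) -> bool:
        return bool(np.any(self.alpha > 0))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for arr in (self.c, self.rho, self.alpha):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


def embed_labels(vol: LabelVolume, grid: SimGrid) -> np.ndarray:
    """Place slab labels into the full interior grid (water elsewhere).

    The slab occupies z voxels ``[slab_offset, slab_offset + nz_slab)``;
    transverse dims must match the grid.
    """
    if vol.labels.ndim != grid.ndim:
        raise ValueError("label volume and grid dimensionality differ")
    if vol.labels.shape[:-1] != grid.dims[:-1]:
        raise ValueError(
            f"transverse label dims {vol.labels.shape[:-1]} do not match grid {grid.dims[:-1]}"
        )
    z0 = vol.origin_offset if vol.origin_offset is not None else grid.slab_offset
    nz_slab = vol.labels.shape[-1]
    if z0 + nz_slab > grid.nz:
        raise ValueError("slab does not fit in the grid along z")
    full = np.full(grid.dims, LABEL_WATER, dtype=np.uint8)
    full[..., z0 : z0 + nz_slab] = vol.labels
    return full


def assign_materials(
    vol: LabelVolume | np.ndarray,
    mat: MaterialTable,
    absorbing: bool = False,
    frequency: float = 650e3,
    grid: SimGrid | None = None,
    attenuation_scale_up: bool = True,
) -> MediumFields:
    """Map material labels to per-voxel acoustic fields.

    If ``grid`` is given the labels are first embedded into the full
    interior grid (surrounded by water along z).  With ``absorbing``
    False the absorption field is identically zero; otherwise each
    voxel gets its material's effective Np/m pre-factor at ``frequency``.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if isinstance(vol, LabelVolume):
        labels = embed_labels(vol, grid) if grid is not None else vol.labels
    else:
        labels = np.asarray(vol)
    if labels.size == 0:
        raise ValueError("empty label volume")
    valid = (LABEL_WATER, LABEL_MARROW, LABEL_CORTICAL)
    if not np.isin(labels, valid).all():
        bad = np.unique(labels[~np.isin(labels, valid)])
        raise KeyError(f"unknown material labels {bad.tolist()}")

    c_lut = np.array([m.speed_of_sound for m in mat.materials])
    rho_lut = np.array([m.density for m in mat.materials])
    if absorbing:
        a_lut = np.array(
            [effective_attenuation(m.attenuation_ref, frequency, attenuation_scale_up) for m in mat.materials]
        )
    else:
        a_lut = np.zeros(3)
    return MediumFields(
        c=c_lut[labels], rho=rho_lut[labels], alpha=a_lut[labels], frequency=frequency
    )


def fields_to_labels(medium: MediumFields, mat: MaterialTable) -> np.ndarray:
    """Recover labels from fields by nearest-table lookup on (c, rho)."""
    c_lut = np.array([m.speed_of_sound for m in mat.materials])
    rho_lut = np.array([m.density for m in mat.materials])
    # normalized squared distance in (c, rho) space
    dc = (medium.c[..., None] - c_lut) / c_lut.max()
    dr = (medium.rho[..., None] - rho_lut) / rho_lut.max()
    return np.argmin(dc**2 + dr**2, axis=-1).astype(np.uint8)


def water_medium(grid: SimGrid, mat: MaterialTable, frequency: float = 650e3) -> MediumFields:
    """All-water interior medium (the insertion-loss reference)."""
    labels = np.full(grid.dims, LABEL_WATER, dtype=np.uint8)
    return assign_materials(labels, mat, absorbing=False, frequency=frequency)


def homogeneous_slab_labels(grid: SimGrid, label: int, thickness_mm: float | None = None) -> np.ndarray:
    """Interior label grid with a homogeneous slab of ``label`` along z.

    The slab starts at ``grid.slab_offset`` and spans ``thickness_mm``
    (default 5 mm).
    """
    thickness_mm = 5.0 if thickness_mm is None else thickness_mm
    nz_slab = int(round(thickness_mm / grid.spacing))
    labels = np.full(grid.dims, LABEL_WATER, dtype=np.uint8)
    z0 = grid.slab_offset
    if z0 + nz_slab > grid.nz:
        raise ValueError("slab thickness exceeds the grid")
    labels[..., z0 : z0 + nz_slab] = label
    return labels
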