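"""Randomized two-material bone-mimicking voxel phantoms.

Phantoms are cortical-bone slabs into which spherical (3D) or circular
(2D) marrow pores of a single fixed diameter are dropped at uniformly
random positions until a target porosity is reached.  Pores may overlap
and are clipped at the slab faces, so the planar water/bone interfaces
are preserved.  The achieved porosity (marrow voxels over bone-region
voxels) is recorded on the output volume; it always lands at or slightly
above the target because placement stops at the first pore that crosses
the threshold.

Curved shell masks (spherical-cap shells with angular thickness
variation) provide nonplanar water/bone interfaces; applying a mask to a
planar phantom sets out-of-mask voxels to water and re-measures the
porosity over the remaining bone region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from porebone.materials import LABEL_CORTICAL, LABEL_MARROW, LABEL_WATER

__all__ = [
    "PhantomSpec",
    "LabelVolume",
    "ShellSpec",
    "SHELL_PRESETS",
    "PhantomGenerationError",
    "phantom_seed",
    "generate_planar_phantom",
    "measure_porosity",
    "generate_shell_mask",
    "apply_mask",
    "single_pore_volume_fraction",
]

#: Pore diameters (mm) used in the planar-phantom study.
STANDARD_PORE_DIAMETERS = (0.2, 0.3, 0.4, 0.6, 0.8, 1.0)
#: Nominal porosities used in the planar-phantom study.
STANDARD_POROSITIES = (0.025, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.75)


class PhantomGenerationError(RuntimeError):
    """Raised when a porosity target cannot be reached within budget."""


def phantom_seed(
    master_seed: int,
    diameter_index: int,
    porosity_index: int,
    realization_index: int,
) -> np.random.SeedSequence:
    """Derive the seed for a single phantom from a master seed.

    Uses :class:`numpy.random.SeedSequence` with a documented spawn key
    ``(diameter_index, porosity_index, realization_index)`` so that any
    individual phantom in a sweep is regenerable in isolation.
    """
    return np.random.SeedSequence(master_seed, spawn_key=(diameter_index, porosity_index, realization_index))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters defining one phantom realization.

    ``extent`` is the physical slab size in mm; its length sets the
    dimensionality (2 -> planar x/z phantom with circular pores, 3 ->
    volumetric phantom with spherical pores).  The last axis is always
    the propagation axis z.
    """

    extent: tuple[float, ...] = (12.8, 12.8, 5.0)
    voxel_size: float = 0.05
    pore_diameter: float = 0.4
    target_porosity: float = 0.0
    seed: int | np.random.SeedSequence = 0
    realization_index: int = 0

    def __post_init__(self) -> None:
        if len(self.extent) not in (1, 2, 3):
            raise ValueError("extent must have 1-3 components")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        for e in self.extent:
            n = e / self.voxel_size
            if abs(n - round(n)) > 1e-6:
                raise ValueError(f"extent component {e} mm is not divisible by voxel_size {self.voxel_size} mm")
        if self.pore_diameter < 2 * self.voxel_size:
            raise ValueError("pore_diameter must be at least two voxels")
        if not (0.0 <= self.target_porosity < 1.0):
            raise ValueError("target_porosity must lie in [0, 1)")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(int(round(e / self.voxel_size)) for e in self.extent)

    @property
    def ndim(self) -> int:
        return len(self.extent)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class LabelVolume:
    """Voxel grid of material labels (0 water, 1 marrow, 2 cortical)."""

    labels: np.ndarray
    voxel_size: float
    achieved_porosity: float
    spec: PhantomSpec | None = None
    origin_offset: int = 10  # placement of the slab along z, in voxels of the simulation grid

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.size and self.labels.max() > LABEL_CORTICAL:
            raise ValueError("labels must take values in {0, 1, 2}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def face_positions_mm(self) -> tuple[float, float]:
        """z positions (mm, simulation-grid frame) of the slab faces."""
        z0 = self.origin_offset * self.voxel_size
        return (z0, z0 + self.labels.shape[-1] * self.voxel_size)


def measure_porosity(vol: LabelVolume | np.ndarray) -> float:
    """Marrow voxel count over the bone-region (marrow + cortical) count."""
    labels = vol.labels if isinstance(vol, LabelVolume) else np.asarray(vol)
    n_marrow = int(np.count_nonzero(labels == LABEL_MARROW))
    n_cortical = int(np.count_nonzero(labels == LABEL_CORTICAL))
    if n_marrow + n_cortical == 0:
        raise ValueError("porosity undefined: volume contains no bone-region voxels")
    return n_marrow / (n_marrow + n_cortical)


def single_pore_volume_fraction(spec: PhantomSpec) -> float:
    """Analytic volume fraction of one unclipped pore relative to the slab.

    For 3D, a sphere of diameter d; for 2D, a disk.  This bounds the
    per-pore porosity increment, hence the possible overshoot of the
    stop-at-target rule (up to voxelization error).
    """
    r = spec.pore_diameter / 2.0
    slab = float(np.prod(spec.extent))
    if spec.ndim == 3:
        return (4.0 / 3.0) * math.pi * r**3 / slab
    if spec.ndim == 2:
        return math.pi * r**2 / slab
    return spec.pore_diameter / slab


def _pore_voxel_bound(spec: PhantomSpec) -> int:
    """Upper bound on voxels converted by a single pore (any center offset)."""
    # every converted voxel center lies within r of the pore center, so the
    # voxel cubes are contained in a ball of radius r + half voxel diagonal
    r = spec.pore_diameter / 2.0 + spec.voxel_size * math.sqrt(spec.ndim) / 2.0
    if spec.ndim == 3:
        vol = (4.0 / 3.0) * math.pi * r**3
    elif spec.ndim == 2:
        vol = math.pi * r**2
    else:
        vol = 2 * r
    return int(math.ceil(vol / spec.voxel_size**spec.ndim))


def generate_planar_phantom(spec: PhantomSpec, max_pores: int | None = None) -> LabelVolume:
    """Generate one planar slab phantom by sequential random pore placement.

    Pores of fixed diameter ``spec.pore_diameter`` are placed one at a
    time with centers drawn uniformly over the slab interior (continuous
    coordinates); a voxel becomes marrow when its center lies within d/2
    of any pore center.  Spheres are clipped at the slab faces.
    Placement stops at the first pore whose addition brings the achieved
    porosity to or above ``spec.target_porosity``.

    Deterministic for a given ``spec`` (including seed).

    Raises
    ------
    PhantomGenerationError
        If the target is not reached within ``max_pores`` placements.
    """
    shape = spec.shape
    labels = np.full(shape, LABEL_CORTICAL, dtype=np.uint8)
    total = labels.size
    if spec.target_porosity == 0.0:
        return LabelVolume(labels, spec.voxel_size, achieved_porosity=0.0, spec=spec)

    rng = spec.rng()
    r = spec.pore_diameter / 2.0
    dx = spec.voxel_size
    extent = np.asarray(spec.extent)

    if max_pores is None:
        # expected pore count for overlapping coverage 1 - exp(-n v / V),
        # padded generously; still finite so impossible targets fail fast
        v_frac = single_pore_volume_fraction(spec)
        expected = -math.log(max(1e-12, 1.0 - spec.target_porosity)) / v_frac
        max_pores = int(50 * expected) + 1000

    # precompute per-axis voxel-center coordinate arrays once
    centers_ax = [(np.arange(n) + 0.5) * dx for n in shape]

    marrow = 0
    target_count = spec.target_porosity * total
    for _ in range(max_pores):
        c = rng.uniform(0.0, 1.0, size=spec.ndim) * extent
        lo = [max(0, int(math.floor((c[a] - r) / dx - 0.5))) for a in range(spec.ndim)]
        hi = [min(shape[a], int(math.ceil((c[a] + r) / dx + 0.5))) for a in range(spec.ndim)]
        window = tuple(slice(lo[a], hi[a]) for a in range(spec.ndim))
        d2 = np.zeros(tuple(h - l for l, h in zip(lo, hi)))
        for a in range(spec.ndim):
            ax_shape = [1] * spec.ndim
            ax_shape[a] = -1
            d2 = d2 + ((centers_ax[a][lo[a]:hi[a]] - c[a]) ** 2).reshape(ax_shape)
        inside = d2 <= r * r
        sub = labels[window]
        converted = int(np.count_nonzero(sub[inside] == LABEL_CORTICAL))
        if converted:
            sub[inside] = LABEL_MARROW
            marrow += converted
        if marrow >= target_count:
            return LabelVolume(labels, dx, achieved_porosity=marrow / total, spec=spec)

    raise PhantomGenerationError(
        f"target porosity {spec.target_porosity} not reached after {max_pores} pores "
        f"(achieved {marrow / total:.4f})"
    )


# ---------------------------------------------------------------------------
# curved shell masks


@dataclass(frozen=True)
class ShellSpec:
    """Spherical-cap shell with angular thickness variation.

    The shell is a section of a spherical annulus whose center sits
    behind the volume on the propagation axis, so the surfaces curve
    toward the source.  ``erosion_depth`` mm is removed from both tables
    before the mask is produced, mirroring the removal of cortical
    layers from segmented bone.
    """

    curvature_radius: float = 40.0  # mm, outer-table radius at the apex
    nominal_thickness: float = 4.0  # mm, before erosion
    thickness_variation: float = 0.3  # mm, amplitude of smooth angular variation
    erosion_depth: float = 1.0  # mm, removed from each table
    apex_depth: float = 0.4  # mm, z of the outer-table apex inside the volume
    variation_cycles: tuple[float, float] = (1.5, 1.0)  # transverse cycles of variation
    seed: int = 0
    name: str = "shell"

    def __post_init__(self) -> None:
        worst = self.nominal_thickness - self.thickness_variation - 2 * self.erosion_depth
        if worst <= 0:
            raise ValueError(
                "degenerate shell: minimum thickness must exceed twice the erosion depth"
            )

    @property
    def eroded_thickness(self) -> float:
        return self.nominal_thickness - 2 * self.erosion_depth


#: Synthetic stand-ins for the three bone shapes; thickness ordering
#: frontal > parietal > temporal.
SHELL_PRESETS: dict[str, ShellSpec] = {
    "temporal": ShellSpec(curvature_radius=35.0, nominal_thickness=3.0, thickness_variation=0.25, seed=11, name="temporal"),
    "parietal": ShellSpec(curvature_radius=42.0, nominal_thickness=4.0, thickness_variation=0.30, seed=12, name="parietal"),
    "frontal": ShellSpec(curvature_radius=48.0, nominal_thickness=4.8, thickness_variation=0.35, seed=13, name="frontal"),
}


def shell_thickness_field(shell: ShellSpec, coords: Sequence[np.ndarray], extent: Sequence[float]) -> np.ndarray:
    """Smooth spatially varying shell thickness (mm) over transverse coords."""
    rng = np.random.default_rng(np.random.SeedSequence(shell.seed, spawn_key=(7,)))
    phases = rng.uniform(0, 2 * math.pi, size=len(coords))
    t = np.zeros(())
    for a, x in enumerate(coords):
        cyc = shell.variation_cycles[a % len(shell.variation_cycles)]
        t = t + np.sin(2 * math.pi * cyc * x / extent[a] + phases[a])
    # normalize the sum of sines to [-1, 1]
    t = t / max(1, len(coords))
    return shell.nominal_thickness + shell.thickness_variation * t


def generate_shell_mask(
    shell: ShellSpec,
    grid_shape: tuple[int, ...],
    voxel_size: float = 0.05,
) -> np.ndarray:
    """Boolean occupancy mask of the eroded shell on a voxel grid.

    ``grid_shape`` is (nx, nz) or (nx, ny, nz); the last axis is the
    propagation axis.  The mask is True inside the shell solid after
    eroding ``erosion_depth`` from both tables.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    ndim = len(grid_shape)
    if ndim not in (2, 3):
        raise ValueError("shell masks are 2D or 3D")
    extent = [n * voxel_size for n in grid_shape]
    # sphere center on the propagation axis, beyond the volume
    center_trans = [e / 2.0 for e in extent[:-1]]
    zc = shell.apex_depth + shell.curvature_radius

    axes = [(np.arange(n) + 0.5) * voxel_size for n in grid_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    trans = mesh[:-1]
    z = mesh[-1]
    r2 = (zc - z) ** 2
    for x, cx in zip(trans, center_trans):
        r2 = r2 + (x - cx) ** 2
    rad = np.sqrt(r2)

    thick = shell_thickness_field(shell, [(x - cx) for x, cx in zip(trans, center_trans)], extent[:-1])
    outer = shell.curvature_radius - shell.erosion_depth
    inner = shell.curvature_radius - thick + shell.erosion_depth
    mask = (rad <= outer) & (rad >= inner)

    if not mask.any():
        raise ValueError("shell does not intersect the grid")
    deepest = shell.apex_depth + shell.nominal_thickness - shell.erosion_depth
    if deepest > extent[-1]:
        raise ValueError("shell does not fit in the grid along the propagation axis")
    n_components = ndimage.label(mask)[1]
    if n_components != 1:
        raise ValueError(f"shell mask is not a single connected component ({n_components} pieces)")
    return mask


def analytic_shell_volume(
    shell: ShellSpec,
    grid_shape: tuple[int, ...],
    voxel_size: float = 0.05,
    n_samples: int = 400_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate (mm^3 or mm^2) of the eroded shell solid inside
    the grid box — an oracle independent of voxelization."""
    grid_shape = tuple(int(n) for n in grid_shape)
    extent = [n * voxel_size for n in grid_shape]
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 1, size=(n_samples, len(grid_shape))) * np.asarray(extent)
    center_trans = [e / 2.0 for e in extent[:-1]]
    zc = shell.apex_depth + shell.curvature_radius
    r2 = (zc - pts[:, -1]) ** 2
    for a, cx in enumerate(center_trans):
        r2 = r2 + (pts[:, a] - cx) ** 2
    rad = np.sqrt(r2)
    thick = shell_thickness_field(shell, [pts[:, a] - cx for a, cx in enumerate(center_trans)], extent[:-1])
    outer = shell.curvature_radius - shell.erosion_depth
    inner = shell.curvature_radius - thick + shell.erosion_depth
    inside = (rad <= outer) & (rad >= inner)
    box = float(np.prod(extent))
    return box * float(np.count_nonzero(inside)) / n_samples


def apply_mask(vol: LabelVolume, mask: np.ndarray) -> LabelVolume:
    """Set labels outside ``mask`` to water and re-measure porosity in-mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.labels.shape:
        raise ValueError(f"mask shape {mask.shape} does not match labels {vol.labels.shape}")
    if not mask.any():
        raise ValueError("empty mask")
    labels = vol.labels.copy()
    labels[~mask] = LABEL_WATER
    achieved = measure_porosity(labels)
    out = replace_labels(vol, labels)
    out.achieved_porosity = achieved
    return out


def replace_labels(vol: LabelVolume, labels: np.ndarray) -> LabelVolume:
    return LabelVolume(
        labels=labels,
        voxel_size=vol.voxel_size,
        achieved_porosity=vol.achieved_porosity,
        spec=vol.spec,
        origin_offset=vol.origin_offset,
    )
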