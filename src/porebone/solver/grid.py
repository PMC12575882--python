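"""Simulation grid, plane-wave source and time-step/duration rules."""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SimGrid",
    "SourceConfig",
    "TimeSettings",
    "time_settings",
    "plane_wave_signal",
    "DEFAULT_GRID_3D",
    "duration_rule",
    "default_cfl",
]

#: Slowest constituent speed of sound (m/s); sets the time-of-flight rule.
SLOWEST_SPEED = 1450.0

#: CFL numbers: nonabsorbing runs, and absorbing runs per source frequency.
CFL_NONABSORBING = 0.3
CFL_ABSORBING_HIGH = 0.06  # 650 kHz
CFL_ABSORBING_LOW = 0.02  # 230 kHz


@dataclass(frozen=True)
class SimGrid:
    """Regular interior grid; the last axis (z) is the propagation axis.

    ``dims`` exclude the absorbing end layers, which the solver pads
    onto both z-faces.  Transverse axes are periodic with no layers.
    The default reproduces a 12.8 x 12.8 x 7.6 mm volume at 0.05 mm
    isotropic spacing with the 5 mm phantom slab starting 10 voxels
    (0.5 mm) into the grid.
    """

    dims: tuple[int, ...] = (256, 256, 152)
    spacing: float = 0.05  # mm
    pml_thickness: int = 20  # voxels, z-faces only
    pml_absorption: float = 2.0  # Np/voxel profile scale
    slab_offset: int = 10  # z voxel where the phantom slab starts

    def __post_init__(self) -> None:
        if len(self.dims) not in (1, 2, 3):
            raise ValueError("grids are 1D, 2D or 3D")
        if any(n < 1 for n in self.dims):
            raise ValueError("grid dims must be positive")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.pml_thickness < 1:
            raise ValueError("pml_thickness must be at least one voxel")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def nz(self) -> int:
        return self.dims[-1]

    @property
    def extent_mm(self) -> tuple[float, ...]:
        return tuple(n * self.spacing for n in self.dims)

    @property
    def diagonal_mm(self) -> float:
        return math.sqrt(sum(e**2 for e in self.extent_mm))

    @property
    def dx(self) -> float:
        """Spacing in meters."""
        return self.spacing * 1e-3

    def z_axis_mm(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.spacing


DEFAULT_GRID_3D = SimGrid()


@dataclass(frozen=True)
class SourceConfig:
    """Continuous uniform plane pressure source at the front z plane."""

    frequency: float  # Hz
    amplitude: float = 1.0e6  # Pa
    ramp_cycles: int = 4
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.ramp_cycles < 0:
            raise ValueError("ramp_cycles must be non-negative")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency


def default_cfl(frequency: float, absorbing: bool) -> float:
    """CFL number by run type: 0.3 nonabsorbing; 0.06 (>=500 kHz) or
    0.02 (<500 kHz) for absorbing runs."""
    if not absorbing:
        return CFL_NONABSORBING
    return CFL_ABSORBING_HIGH if frequency >= 500e3 else CFL_ABSORBING_LOW


#: Diagonal (mm) of the full-scale 12.8 x 12.8 x 7.6 mm study grid.
REFERENCE_DIAGONAL_MM = math.sqrt(12.8**2 + 12.8**2 + 7.6**2)


def duration_rule(frequency: float, grid: SimGrid, ramp_cycles: int = 4) -> float:
    """Simulation duration: a multiple of the grid-diagonal time of flight
    at the slowest constituent speed — 2.5x below 500 kHz (longer
    wavelengths take longer to settle), 2x at and above.

    Reduced grids keep the full-scale z-extent but have much shorter
    diagonals, which would starve them of settling time, so the diagonal
    is floored at the full-scale reference value (giving every grid the
    study's 27/34 us durations) and the result at the source ramp time
    plus three z transits.  Both floors are inactive for grids at or
    above the full-scale diagonal.
    """
    multiplier = 2.0 if frequency >= 500e3 else 2.5
    diag = max(grid.diagonal_mm, REFERENCE_DIAGONAL_MM)
    rule = multiplier * (diag * 1e-3) / SLOWEST_SPEED
    floor = ramp_cycles / frequency + 3.0 * (grid.extent_mm[-1] * 1e-3) / SLOWEST_SPEED
    return max(rule, floor)


@dataclass(frozen=True)
class TimeSettings:
    """Time step, duration and steady-state sensing window."""

    cfl: float
    dt: float  # s
    duration: float  # s
    steady_periods: float = 2.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")

    @property
    def n_steps(self) -> int:
        return int(math.ceil(self.duration / self.dt))

    def steady_window_steps(self, frequency: float) -> int:
        """Number of trailing steps covering the steady-state window."""
        return min(self.n_steps, int(math.ceil(self.steady_periods / frequency / self.dt)))

    def with_cfl(self, cfl: float) -> "TimeSettings":
        return replace(self, cfl=cfl, dt=self.dt * cfl / self.cfl)

    def with_duration(self, duration: float) -> "TimeSettings":
        return replace(self, duration=duration)


def time_settings(
    frequency: float,
    grid: SimGrid,
    c_max: float,
    absorbing: bool = False,
    cfl: float | None = None,
    duration: float | None = None,
) -> TimeSettings:
    """Build :class:`TimeSettings` from the CFL table and duration rule.

    ``c_max`` is the fastest speed of sound present in the medium; for
    matched phantom/water comparisons pass the phantom's ``c_max`` to
    both so the records share a time axis.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if c_max <= 0:
        raise ValueError("c_max must be positive")
    if cfl is None:
        cfl = default_cfl(frequency, absorbing)
    dt = cfl * grid.dx / c_max
    if duration is None:
        duration = duration_rule(frequency, grid)
    return TimeSettings(cfl=cfl, dt=dt, duration=duration)


def plane_wave_signal(src: SourceConfig, t_axis: np.ndarray) -> np.ndarray:
    """Source pressure time series: A * ramp(t) * sin(2*pi*f*t + phase).

    The ramp is a raised cosine rising smoothly from 0 to 1 over exactly
    ``ramp_cycles`` source periods, then held at 1.
    """
    t = np.asarray(t_axis, dtype=float)
    ramp_time = src.ramp_cycles * src.period
    if ramp_time > 0:
        ramp = np.where(t < ramp_time, 0.5 * (1.0 - np.cos(np.pi * np.minimum(t, ramp_time) / ramp_time)), 1.0)
    else:
        ramp = np.ones_like(t)
    return src.amplitude * ramp * np.sin(2.0 * np.pi * src.frequency * t + src.phase)
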