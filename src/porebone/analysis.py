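"""Insertion loss, axial profiles, standing-wave metrics and loss curves."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from porebone.materials import MaterialTable
from porebone.solver.pstd import PressureRecord

__all__ = [
    "LOSS_TABLE_COLUMNS",
    "AxialProfile",
    "StandingWaveMetrics",
    "insertion_loss",
    "axial_mean_profile",
    "standing_wave_metrics",
    "aggregate_loss_curves",
    "porosity_to_density_hu",
    "convergence_diff",
    "NegativeLossWarning",
]

#: Column names of the tidy loss table (one row per completed simulation cell).
LOSS_TABLE_COLUMNS = (
    "frequency_hz",
    "pore_diameter_mm",
    "nominal_porosity",
    "achieved_porosity",
    "realization",
    "absorbing",
    "insertion_loss_pct",
    "plane_mean_pressure_pa",
)


class NegativeLossWarning(UserWarning):
    """Scattering locally raised the plane mean above the water reference."""


def insertion_loss(phantom_rec: PressureRecord, water_rec: PressureRecord) -> float:
    """Insertion loss in percent: 100 * (1 - P_phantom / P_water).

    Both records must share grid shape, frequency and time step; the
    mean steady-state maximum pressure is taken over the measurement
    plane (the last interior transverse plane, in water).  Negative
    values are possible for heterogeneous media and are flagged with a
    :class:`NegativeLossWarning` rather than clipped.
    """
    if phantom_rec.shape != water_rec.shape:
        raise ValueError("records are on different grids")
    if phantom_rec.frequency != water_rec.frequency:
        raise ValueError("records have different source frequencies")
    if phantom_rec.time_settings.dt != water_rec.time_settings.dt:
        raise ValueError("records have different time steps")
    p_water = water_rec.plane_mean()
    if p_water <= 0:
        raise ValueError("water reference plane mean is non-positive")
    loss = 100.0 * (1.0 - phantom_rec.plane_mean() / p_water)
    if loss < 0:
        warnings.warn(f"negative insertion loss {loss:.3f}%", NegativeLossWarning, stacklevel=2)
    return loss


@dataclass
class AxialProfile:
    """Transverse-mean pressure along the propagation axis."""

    z_mm: np.ndarray
    mean_pressure: np.ndarray  # Pa
    face_positions_mm: tuple[float, float] | None = None

    def __len__(self) -> int:
        return len(self.z_mm)


def axial_mean_profile(
    rec: PressureRecord,
    face_positions_mm: tuple[float, float] | None = None,
) -> AxialProfile:
    """Mean steady-state pressure over each transverse plane.

    All interior voxels in a plane are averaged, bone included; the
    absorbing end layers are already excluded from the record.
    """
    field = rec.max_pressure
    axes = tuple(range(field.ndim - 1))
    mean = field.mean(axis=axes) if axes else field.copy()
    z = (np.arange(field.shape[-1]) + 0.5) * rec.spacing
    return AxialProfile(z_mm=z, mean_pressure=mean, face_positions_mm=face_positions_mm)


@dataclass
class StandingWaveMetrics:
    """Peak/valley statistics of an axial profile between the slab faces."""

    amplitude: float  # Pa, mean(peaks) - mean(valleys)
    mean_peak_spacing_mm: float | None  # None when fewer than two peaks
    peak_count: int


def standing_wave_metrics(
    profile: AxialProfile,
    smoothing_voxels: int = 3,
    detrend_order: int = 2,
    min_relative_prominence: float = 0.01,
) -> StandingWaveMetrics:
    """Locate interference extrema between the marked slab faces.

    The in-slab profile is lightly smoothed with a
    ``smoothing_voxels``-wide moving average, and a polynomial baseline
    of order ``detrend_order`` is removed so the monotone decay through
    a scattering slab is not mistaken for oscillation.  Peaks and
    valleys of the residual with prominence of at least
    ``min_relative_prominence`` times the baseline level count as
    standing-wave extrema; amplitude is mean(peaks) - mean(valleys) of
    the residual, spacing the mean inter-peak distance (``None`` when
    fewer than two peaks are found).
    """
    if profile.face_positions_mm is None:
        raise ValueError("profile has no marked slab faces")
    z0, z1 = profile.face_positions_mm
    inside = (profile.z_mm >= z0) & (profile.z_mm <= z1)
    y = profile.mean_pressure[inside].astype(float)
    z = profile.z_mm[inside]
    if y.size < max(5, detrend_order + 2):
        raise ValueError("too few samples between the faces")
    if smoothing_voxels > 1:
        kernel = np.ones(smoothing_voxels) / smoothing_voxels
        y = np.convolve(y, kernel, mode="same")
        y[: smoothing_voxels // 2] = y[smoothing_voxels // 2]
        y[-(smoothing_voxels // 2) or len(y):] = y[-(smoothing_voxels // 2) - 1]

    baseline = np.polyval(np.polyfit(z, y, detrend_order), z)
    resid = y - baseline
    prominence = min_relative_prominence * max(float(np.abs(baseline).mean()), 1e-300)
    peaks, _ = find_peaks(resid, prominence=prominence)
    valleys, _ = find_peaks(-resid, prominence=prominence)
    if len(peaks) == 0:
        return StandingWaveMetrics(amplitude=0.0, mean_peak_spacing_mm=None, peak_count=0)
    low = float(resid[valleys].mean()) if len(valleys) else float(resid.min())
    amp = float(resid[peaks].mean()) - low
    dz = float(z[1] - z[0])
    spacing = float(np.diff(peaks).mean() * dz) if len(peaks) >= 2 else None
    return StandingWaveMetrics(amplitude=amp, mean_peak_spacing_mm=spacing, peak_count=int(len(peaks)))


def aggregate_loss_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse realizations into per-(frequency, diameter, porosity) curves.

    Returns one row per cell with the sample mean and sample standard
    deviation (ddof=1) of the insertion loss, the mean achieved porosity
    (the x position of the plotted point) and the realization count.
    Cells with a single realization get std 0 and ``degenerate=True``.
    """
    if len(table) == 0:
        raise ValueError("empty loss table")
    grouped = table.groupby(["frequency_hz", "pore_diameter_mm", "nominal_porosity"], as_index=False)
    out = grouped.agg(
        mean_loss_pct=("insertion_loss_pct", "mean"),
        std_loss_pct=("insertion_loss_pct", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_achieved_porosity=("achieved_porosity", "mean"),
        n_realizations=("insertion_loss_pct", "size"),
    )
    out["degenerate"] = out["n_realizations"] < 2
    return out


def porosity_to_density_hu(
    porosity: float | np.ndarray,
    mat: MaterialTable | None = None,
    hu_anchors: tuple[tuple[float, float], tuple[float, float]] = ((1000.0, 0.0), (1908.0, 1500.0)),
) -> tuple[np.ndarray, np.ndarray]:
    """Map porosity to (average density, Hounsfield units).

    Density interpolates linearly between cortical (porosity 0) and
    marrow (porosity 1); HU is linear in density between two
    configurable ``(density, HU)`` anchor points (defaults: water at
    0 HU, cortical bone at a nominal high anchor).  Presentation-only —
    this mapping never feeds the simulation.
    """
    mat = MaterialTable() if mat is None else mat
    phi = np.asarray(porosity, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("porosity must lie in [0, 1]")
    density = phi * mat.marrow.density + (1.0 - phi) * mat.cortical.density
    (d0, h0), (d1, h1) = hu_anchors
    if d1 == d0:
        raise ValueError("degenerate HU anchors")
    hu = h0 + (density - d0) * (h1 - h0) / (d1 - d0)
    return density, hu


def convergence_diff(rec_a: PressureRecord, rec_b: PressureRecord) -> float:
    """Percentage difference of measurement-plane means: 100|a - b| / b."""
    if rec_a.shape != rec_b.shape:
        raise ValueError("records are on different grids")
    mean_b = rec_b.plane_mean()
    if mean_b == 0:
        raise ValueError("reference plane mean is zero")
    return 100.0 * abs(rec_a.plane_mean() - mean_b) / mean_b
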