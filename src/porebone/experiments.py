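"""Sweep orchestration: porosity/pore-diameter grids, convergence tests,
and the curved-shell study, driven from a single config.

Execution scales
----------------
``full3d``
    The full-size study geometry (12.8 x 12.8 x 5 mm slab at 0.05 mm in
    a 256 x 256 x 152 grid).  Hours-to-days on one CPU; opt-in.
``reduced2d``
    An x-z section (6.4 x 5 mm slab, 128 x 152 grid) with circular
    pores.  Minutes; preserves trends but is not equivalent to 3D.
``coarse3d``
    A 0.1 mm, 6.4 x 6.4 x 5 mm 3D slab; only pore diameters >= 0.4 mm
    are resolvable.  Flagged non-equivalent to the full-scale results.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from porebone.analysis import LOSS_TABLE_COLUMNS, convergence_diff, insertion_loss
from porebone.materials import MaterialTable
from porebone.phantoms import (
    SHELL_PRESETS,
    STANDARD_PORE_DIAMETERS,
    STANDARD_POROSITIES,
    LabelVolume,
    PhantomSpec,
    ShellSpec,
    apply_mask,
    generate_planar_phantom,
    generate_shell_mask,
    phantom_seed,
)
from porebone.solver.grid import SimGrid, SourceConfig, time_settings
from porebone.solver.medium import assign_materials
from porebone.solver.pstd import PressureRecord, SolverError, run_simulation, water_reference

__all__ = [
    "SweepConfig",
    "ScalePreset",
    "SCALE_PRESETS",
    "run_sweep",
    "convergence_suite",
    "shell_study",
]


@dataclass(frozen=True)
class ScalePreset:
    """Phantom extent (mm), voxel size (mm) and simulation grid for a scale."""

    phantom_extent: tuple[float, ...]
    voxel_size: float
    grid: SimGrid
    equivalent_to_full: bool


SCALE_PRESETS: dict[str, ScalePreset] = {
    "full3d": ScalePreset((12.8, 12.8, 5.0), 0.05, SimGrid(dims=(256, 256, 152), spacing=0.05), True),
    "reduced2d": ScalePreset((6.4, 5.0), 0.05, SimGrid(dims=(128, 152), spacing=0.05), False),
    "coarse3d": ScalePreset(
        (6.4, 6.4, 5.0), 0.1, SimGrid(dims=(64, 64, 76), spacing=0.1, slab_offset=5), False
    ),
}


@dataclass
class SweepConfig:
    """One config object drives sweeps, convergence tests and shell runs."""

    frequencies: tuple[float, ...] = (650e3,)
    pore_diameters: tuple[float, ...] = STANDARD_PORE_DIAMETERS
    porosities: tuple[float, ...] = STANDARD_POROSITIES
    realizations: int = 5
    absorbing: bool = False
    scale: str = "reduced2d"
    master_seed: int = 0
    output_dir: str | Path | None = None
    amplitude: float = 1.0e6
    cfl: float | None = None
    transverse_voxels: int | None = None  # override for desk-scale runs
    save_artifacts: bool = False
    progress: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale {self.scale!r}; choose from {sorted(SCALE_PRESETS)}")
        if self.realizations < 1:
            raise ValueError("realizations must be >= 1")

    @property
    def preset(self) -> ScalePreset:
        preset = SCALE_PRESETS[self.scale]
        if self.transverse_voxels is not None:
            nt = self.transverse_voxels
            dims = tuple([nt] * (len(preset.grid.dims) - 1) + [preset.grid.dims[-1]])
            extent = tuple(
                [nt * preset.voxel_size] * (len(preset.phantom_extent) - 1)
                + [preset.phantom_extent[-1]]
            )
            preset = replace(preset, phantom_extent=extent, grid=replace(preset.grid, dims=dims))
        return preset

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        for key in ("frequencies", "pore_diameters", "porosities"):
            if key in kwargs:
                kwargs[key] = tuple(float(v) for v in kwargs[key])
        return cls(**kwargs)


class _SweepRunner:
    """Shared plumbing: phantom cache, timing, per-cell execution, logging."""

    def __init__(self, cfg: SweepConfig, mat: MaterialTable | None = None) -> None:
        self.cfg = cfg
        self.mat = mat or MaterialTable()
        self.preset = cfg.preset
        self.grid = self.preset.grid
        self._phantoms: dict[tuple, LabelVolume] = {}
        self._log_fh = None
        if cfg.output_dir is not None:
            out = Path(cfg.output_dir)
            out.mkdir(parents=True, exist_ok=True)
            self._log_fh = open(out / "cells.jsonl", "a")

    def log(self, **entry) -> None:
        if self._log_fh is not None:
            self._log_fh.write(json.dumps(entry) + "\n")
            self._log_fh.flush()

    def close(self) -> None:
        if self._log_fh is not None:
            self._log_fh.close()

    def phantom(self, di: int, pi: int, realization: int) -> LabelVolume:
        key = (di, pi, realization)
        vol = self._phantoms.get(key)
        if vol is None:
            spec = PhantomSpec(
                extent=self.preset.phantom_extent,
                voxel_size=self.preset.voxel_size,
                pore_diameter=self.cfg.pore_diameters[di],
                target_porosity=self.cfg.porosities[pi],
                seed=phantom_seed(self.cfg.master_seed, di, pi, realization),
                realization_index=realization,
            )
            vol = generate_planar_phantom(spec)
            vol.origin_offset = self.grid.slab_offset
            self._phantoms[key] = vol
        return vol

    def timing(self, frequency: float, cfl: float | None = None, duration: float | None = None):
        c_max = self.mat.cortical.speed_of_sound
        return time_settings(
            frequency,
            self.grid,
            c_max=c_max,
            absorbing=self.cfg.absorbing,
            cfl=cfl if cfl is not None else self.cfg.cfl,
            duration=duration,
        )

    def run_cell(self, vol: LabelVolume, frequency: float, ts, src: SourceConfig) -> tuple[PressureRecord, PressureRecord]:
        medium = assign_materials(vol, self.mat, self.cfg.absorbing, frequency, grid=self.grid)
        rec = run_simulation(medium, src, ts, self.grid)
        wrec = water_reference(src, ts, self.grid, self.mat)
        return rec, wrec


def run_sweep(cfg: SweepConfig, mat: MaterialTable | None = None) -> pd.DataFrame:
    """Execute the (frequency x diameter x porosity x realization) sweep.

    Returns the tidy loss table (one row per completed cell; failed
    cells keep their row with NaN loss and are logged).  Deterministic
    given ``cfg.master_seed``; phantoms and water references are cached
    and shared across frequencies / cells.
    """
    runner = _SweepRunner(cfg, mat)
    rows = []
    try:
        for frequency in cfg.frequencies:
            src = SourceConfig(frequency=frequency, amplitude=cfg.amplitude)
            ts = runner.timing(frequency)
            for di in range(len(cfg.pore_diameters)):
                for pi in range(len(cfg.porosities)):
                    for r in range(cfg.realizations):
                        t0 = time.perf_counter()
                        vol = runner.phantom(di, pi, r)
                        row = {
                            "frequency_hz": frequency,
                            "pore_diameter_mm": cfg.pore_diameters[di],
                            "nominal_porosity": cfg.porosities[pi],
                            "achieved_porosity": vol.achieved_porosity,
                            "realization": r,
                            "absorbing": cfg.absorbing,
                        }
                        try:
                            rec, wrec = runner.run_cell(vol, frequency, ts, src)
                            row["insertion_loss_pct"] = insertion_loss(rec, wrec)
                            row["plane_mean_pressure_pa"] = rec.plane_mean()
                            status = "ok"
                        except SolverError as exc:
                            row["insertion_loss_pct"] = np.nan
                            row["plane_mean_pressure_pa"] = np.nan
                            status = f"failed: {exc}"
                        rows.append(row)
                        runner.log(
                            status=status,
                            scale=cfg.scale,
                            elapsed_s=round(time.perf_counter() - t0, 3),
                            **{k: v for k, v in row.items() if k != "absorbing"},
                        )
                        if cfg.progress:
                            print(
                                f"[sweep] f={frequency/1e3:.0f}k d={cfg.pore_diameters[di]} "
                                f"phi={cfg.porosities[pi]} r={r} -> {row['insertion_loss_pct']:.2f}% "
                                f"({time.perf_counter() - t0:.1f}s)",
                                flush=True,
                            )
    finally:
        runner.close()
    table = pd.DataFrame(rows, columns=list(LOSS_TABLE_COLUMNS))
    table["scale"] = cfg.scale
    if cfg.output_dir is not None:
        table.to_csv(Path(cfg.output_dir) / "loss_table.csv", index=False)
    return table


def convergence_suite(cfg: SweepConfig, mat: MaterialTable | None = None) -> pd.DataFrame:
    """Convergence tests on the representative phantom suite.

    For each frequency and each phantom in the (diameters x porosities)
    grid of ``cfg`` (realization 0), runs a reference simulation plus
    two perturbed ones — duration doubled, CFL halved — and reports the
    maximum measurement-plane percentage difference across phantoms.
    """
    runner = _SweepRunner(cfg, mat)
    rows = []
    try:
        for frequency in cfg.frequencies:
            src = SourceConfig(frequency=frequency, amplitude=cfg.amplitude)
            ts_ref = runner.timing(frequency)
            variants = {
                "duration_x2": runner.timing(frequency, duration=2.0 * ts_ref.duration),
                "cfl_half": ts_ref.with_cfl(ts_ref.cfl / 2.0),
            }
            diffs: dict[str, list[float]] = {name: [] for name in variants}
            for di in range(len(cfg.pore_diameters)):
                for pi in range(len(cfg.porosities)):
                    vol = runner.phantom(di, pi, 0)
                    rec_ref, _ = runner.run_cell(vol, frequency, ts_ref, src)
                    for name, ts_test in variants.items():
                        rec_test, _ = runner.run_cell(vol, frequency, ts_test, src)
                        diffs[name].append(convergence_diff(rec_test, rec_ref))
            for name, values in diffs.items():
                rows.append(
                    {
                        "frequency_hz": frequency,
                        "test": name,
                        "max_diff_pct": max(values),
                        "n_phantoms": len(values),
                    }
                )
                runner.log(test=name, frequency_hz=frequency, max_diff_pct=max(values))
    finally:
        runner.close()
    return pd.DataFrame(rows)


def shell_study(
    cfg: SweepConfig,
    presets: dict[str, ShellSpec] | None = None,
    mat: MaterialTable | None = None,
) -> pd.DataFrame:
    """Loss through shell-masked phantoms for each preset bone shape.

    Produces one row per (shape, porosity, diameter) with the default
    3 x 3 x 3 grid of the shell study.
    """
    presets = SHELL_PRESETS if presets is None else presets
    if cfg.pore_diameters == STANDARD_PORE_DIAMETERS:
        cfg = replace(cfg, pore_diameters=(0.2, 0.4, 0.6))
    if cfg.porosities == STANDARD_POROSITIES:
        cfg = replace(cfg, porosities=(0.10, 0.30, 0.50))
    runner = _SweepRunner(cfg, mat)
    masks = {
        name: generate_shell_mask(spec, runner.preset.grid.dims[:-1] + (runner.phantom(0, 0, 0).shape[-1],), runner.preset.voxel_size)
        for name, spec in presets.items()
    }
    rows = []
    try:
        for frequency in cfg.frequencies:
            src = SourceConfig(frequency=frequency, amplitude=cfg.amplitude)
            ts = runner.timing(frequency)
            for name, mask in masks.items():
                for di in range(len(cfg.pore_diameters)):
                    for pi in range(len(cfg.porosities)):
                        vol = apply_mask(runner.phantom(di, pi, 0), mask)
                        rec, wrec = runner.run_cell(vol, frequency, ts, src)
                        rows.append(
                            {
                                "frequency_hz": frequency,
                                "bone_shape": name,
                                "pore_diameter_mm": cfg.pore_diameters[di],
                                "nominal_porosity": cfg.porosities[pi],
                                "achieved_porosity": vol.achieved_porosity,
                                "realization": 0,
                                "absorbing": cfg.absorbing,
                                "insertion_loss_pct": insertion_loss(rec, wrec),
                                "plane_mean_pressure_pa": rec.plane_mean(),
                            }
                        )
                        runner.log(**rows[-1])
    finally:
        runner.close()
    table = pd.DataFrame(rows)
    if cfg.output_dir is not None:
        table.to_csv(Path(cfg.output_dir) / "shell_loss_table.csv", index=False)
    return table
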