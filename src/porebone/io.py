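"""Persistence: NIfTI label volumes, HDF5 pressure records, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from porebone.analysis import LOSS_TABLE_COLUMNS
from porebone.phantoms import LabelVolume, PhantomSpec
from porebone.solver.grid import SourceConfig, TimeSettings
from porebone.solver.pstd import PressureRecord

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_pressure_record",
    "load_pressure_record",
    "save_loss_table",
    "load_loss_table",
]


def _spec_to_dict(spec: PhantomSpec) -> dict:
    seed = spec.seed
    if isinstance(seed, np.random.SeedSequence):
        seed = {"entropy": seed.entropy, "spawn_key": list(seed.spawn_key)}
    return {
        "extent": list(spec.extent),
        "voxel_size": spec.voxel_size,
        "pore_diameter": spec.pore_diameter,
        "target_porosity": spec.target_porosity,
        "seed": seed,
        "realization_index": spec.realization_index,
    }


def _spec_from_dict(data: dict) -> PhantomSpec:
    seed = data["seed"]
    if isinstance(seed, dict):
        seed = np.random.SeedSequence(seed["entropy"], spawn_key=tuple(seed["spawn_key"]))
    return PhantomSpec(
        extent=tuple(data["extent"]),
        voxel_size=data["voxel_size"],
        pore_diameter=data["pore_diameter"],
        target_porosity=data["target_porosity"],
        seed=seed,
        realization_index=data.get("realization_index", 0),
    )


def save_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write labels as uint8 NIfTI (voxel size in the header, mm) with a
    JSON sidecar holding the spec, seed and achieved porosity."""
    path = Path(path)
    affine = np.diag([vol.voxel_size] * 3 + [1.0])
    data = vol.labels
    while data.ndim < 3:  # NIfTI is inherently 3D; pad singleton axes
        data = data[np.newaxis, ...]
    nib.save(nib.Nifti1Image(data.astype(np.uint8), affine), str(path))
    sidecar = {
        "achieved_porosity": vol.achieved_porosity,
        "voxel_size": vol.voxel_size,
        "origin_offset": vol.origin_offset,
        "ndim": vol.labels.ndim,
        "spec": _spec_to_dict(vol.spec) if vol.spec is not None else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_label_volume(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.uint8)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    while data.ndim > meta["ndim"]:
        data = data[0]
    return LabelVolume(
        labels=data,
        voxel_size=meta["voxel_size"],
        achieved_porosity=meta["achieved_porosity"],
        spec=_spec_from_dict(meta["spec"]) if meta.get("spec") else None,
        origin_offset=meta.get("origin_offset", 10),
    )


def save_pressure_record(rec: PressureRecord, path: str | Path) -> Path:
    """Write a pressure record as HDF5: the field array plus
    JSON-serialized metadata attributes."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("max_pressure", data=rec.max_pressure)
        fh.attrs["spacing"] = rec.spacing
        fh.attrs["frequency"] = rec.frequency
        fh.attrs["measurement_plane"] = rec.measurement_plane
        fh.attrs["medium_hash"] = rec.medium_hash
        fh.attrs["absorbing"] = rec.absorbing
        fh.attrs["source"] = json.dumps(
            {
                "frequency": rec.source.frequency,
                "amplitude": rec.source.amplitude,
                "ramp_cycles": rec.source.ramp_cycles,
                "phase": rec.source.phase,
            }
        )
        fh.attrs["time_settings"] = json.dumps(
            {
                "cfl": rec.time_settings.cfl,
                "dt": rec.time_settings.dt,
                "duration": rec.time_settings.duration,
                "steady_periods": rec.time_settings.steady_periods,
            }
        )
        fh.attrs["metadata"] = json.dumps(rec.metadata)
    return path


def load_pressure_record(path: str | Path) -> PressureRecord:
    with h5py.File(path, "r") as fh:
        s = json.loads(fh.attrs["source"])
        t = json.loads(fh.attrs["time_settings"])
        return PressureRecord(
            max_pressure=fh["max_pressure"][()],
            spacing=float(fh.attrs["spacing"]),
            frequency=float(fh.attrs["frequency"]),
            source=SourceConfig(**s),
            time_settings=TimeSettings(**t),
            measurement_plane=int(fh.attrs["measurement_plane"]),
            medium_hash=str(fh.attrs["medium_hash"]),
            absorbing=bool(fh.attrs["absorbing"]),
            metadata=json.loads(fh.attrs["metadata"]),
        )


def save_loss_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in LOSS_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"loss table missing columns {missing}")
    table.to_csv(path, index=False)
    return path


def load_loss_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
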