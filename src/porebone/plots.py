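"""Figure export for loss curves and axial profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from porebone.analysis import AxialProfile

__all__ = ["plot_loss_curves", "plot_axial_profiles", "plot_shell_losses"]


def plot_loss_curves(curves: pd.DataFrame, path: str | Path, title: str | None = None) -> Path:
    """Loss vs mean achieved porosity, one line per pore diameter, with
    error bars from the per-cell standard deviation, one panel per
    frequency."""
    path = Path(path)
    freqs = sorted(curves["frequency_hz"].unique())
    fig, axes = plt.subplots(1, len(freqs), figsize=(5.5 * len(freqs), 4.2), squeeze=False)
    for ax, f in zip(axes[0], freqs):
        sub = curves[curves["frequency_hz"] == f]
        for d, grp in sub.groupby("pore_diameter_mm"):
            grp = grp.sort_values("mean_achieved_porosity")
            ax.errorbar(
                100 * grp["mean_achieved_porosity"],
                grp["mean_loss_pct"],
                yerr=grp["std_loss_pct"],
                marker="o",
                ms=3,
                capsize=2,
                label=f"{d:g} mm",
            )
        ax.set_xlabel("porosity (%)")
        ax.set_ylabel("insertion loss (%)")
        ax.set_title(f"{f/1e3:.0f} kHz")
        ax.legend(title="pore diameter", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_axial_profiles(
    profiles: dict[str, AxialProfile], path: str | Path, title: str | None = None
) -> Path:
    """Overlayed transverse-mean pressure vs depth with slab faces marked."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6.5, 4.2))
    faces = None
    for label, prof in profiles.items():
        ax.plot(prof.z_mm, prof.mean_pressure / 1e6, label=label, lw=1.2)
        if prof.face_positions_mm is not None:
            faces = prof.face_positions_mm
    if faces is not None:
        for z in faces:
            ax.axvline(z, color="k", ls="--", lw=0.8)
    ax.set_xlabel("depth z (mm)")
    ax.set_ylabel("mean pressure (MPa)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_shell_losses(table: pd.DataFrame, path: str | Path) -> Path:
    """Loss vs porosity per pore diameter, one panel per bone shape."""
    path = Path(path)
    shapes = list(table["bone_shape"].unique())
    fig, axes = plt.subplots(1, len(shapes), figsize=(4.5 * len(shapes), 4.0), squeeze=False, sharey=True)
    for ax, shape in zip(axes[0], shapes):
        sub = table[table["bone_shape"] == shape]
        for d, grp in sub.groupby("pore_diameter_mm"):
            grp = grp.sort_values("nominal_porosity")
            ax.plot(100 * grp["nominal_porosity"], grp["insertion_loss_pct"], marker="o", label=f"{d:g} mm")
        ax.set_title(shape)
        ax.set_xlabel("porosity (%)")
        ax.legend(fontsize=8)
    axes[0][0].set_ylabel("insertion loss (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
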