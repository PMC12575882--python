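"""Second-order finite-difference cross-check solver.

An independent discretization of the same first-order acoustic system
used by :mod:`porebone.solver.pstd`: staggered-grid leapfrog with
second-order centered differences, periodic transverse axes and an
exponential sponge on the z-faces.  It is deliberately simple and only
intended for small 1D/2D instances, where agreement between the two
schemes guards against discretization-specific bias in either.
"""

from __future__ import annotations

import numpy as np

from porebone.solver.grid import SimGrid, SourceConfig, TimeSettings, plane_wave_signal
from porebone.solver.medium import MediumFields
from porebone.solver.pstd import PressureRecord, SolverError

__all__ = ["run_fd_simulation"]


def run_fd_simulation(
    medium: MediumFields,
    src: SourceConfig,
    ts: TimeSettings,
    grid: SimGrid,
) -> PressureRecord:
    """Lossless finite-difference run mirroring :func:`run_simulation`.

    The FD stencil needs a finer CFL than the pseudospectral scheme for
    comparable accuracy; callers typically pass ``ts.with_cfl(0.1)`` or
    smaller.  Absorbing media are not supported.
    """
    if medium.absorbing:
        raise NotImplementedError("the FD cross-check solver is lossless")
    if medium.shape != grid.dims:
        raise ValueError("medium shape does not match grid dims")
    ndim = grid.ndim
    if ndim > 2:
        raise NotImplementedError("FD cross-check supports 1D and 2D only")
    npml = grid.pml_thickness
    dx = grid.dx
    dt = ts.dt

    pad = [(0, 0)] * (ndim - 1) + [(npml, npml)]
    c = np.pad(medium.c, pad, mode="edge")
    rho0 = np.pad(medium.rho, pad, mode="edge")
    shape = c.shape
    nz_pad = shape[-1]
    c2 = c * c
    rho0_sg = [0.5 * (rho0 + np.roll(rho0, -1, axis=a)) for a in range(ndim)]

    sigma_max = grid.pml_absorption * float(c.max()) / dx
    pos = np.arange(nz_pad, dtype=np.float64)

    def rate(pz: np.ndarray) -> np.ndarray:
        sig = np.zeros_like(pz)
        left = pz < npml
        sig[left] = sigma_max * ((npml - pz[left]) / npml) ** 4
        right = pz > nz_pad - 1 - npml
        sig[right] = sigma_max * ((pz[right] - (nz_pad - 1 - npml)) / npml) ** 4
        return sig

    zsh = [1] * ndim
    zsh[-1] = -1
    pml_r = np.exp(-rate(pos) * dt / 2.0).reshape(zsh)
    pml_u = np.exp(-rate(pos + 0.5) * dt / 2.0).reshape(zsh)

    src_iz = npml
    c_src = float(np.mean(c[..., src_iz]))
    signal = plane_wave_signal(src, np.arange(ts.n_steps) * dt)
    source_scale = 2.0 * dt / (c_src * dx)

    u = [np.zeros(shape) for _ in range(ndim)]
    rho = [np.zeros(shape) for _ in range(ndim)]
    p = np.zeros(shape)
    interior = tuple([slice(None)] * (ndim - 1) + [slice(npml, npml + grid.nz)])
    pmax = np.zeros(grid.dims)
    window_start = ts.n_steps - ts.steady_window_steps(src.frequency)

    for n in range(ts.n_steps):
        for a in range(ndim):
            dpda = (np.roll(p, -1, axis=a) - p) / dx
            if a == ndim - 1:
                u[a] = pml_u * (pml_u * u[a] - (dt / rho0_sg[a]) * dpda)
            else:
                u[a] -= (dt / rho0_sg[a]) * dpda
        for a in range(ndim):
            dua = (u[a] - np.roll(u[a], 1, axis=a)) / dx
            if a == ndim - 1:
                rho[a] = pml_r * (pml_r * rho[a] - dt * rho0 * dua)
            else:
                rho[a] -= dt * rho0 * dua
        inj = signal[n] * source_scale / ndim
        for a in range(ndim):
            rho[a][..., src_iz] += inj
        p = c2 * (rho[0] if ndim == 1 else sum(rho))
        if n >= window_start:
            np.maximum(pmax, p[interior], out=pmax)
        if n % 500 == 0 and not np.isfinite(p).all():
            raise SolverError(f"FD instability at step {n}")

    return PressureRecord(
        max_pressure=pmax,
        spacing=grid.spacing,
        frequency=src.frequency,
        source=src,
        time_settings=ts,
        medium_hash=medium.content_hash(),
        absorbing=False,
        metadata={"scheme": "fdtd2", "grid_dims": grid.dims},
    )
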