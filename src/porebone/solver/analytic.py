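"""Closed-form layered-media oracles for normal-incidence plane waves."""

from __future__ import annotations

import math

__all__ = [
    "analytic_slab_transmission",
    "slab_insertion_loss",
    "interface_coefficients",
    "plane_wave_decay",
]


def analytic_slab_transmission(z1: float, z2: float, c2: float, thickness: float, frequency: float) -> float:
    """|T| for a lossless slab between identical half-spaces, normal incidence.

    ``z1`` is the half-space impedance (Rayl), ``z2``/``c2`` the slab
    impedance and sound speed, ``thickness`` in meters.  The standing-wave
    interference inside the slab gives

        |T| = [1 + 1/4 (z2/z1 - z1/z2)^2 sin^2(2 pi f L / c2)]^(-1/2)

    which is 1 at impedance match and at half-wave resonances.
    """
    for name, v in (("z1", z1), ("z2", z2), ("c2", c2), ("thickness", thickness), ("frequency", frequency)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    mismatch = z2 / z1 - z1 / z2
    s = math.sin(2.0 * math.pi * frequency * thickness / c2)
    return 1.0 / math.sqrt(1.0 + 0.25 * mismatch**2 * s**2)


def slab_insertion_loss(z1: float, z2: float, c2: float, thickness: float, frequency: float) -> float:
    """Insertion loss (%) of the lossless slab: 100 * (1 - |T|)."""
    return 100.0 * (1.0 - analytic_slab_transmission(z1, z2, c2, thickness, frequency))


def lossy_slab_transmission(
    z1: float,
    z2: float,
    c2: float,
    alpha2: float,
    thickness: float,
    frequency: float,
) -> float:
    """|T| for an absorbing slab between identical lossless half-spaces.

    Sums the multiple-reflection series with a complex propagation
    factor ``exp((i omega / c2 - alpha2) L)``; reduces to
    :func:`analytic_slab_transmission` when ``alpha2`` is zero.
    """
    r, t12 = interface_coefficients(z1, z2)
    _, t21 = interface_coefficients(z2, z1)
    phase = 2.0 * math.pi * frequency * thickness / c2
    e = complex(math.cos(phase), math.sin(phase)) * math.exp(-alpha2 * thickness)
    return abs(t12 * t21 * e / (1.0 - r**2 * e**2))


def interface_coefficients(z1: float, z2: float) -> tuple[float, float]:
    """Pressure reflection and transmission coefficients at one interface."""
    r = (z2 - z1) / (z2 + z1)
    t = 2.0 * z2 / (z2 + z1)
    return r, t


def plane_wave_decay(amplitude: float, alpha: float, distance: float) -> float:
    """Amplitude of a plane wave after ``distance`` m in a medium with
    amplitude attenuation ``alpha`` Np/m."""
    return amplitude * math.exp(-alpha * distance)
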