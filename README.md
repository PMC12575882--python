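# porebone

Digital two-material bone phantoms, full-wave lossy acoustic simulation,
and ultrasound insertion-loss analysis.

The package studies how unresolved trabecular microstructure affects
ultrasound transmission through skull-like slabs: randomized phantoms of
marrow pores in a cortical background (controlled porosity and a single
pore diameter per phantom) are insonified with a continuous plane wave
at 230 or 650 kHz, and the insertion loss relative to a water-only
reference is computed from the steady-state pressure at a distal
measurement plane.

## Components

- `porebone.materials` / `porebone.phantoms` — material table (water,
  red marrow, cortical bone), randomized overlapping-sphere pore
  phantoms with achieved-porosity bookkeeping, and curved shell masks
  (temporal/frontal/parietal presets) for nonplanar interfaces.
- `porebone.solver` — a k-space pseudospectral time-domain solver
  (1D/2D/3D, staggered grid, periodic transverse boundaries, absorbing
  end layers, dispersion-free exponent-2 power-law absorption), a
  second-order finite-difference cross-check solver, and closed-form
  slab-transmission oracles.
- `porebone.analysis` — insertion loss, axial mean-pressure profiles,
  standing-wave metrics, loss-curve aggregation, porosity → density/HU
  axis mapping.
- `porebone.experiments` — sweep orchestration (frequency × porosity ×
  pore diameter × realization × absorption), the convergence suite and
  the shell study, from one YAML config, with water-reference caching.

## CLI

```bash
porebone sweep    --config cfg.yaml   # loss table + curves + figure
porebone converge --config cfg.yaml   # duration/CFL convergence suite
porebone shells   --config cfg.yaml   # temporal/frontal/parietal study
porebone simulate --phantom vol.nii --freq 650k --nonabsorbing --out rec.h5
```

Example config:

```yaml
frequencies: [650000.0, 230000.0]
pore_diameters: [0.2, 0.3, 0.4, 0.6, 0.8, 1.0]
porosities: [0.025, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75]
realizations: 5
absorbing: false
scale: reduced2d        # full3d | reduced2d | coarse3d
master_seed: 1
output_dir: results/sweep
```

`scale: full3d` reproduces the full-size study geometry
(256 × 256 × 152 at 0.05 mm); expect hours per simulation on CPU.
`reduced2d` (x–z sections) and `coarse3d` preserve trends at desk scale
but are not numerically equivalent to the 3D results.

## Phantom persistence

Label volumes are saved as uint8 NIfTI plus a JSON sidecar (spec, seed,
achieved porosity); pressure records as HDF5 with JSON metadata
attributes; loss tables as CSV with fixed column names.
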