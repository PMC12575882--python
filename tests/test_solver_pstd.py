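import numpy as np
import pytest

from porebone.materials import LABEL_CORTICAL, LABEL_WATER
from porebone.solver.analytic import (
    analytic_slab_transmission,
    interface_coefficients,
    lossy_slab_transmission,
)
from porebone.solver.fdtd import run_fd_simulation
from porebone.solver.grid import SimGrid, SourceConfig, time_settings
from porebone.solver.medium import MediumFields, assign_materials, homogeneous_slab_labels, water_medium
from porebone.solver.pstd import (
    SolverError,
    clear_reference_cache,
    run_simulation,
    water_reference,
)


class TestWaterReference:
    def test_plane_mean_is_source_amplitude(self, water650_1d):
        assert water650_1d.plane_mean() == pytest.approx(1.0e6, rel=0.01)

    def test_axial_profile_flat(self, water650_1d):
        prof = water650_1d.max_pressure
        assert prof.min() == pytest.approx(prof.max(), rel=0.01)

    def test_cache_returns_identical_record(self, src650, ts650_1d, grid1d, mat):
        clear_reference_cache()
        first = water_reference(src650, ts650_1d, grid1d, mat)
        again = water_reference(src650, ts650_1d, grid1d, mat)
        assert again is first

    def test_recompute_is_bit_identical(self, src650, ts650_1d, grid1d, mat, water650_1d):
        clear_reference_cache()
        fresh = water_reference(src650, ts650_1d, grid1d, mat)
        assert np.array_equal(fresh.max_pressure, water650_1d.max_pressure)

    def test_230_and_650_references_agree(self, grid1d, mat):
        means = []
        for f in (230e3, 650e3):
            src = SourceConfig(frequency=f)
            ts = time_settings(f, grid1d, c_max=3514.0)
            means.append(water_reference(src, ts, grid1d, mat).plane_mean())
        assert means[0] == pytest.approx(means[1], rel=0.01)


@pytest.fixture(scope="module")
def water2d(grid2d_small, mat):
    src = SourceConfig(frequency=650e3)
    ts = time_settings(650e3, grid2d_small, c_max=1500.0)
    return run_simulation(water_medium(grid2d_small, mat, 650e3), src, ts, grid2d_small)


class TestPlaneWave2D:
    def test_transverse_uniformity(self, water2d):
        # periodic transverse handling keeps a uniform source uniform
        plane = water2d.plane()
        spread = (plane.max() - plane.min()) / plane.mean()
        assert spread < 1e-6

    def test_amplitude(self, water2d):
        assert water2d.plane_mean() == pytest.approx(1.0e6, rel=0.01)

    def test_every_plane_uniform(self, water2d):
        field = water2d.max_pressure
        spread = (field.max(axis=0) - field.min(axis=0)) / field.mean(axis=0)
        assert float(spread.max()) < 1e-6


class TestSlabOracle:
    def test_cortical_5mm_650k(self, cortical650_1d, water650_1d, mat):
        T_sim = cortical650_1d.plane_mean() / water650_1d.plane_mean()
        T_an = analytic_slab_transmission(mat.water.impedance, mat.cortical.impedance, 3514.0, 0.005, 650e3)
        assert T_sim == pytest.approx(T_an, rel=0.02)

    def test_marrow_5mm_650k(self, marrow650_1d, water650_1d, mat):
        T_sim = marrow650_1d.plane_mean() / water650_1d.plane_mean()
        T_an = analytic_slab_transmission(mat.water.impedance, mat.marrow.impedance, 1450.0, 0.005, 650e3)
        assert T_sim == pytest.approx(T_an, rel=0.02)

    @pytest.mark.parametrize("thickness_mm", [1.0, 3.0])
    def test_cortical_thickness_sweep_230k(self, grid1d, mat, thickness_mm):
        src = SourceConfig(frequency=230e3)
        ts = time_settings(230e3, grid1d, c_max=3514.0)
        medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL, thickness_mm), mat, False, 230e3)
        rec = run_simulation(medium, src, ts, grid1d)
        wrec = water_reference(src, ts, grid1d, mat)
        T_an = analytic_slab_transmission(
            mat.water.impedance, mat.cortical.impedance, 3514.0, thickness_mm * 1e-3, 230e3
        )
        assert rec.plane_mean() / wrec.plane_mean() == pytest.approx(T_an, rel=0.02)


class TestAbsorption:
    def test_uniform_absorbing_water_decay(self, grid1d, mat):
        # plane-wave amplitude decays as exp(-alpha z)
        f, alpha = 650e3, 80.0
        src = SourceConfig(frequency=f)
        ts = time_settings(f, grid1d, c_max=1500.0, absorbing=True)
        wm = water_medium(grid1d, mat, f)
        medium = MediumFields(c=wm.c, rho=wm.rho, alpha=np.full(grid1d.dims, alpha), frequency=f)
        rec = run_simulation(medium, src, ts, grid1d)
        prof = rec.max_pressure
        z = grid1d.z_axis_mm() * 1e-3
        i0, i1 = 20, 140
        sim_ratio = prof[i1] / prof[i0]
        assert sim_ratio == pytest.approx(np.exp(-alpha * (z[i1] - z[i0])), rel=0.01)

    def test_zero_absorption_path_equivalence(self, grid1d, mat, src650, ts650_1d):
        medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, False, 650e3)
        r_non = run_simulation(medium, src650, ts650_1d, grid1d, use_absorbing_path=False)
        r_abs = run_simulation(medium, src650, ts650_1d, grid1d, use_absorbing_path=True)
        rel = np.abs(r_abs.plane() / r_non.plane() - 1.0)
        assert float(np.max(rel)) <= 1e-6

    def test_absorbing_cortical_slab_vs_lossy_oracle(self, grid1d, mat):
        f = 650e3
        src = SourceConfig(frequency=f)
        ts = time_settings(f, grid1d, c_max=3514.0, absorbing=True)
        assert ts.cfl == 0.06
        medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, True, f)
        rec = run_simulation(medium, src, ts, grid1d)
        wrec = water_reference(src, ts, grid1d, mat)
        alpha_eff = 54.55 * np.sqrt(0.65)
        T_an = lossy_slab_transmission(
            mat.water.impedance, mat.cortical.impedance, 3514.0, alpha_eff, 0.005, f
        )
        # first-order oracle: agreement to 2% (the exponent-2 loss model
        # perturbs the slab resonance phase slightly)
        assert rec.plane_mean() / wrec.plane_mean() == pytest.approx(T_an, rel=0.02)


class TestInterfacePower:
    def test_reflection_transmission_power_budget(self, grid1d, mat, src650, ts650_1d):
        # water / cortical half-space: R^2 + (Z1/Z2) T^2 = 1 within 0.5%
        labels = np.full(grid1d.dims, LABEL_WATER, dtype=np.uint8)
        labels[60:] = LABEL_CORTICAL
        medium = assign_materials(labels, mat, False, 650e3)
        rec = run_simulation(medium, src650, ts650_1d, grid1d)
        prof = rec.max_pressure
        front = prof[10:55]
        pmax, pmin = front.max(), front.min()
        R = (pmax - pmin) / (pmax + pmin)
        p_incident = (pmax + pmin) / 2
        T = prof[100:140].mean() / p_incident
        z1, z2 = mat.water.impedance, mat.cortical.impedance
        assert R**2 + (z1 / z2) * T**2 == pytest.approx(1.0, abs=0.005)
        r_an, t_an = interface_coefficients(z1, z2)
        assert R == pytest.approx(r_an, rel=0.005)
        assert T == pytest.approx(t_an, rel=0.005)


class TestCrossCheckSolver:
    def test_fd_agrees_with_pstd_on_slab(self, grid1d, mat, src650, ts650_1d, cortical650_1d, water650_1d):
        ts_fd = ts650_1d.with_cfl(0.05)
        w_fd = run_fd_simulation(water_medium(grid1d, mat, 650e3), src650, ts_fd, grid1d)
        c_fd = run_fd_simulation(
            assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, False, 650e3),
            src650,
            ts_fd,
            grid1d,
        )
        T_fd = c_fd.plane_mean() / w_fd.plane_mean()
        T_ps = cortical650_1d.plane_mean() / water650_1d.plane_mean()
        assert T_fd == pytest.approx(T_ps, rel=0.02)

    def test_fd_rejects_absorbing(self, grid1d, mat, src650, ts650_1d):
        medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, True, 650e3)
        with pytest.raises(NotImplementedError):
            run_fd_simulation(medium, src650, ts650_1d, grid1d)


class TestErrors:
    def test_under_resolved_medium(self, grid1d, mat):
        src = SourceConfig(frequency=10e6)  # 1450/10e6/5e-5 ~ 2.9 ppw
        ts = time_settings(10e6, grid1d, c_max=3514.0)
        with pytest.raises(SolverError, match="under-resolved"):
            run_simulation(water_medium(grid1d, mat, 10e6), src, ts, grid1d)

    def test_cfl_above_bound(self, grid1d, mat, src650, ts650_1d):
        ts_bad = ts650_1d.with_cfl(1.5)
        with pytest.raises(SolverError, match="CFL"):
            run_simulation(water_medium(grid1d, mat, 650e3), src650, ts_bad, grid1d)

    def test_shape_mismatch(self, grid1d, mat, src650, ts650_1d):
        medium = water_medium(SimGrid(dims=(64,), spacing=0.05), mat, 650e3)
        with pytest.raises(ValueError):
            run_simulation(medium, src650, ts650_1d, grid1d)


def test_determinism(grid1d, mat, src650, ts650_1d, cortical650_1d):
    medium = assign_materials(homogeneous_slab_labels(grid1d, LABEL_CORTICAL), mat, False, 650e3)
    again = run_simulation(medium, src650, ts650_1d, grid1d)
    assert np.array_equal(again.max_pressure, cortical650_1d.max_pressure)


def test_smoothed_uniform_source_unchanged(grid2d_small, mat):
    # Blackman k-space smoothing leaves a uniform (pure-DC) source intact
    src = SourceConfig(frequency=650e3)
    ts = time_settings(650e3, grid2d_small, c_max=1500.0)
    medium = water_medium(grid2d_small, mat, 650e3)
    plain = run_simulation(medium, src, ts, grid2d_small)
    smoothed = run_simulation(medium, src, ts, grid2d_small, smooth_source=True)
    assert np.allclose(plain.max_pressure, smoothed.max_pressure, rtol=1e-9)
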