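import numpy as np
import pandas as pd
import pytest

from porebone.analysis import (
    AxialProfile,
    NegativeLossWarning,
    aggregate_loss_curves,
    axial_mean_profile,
    convergence_diff,
    insertion_loss,
    porosity_to_density_hu,
    standing_wave_metrics,
)
from porebone.materials import MaterialTable
from porebone.solver.grid import SourceConfig, TimeSettings
from porebone.solver.pstd import PressureRecord


def _record(field, frequency=650e3, dt=4e-9):
    return PressureRecord(
        max_pressure=np.asarray(field, dtype=float),
        spacing=0.05,
        frequency=frequency,
        source=SourceConfig(frequency=frequency),
        time_settings=TimeSettings(cfl=0.3, dt=dt, duration=2e-5),
    )


class TestInsertionLoss:
    def test_identical_records_zero(self):
        rec = _record(np.ones((4, 10)))
        assert insertion_loss(rec, rec) == 0.0

    def test_dead_plane_is_full_loss(self):
        water = _record(np.ones((4, 10)))
        phantom = _record(np.concatenate([np.ones((4, 9)), np.zeros((4, 1))], axis=1))
        assert insertion_loss(phantom, water) == 100.0

    def test_negative_loss_flagged_not_clipped(self):
        water = _record(np.ones((4, 10)))
        hot = _record(np.full((4, 10), 1.1))
        with pytest.warns(NegativeLossWarning):
            loss = insertion_loss(hot, water)
        assert loss == pytest.approx(-10.0)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            insertion_loss(_record(np.ones((4, 10))), _record(np.ones((5, 10))))

    def test_frequency_mismatch_raises(self):
        with pytest.raises(ValueError):
            insertion_loss(_record(np.ones((4, 10))), _record(np.ones((4, 10)), frequency=230e3))

    def test_nonpositive_reference_raises(self):
        with pytest.raises(ValueError):
            insertion_loss(_record(np.ones((4, 10))), _record(np.zeros((4, 10))))

    def test_simulated_water_flat(self, water650_1d):
        assert insertion_loss(water650_1d, water650_1d) == 0.0


class TestAxialProfile:
    def test_water_profile_flat(self, water650_1d):
        prof = axial_mean_profile(water650_1d)
        assert prof.mean_pressure == pytest.approx(1.0e6, rel=0.01)

    def test_length_bookkeeping(self, water650_1d):
        prof = axial_mean_profile(water650_1d)
        assert len(prof) == water650_1d.max_pressure.shape[-1] == 152

    def test_cortical_front_water_oscillates(self, cortical650_1d):
        # incident + reflected interference in the 0.5 mm front water segment
        prof = axial_mean_profile(cortical650_1d, face_positions_mm=(0.5, 5.5))
        front = prof.mean_pressure[prof.z_mm < 0.5]
        assert front.max() > 1.2e6  # antinode above the incident amplitude

    def test_transverse_mean_includes_all_voxels(self):
        field = np.stack([np.full(10, 1.0), np.full(10, 3.0)])
        prof = axial_mean_profile(_record(field))
        assert np.allclose(prof.mean_pressure, 2.0)


class TestStandingWaveMetrics:
    def test_flat_profile_no_peaks(self):
        z = (np.arange(100) + 0.5) * 0.05
        m = standing_wave_metrics(AxialProfile(z, np.full(100, 2.0e6), (0.5, 4.5)))
        assert m.amplitude == 0.0
        assert m.peak_count == 0
        assert m.mean_peak_spacing_mm is None

    def test_synthetic_sinusoid_period_recovered(self):
        z = (np.arange(152) + 0.5) * 0.05
        period = 0.9
        y = 1e6 * (1 + 0.2 * np.sin(2 * np.pi * z / period)) + 2e4 * z
        m = standing_wave_metrics(AxialProfile(z, y, (0.5, 5.5)))
        assert m.mean_peak_spacing_mm == pytest.approx(period, abs=0.05)
        assert m.peak_count >= 3

    def test_missing_faces_raise(self):
        z = (np.arange(100) + 0.5) * 0.05
        with pytest.raises(ValueError):
            standing_wave_metrics(AxialProfile(z, np.ones(100)))

    def test_single_peak_flags_undefined_spacing(self):
        z = (np.arange(100) + 0.5) * 0.05
        y = 1e6 * np.exp(-0.5 * ((z - 2.5) / 0.3) ** 2)
        m = standing_wave_metrics(AxialProfile(z, y, (0.5, 4.5)))
        assert m.peak_count >= 1
        if m.peak_count == 1:
            assert m.mean_peak_spacing_mm is None


class TestAggregation:
    @staticmethod
    def _table(losses, **overrides):
        n = len(losses)
        base = dict(
            frequency_hz=[650e3] * n,
            pore_diameter_mm=[0.2] * n,
            nominal_porosity=[0.3] * n,
            achieved_porosity=[0.301] * n,
            realization=list(range(n)),
            absorbing=[False] * n,
            insertion_loss_pct=losses,
            plane_mean_pressure_pa=[7e5] * n,
        )
        base.update(overrides)
        return pd.DataFrame(base)

    def test_single_realization_degenerate(self):
        out = aggregate_loss_curves(self._table([30.0]))
        assert out.loc[0, "std_loss_pct"] == 0.0
        assert bool(out.loc[0, "degenerate"])

    def test_five_identical_rows(self):
        out = aggregate_loss_curves(self._table([25.0] * 5))
        assert out.loc[0, "mean_loss_pct"] == 25.0
        assert out.loc[0, "std_loss_pct"] == 0.0
        assert not bool(out.loc[0, "degenerate"])

    def test_x_position_is_mean_achieved_porosity(self):
        out = aggregate_loss_curves(self._table([1.0, 2.0], achieved_porosity=[0.30, 0.32]))
        assert out.loc[0, "mean_achieved_porosity"] == pytest.approx(0.31)

    def test_gaussian_spread_recovered(self, rng):
        # independent oracle: 100 cells of 5 draws from N(30, sigma) must
        # recover sigma within 20% on average (E[s_5] = c4 * sigma, c4 ~ 0.94)
        sigma = 2.0
        frames = []
        for cell in range(100):
            frames.append(
                self._table(list(rng.normal(30.0, sigma, size=5)), nominal_porosity=[cell / 1000.0] * 5)
            )
        out = aggregate_loss_curves(pd.concat(frames, ignore_index=True))
        assert out["std_loss_pct"].mean() == pytest.approx(sigma, rel=0.2)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            aggregate_loss_curves(self._table([]).iloc[0:0])


class TestPorosityDensityHU:
    def test_endpoints(self):
        mat = MaterialTable()
        assert porosity_to_density_hu(0.0, mat)[0] == pytest.approx(1908.0)
        assert porosity_to_density_hu(1.0, mat)[0] == pytest.approx(1029.0)

    def test_midpoint(self):
        assert porosity_to_density_hu(0.5)[0] == pytest.approx(1468.5)

    def test_water_anchor_maps_to_zero_hu(self):
        # density 1000 is the first anchor -> 0 HU by construction
        _, hu = porosity_to_density_hu(0.0, hu_anchors=((1000.0, 0.0), (1908.0, 1500.0)))
        assert hu == pytest.approx(1500.0)
        density, hu_mid = porosity_to_density_hu(0.5, hu_anchors=((1000.0, 0.0), (2000.0, 1000.0)))
        assert hu_mid == pytest.approx(density - 1000.0)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            porosity_to_density_hu(1.2)
        with pytest.raises(ValueError):
            porosity_to_density_hu(-0.1)

    def test_vectorized(self):
        density, hu = porosity_to_density_hu(np.array([0.0, 0.5, 1.0]))
        assert density.shape == (3,)
        assert np.all(np.diff(density) < 0)


class TestConvergenceDiff:
    def test_identical_records_zero(self):
        rec = _record(np.ones((4, 10)))
        assert convergence_diff(rec, rec) == 0.0

    def test_value(self):
        a = _record(np.full((4, 10), 1.02))
        b = _record(np.ones((4, 10)))
        assert convergence_diff(a, b) == pytest.approx(2.0)

    def test_mismatched_grids_raise(self):
        with pytest.raises(ValueError):
            convergence_diff(_record(np.ones((4, 10))), _record(np.ones((3, 10))))
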