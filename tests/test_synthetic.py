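"""Synthetic acquisition: grids, layout, scenarios, noise, schedule, timelapse."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import teerkit as tk
from teerkit.synthetic import (
    DEFAULT_CHIP_PARAMS,
    DEFAULT_PARASITICS,
    BarrierScenario,
    MeasurementSchedule,
    NoiseModel,
    barrier_trajectory,
    default_plate_layout,
    make_frequency_grid,
    simulate_chip_spectrum,
    simulate_compensation_boards,
    simulate_timelapse,
)


class TestFrequencyGrid:
    def test_default_acquisition_sweep(self):
        g = make_frequency_grid(1e3, 1e6, 121)
        assert len(g) == 121
        assert g.f_min == 1000.0
        assert g.f_max == 1.0e6
        # log-equal spacing
        ratios = np.diff(np.log10(g.values))
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_one_point_per_decade(self):
        g = make_frequency_grid(1e3, 1e6, 4)
        np.testing.assert_allclose(g.values, [1e3, 1e4, 1e5, 1e6], rtol=1e-12)

    @pytest.mark.parametrize("args", [(10.0, 10.0, 2), (1e6, 1e3, 10), (1e3, 1e6, 1)])
    def test_degenerate_bounds_rejected(self, args):
        with pytest.raises(ValueError):
            make_frequency_grid(*args)


class TestPlateLayout:
    def test_default_layout_counts(self):
        layout = default_plate_layout()
        assert layout.n_chips == 64
        assert len(set(layout.chip_ids)) == 64
        assert layout.total_electrodes == 512
        assert layout.wells_per_chip == 6

    def test_electrode_count_conservation(self):
        layout = default_plate_layout()
        assert sum(layout.electrodes_per_chip for _ in layout.chips) == layout.total_electrodes


class TestBarrierTrajectory:
    def test_control_is_constant_baseline(self):
        sc = BarrierScenario(kind="control", baseline_r_barrier=1234.0)
        t = np.linspace(0, 44, 50)
        np.testing.assert_array_equal(barrier_trajectory(sc, t), 1234.0)

    def test_tnfa_starts_at_baseline(self):
        sc = BarrierScenario(kind="tnfa", dose=10.0, baseline_r_barrier=2000.0)
        assert barrier_trajectory(sc, 0.0) == 2000.0

    def test_tnfa_nadir_near_two_hours_with_recovery(self):
        sc = BarrierScenario(kind="tnfa", dose=10.0, baseline_r_barrier=2000.0)
        t = np.linspace(0, 44, 4001)
        traj = barrier_trajectory(sc, t)
        assert t[np.argmin(traj)] == pytest.approx(2.0, abs=0.1)
        assert traj[-1] / 2000.0 > traj.min() / 2000.0  # recovered

    def test_combo_floor_persists(self):
        sc = BarrierScenario(kind="combo", dose=10.0, baseline_r_barrier=2000.0)
        v4 = barrier_trajectory(sc, 4.0)
        v44 = barrier_trajectory(sc, 44.0)
        assert v44 / 2000.0 == pytest.approx(v4 / 2000.0, abs=0.02)

    def test_disruptor_collapses_monotonically(self):
        sc = BarrierScenario(kind="disruptor", baseline_r_barrier=2000.0)
        t = np.linspace(0, 24, 200)
        traj = barrier_trajectory(sc, t)
        assert np.all(np.diff(traj) < 0)
        assert traj[-1] < 0.01 * 2000.0
        assert np.all(traj > 0)

    @pytest.mark.parametrize("kind", ["ifng", "combo"])
    def test_dose_ordering_non_increasing(self, kind):
        doses = [0.1, 1.0, 10.0, 100.0]
        vals = [
            barrier_trajectory(
                BarrierScenario(kind=kind, dose=d, baseline_r_barrier=2000.0), 20.0
            )
            for d in doses
        ]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_saturation_above_ten_ng_ml(self):
        lo = BarrierScenario(kind="tnfa", dose=10.0, baseline_r_barrier=2000.0)
        hi = BarrierScenario(kind="tnfa", dose=100.0, baseline_r_barrier=2000.0)
        t = np.linspace(0, 44, 1000)
        amp_lo = 1 - barrier_trajectory(lo, t).min() / 2000.0
        amp_hi = 1 - barrier_trajectory(hi, t).min() / 2000.0
        assert amp_hi - amp_lo < 0.02

    @given(t=st.floats(0.0, 48.0), dose=st.floats(0.0, 100.0))
    @settings(max_examples=100, deadline=None)
    def test_trajectories_strictly_positive(self, t, dose):
        for kind in ("control", "ifng", "tnfa", "combo", "disruptor"):
            sc = BarrierScenario(kind=kind, dose=dose, baseline_r_barrier=2000.0)
            assert barrier_trajectory(sc, t) > 0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            BarrierScenario(kind="caffeine", baseline_r_barrier=2000.0)


class TestSimulateChipSpectrum:
    def test_noiseless_no_parasitics_equals_circuit(self, grid, chip_params):
        s = simulate_chip_spectrum(
            chip_params, tk.ParasiticParams(0, 0), grid, NoiseModel(0.0, 0)
        )
        np.testing.assert_array_equal(s.z, tk.chip_impedance(chip_params, grid).z)

    def test_same_seed_reproduces_spectrum(self, grid, chip_params, parasitics):
        a = simulate_chip_spectrum(chip_params, parasitics, grid, NoiseModel(0.01, 7))
        b = simulate_chip_spectrum(chip_params, parasitics, grid, NoiseModel(0.01, 7))
        np.testing.assert_array_equal(a.z, b.z)

    def test_noise_scale_matches_model(self, small_grid, chip_params):
        """Empirical per-part SD over 200 replicates matches sigma_rel."""
        par = tk.ParasiticParams(0, 0)
        truth = tk.chip_impedance(chip_params, small_grid).z
        reps = np.array(
            [
                simulate_chip_spectrum(
                    chip_params, par, small_grid, NoiseModel(0.01, 1000 + i)
                ).z
                for i in range(200)
            ]
        )
        sd_re = reps.real.std(axis=0) / np.abs(truth.real)
        assert np.all(np.abs(sd_re - 0.01) < 0.2 * 0.01 + 3 * 0.01 / np.sqrt(2 * 200))

    def test_noise_scaling_doubles_with_sigma(self, small_grid, chip_params):
        par = tk.ParasiticParams(0, 0)
        def resid_sd(sigma):
            truth = tk.chip_impedance(chip_params, small_grid).z
            reps = np.array(
                [
                    simulate_chip_spectrum(
                        chip_params, par, small_grid, NoiseModel(sigma, 5000 + i)
                    ).z
                    for i in range(150)
                ]
            )
            return np.median(reps.real.std(axis=0))
        r = resid_sd(0.02) / resid_sd(0.01)
        assert r == pytest.approx(2.0, rel=0.25)


class TestCompensationBoards:
    def test_zero_parasitics_no_noise_flat_spectra(self, small_grid):
        comp = simulate_compensation_boards(
            tk.ParasiticParams(0, 0), grid=small_grid, noise=NoiseModel(0.0, 0)
        )
        assert len(comp.spectra) == 3
        np.testing.assert_array_equal(comp.spectra[0].z, 24_000.0 + 0j)
        np.testing.assert_allclose(comp.loads, [24e3, 30e3, 36e3])

    def test_duplicate_loads_rejected(self, small_grid):
        with pytest.raises(ValueError):
            simulate_compensation_boards(
                tk.ParasiticParams(0, 0), loads=(24e3, 24e3, 36e3), grid=small_grid
            )


class TestSchedule:
    def test_default_schedule_phases(self):
        s = MeasurementSchedule()
        t = s.times_min()
        assert t[0] == -6.0  # baseline precedes exposure
        assert t[1] == 0.0
        fast = t[(t >= 0) & (t <= 44)]
        np.testing.assert_allclose(np.diff(fast), 4.0)
        slow = t[(t > 44) & (t <= 43 * 60)]
        np.testing.assert_allclose(np.diff(slow), 64.0)
        assert 44 * 60 <= t[-1] <= 48 * 60
        assert np.all(np.diff(t) > 0)

    def test_baseline_must_precede_exposure(self):
        with pytest.raises(ValueError):
            MeasurementSchedule(baseline_time_min=5.0)


class TestSimulateTimelapse:
    def test_all_control_noiseless_constant_spectra(self):
        layout = default_plate_layout()
        cmap = {cid: ("control", 0.0) for cid in layout.chip_ids}
        sched = MeasurementSchedule(
            slow_duration_min=300, endpoint_time_min=400
        )
        ds = simulate_timelapse(
            layout, cmap, sched, noise=NoiseModel(0.0, 0), chip_cv=0.0
        )
        times = sched.times_min()
        assert len(ds.records) == 64 * times.size
        recs = ds.spectra_for_chip(layout.chip_ids[0])
        for r in recs[1:]:
            np.testing.assert_array_equal(r.spectrum.z, recs[0].spectrum.z)

    def test_every_chip_time_pair_has_one_record(self):
        layout = default_plate_layout()
        cmap = {cid: ("tnfa", 10.0) for cid in layout.chip_ids}
        sched = MeasurementSchedule(slow_duration_min=300, endpoint_time_min=400)
        ds = simulate_timelapse(layout, cmap, sched, noise=NoiseModel(0.005, 1))
        keys = {(r.chip_id, r.time_min) for r in ds.records}
        assert len(keys) == len(ds.records) == 64 * sched.times_min().size

    def test_missing_chip_in_condition_map_rejected(self):
        layout = default_plate_layout()
        cmap = {cid: ("control", 0.0) for cid in layout.chip_ids[:-1]}
        with pytest.raises(ValueError, match="missing"):
            simulate_timelapse(layout, cmap, MeasurementSchedule())

    def test_same_seed_bitwise_reproducible(self):
        layout = default_plate_layout()
        doses = [0.1, 1.0, 10.0, 100.0]
        cmap = {}
        for i, cid in enumerate(layout.chip_ids):
            kind = ("ifng", "tnfa")[i % 2]
            cmap[cid] = (kind, doses[(i // 2) % 4])
        sched = MeasurementSchedule(slow_duration_min=200, endpoint_time_min=300)
        ds1 = simulate_timelapse(layout, cmap, sched, noise=NoiseModel(0.01, 99))
        ds2 = simulate_timelapse(layout, cmap, sched, noise=NoiseModel(0.01, 99))
        for r1, r2 in zip(ds1.records, ds2.records):
            assert r1.chip_id == r2.chip_id and r1.time_min == r2.time_min
            np.testing.assert_array_equal(r1.spectrum.z, r2.spectrum.z)
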