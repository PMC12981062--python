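"""Generator contracts: membrane tests, IPSC sweeps, containers."""

import dataclasses

import numpy as np
import pytest

from inhibpipe import (
    EphysGenConfig,
    compute_mean_trace,
    generate_io_dataset,
    generate_ipsc_sweeps,
    generate_membrane_test,
    load_cells,
    measure_ipsc,
    save_cells,
    solve_rise_tau,
)
from inhibpipe.synth_ephys import _rise_20_80, cells_to_long_csv


class TestMembraneTest:
    def test_steady_state_follows_ohms_law(self):
        # -5 mV across R_s + R_in = 350 MOhm -> -14.29 pA at steady state
        cfg = EphysGenConfig(R_s_true=10, R_in_true=340, C_true=120, noise_sd=0)
        sweep = generate_membrane_test(cfg)
        tr = sweep.trace
        i_ss = tr.samples[tr.index_at(sweep.test_pulse_onset + 0.15)]
        assert i_ss == pytest.approx(-5 / 350 * 1e3, rel=1e-3)

    def test_zero_capacitance_limit_settles_within_one_sample(self):
        cfg = EphysGenConfig(R_s_true=10, R_in_true=340, C_true=1e-9, noise_sd=0)
        sweep = generate_membrane_test(cfg)
        tr = sweep.trace
        i0 = tr.index_at(sweep.test_pulse_onset)
        i_ss = -5 / 350 * 1e3
        assert tr.samples[i0 + 1] == pytest.approx(i_ss, rel=1e-6)

    def test_seed_determinism_bit_identical(self):
        cfg = EphysGenConfig(noise_sd=5.0, seed=42)
        a = generate_membrane_test(cfg).trace.samples
        b = generate_membrane_test(cfg).trace.samples
        assert np.array_equal(a, b)


class TestRiseTauSolver:
    @pytest.mark.parametrize("rise,tau", [(1.88, 35.49), (4.92, 79.86), (3.95, 55.82)])
    def test_solved_kinetics_reproduce_requested_rise(self, rise, tau):
        tau_r = solve_rise_tau(rise, tau)
        assert _rise_20_80(tau_r, tau) == pytest.approx(rise, rel=1e-6)

    def test_unreachable_rise_raises(self):
        with pytest.raises(ValueError):
            solve_rise_tau(500.0, 35.0)


class TestIpscSweeps:
    def test_noiseless_round_trip_ppr(self):
        cfg = EphysGenConfig(A1_true=100.0, ppr_true=0.84, rise_20_80_true=4.92,
                             tau_decay_true=79.86, noise_sd=0)
        cell = generate_ipsc_sweeps(cfg)
        m = measure_ipsc(compute_mean_trace(cell), cell.sweeps[0].stim_times)
        assert m.ppr == pytest.approx(0.84, abs=0.01)

    def test_mean_of_identical_sweeps_equals_single_sweep(self):
        cfg1 = EphysGenConfig(noise_sd=0, n_sweeps=1)
        cfg50 = dataclasses.replace(cfg1, n_sweeps=50)
        t1 = compute_mean_trace(generate_ipsc_sweeps(cfg1)).samples
        t50 = compute_mean_trace(generate_ipsc_sweeps(cfg50)).samples
        np.testing.assert_allclose(t50, t1, rtol=1e-14, atol=1e-12)

    def test_configured_rise_measured_back_noiseless(self):
        cfg = EphysGenConfig(A1_true=372.5, rise_20_80_true=4.92,
                             tau_decay_true=79.86, noise_sd=0)
        cell = generate_ipsc_sweeps(cfg)
        m = measure_ipsc(compute_mean_trace(cell), cell.sweeps[0].stim_times)
        assert m.rise_20_80 == pytest.approx(4.92, rel=0.02)

    def test_unrealizable_rise_on_grid_raises(self):
        cfg = EphysGenConfig(rise_20_80_true=0.05, tau_decay_true=35.0)
        with pytest.raises(ValueError, match="unrealizable"):
            generate_ipsc_sweeps(cfg)

    @pytest.mark.parametrize("a1", [50.0, 372.5, 620.0])
    @pytest.mark.parametrize("ppr", [0.56, 0.84])
    @pytest.mark.parametrize("tau", [35.0, 80.0])
    def test_noiseless_recovery_grid(self, a1, ppr, tau):
        """Generator -> analyzer round trip across the reported ranges."""
        rise = 1.9 if tau < 50 else 4.9
        cfg = EphysGenConfig(A1_true=a1, ppr_true=ppr, rise_20_80_true=rise,
                             tau_decay_true=tau, noise_sd=0)
        cell = generate_ipsc_sweeps(cfg)
        m = measure_ipsc(compute_mean_trace(cell), cell.sweeps[0].stim_times)
        assert m.A1 == pytest.approx(a1, rel=0.03)
        assert m.ppr == pytest.approx(ppr, rel=0.03)
        assert m.rise_20_80 == pytest.approx(rise, rel=0.03)
        assert m.tau_decay_w == pytest.approx(tau, rel=0.03)

    def test_noise_scaling_with_sweep_count(self):
        """SE of the measured amplitude scales as noise_sd / sqrt(n_sweeps)."""

        def measured_a1(n_sweeps, seed):
            cfg = EphysGenConfig(A1_true=300.0, noise_sd=40.0,
                                 n_sweeps=n_sweeps, seed=seed)
            cell = generate_ipsc_sweeps(cfg)
            return measure_ipsc(compute_mean_trace(cell),
                                cell.sweeps[0].stim_times).A1

        a1_4 = np.std([measured_a1(4, s) for s in range(30)])
        a1_16 = np.std([measured_a1(16, s) for s in range(30, 60)])
        assert a1_4 / a1_16 == pytest.approx(2.0, rel=0.45)

    def test_seed_determinism(self):
        cfg = EphysGenConfig(noise_sd=20.0, n_sweeps=3, seed=9)
        a = generate_ipsc_sweeps(cfg)
        b = generate_ipsc_sweeps(cfg)
        for sa, sb in zip(a.sweeps, b.sweeps):
            assert np.array_equal(sa.trace.samples, sb.trace.samples)


class TestIODataset:
    def test_flat_gain_model_shares_expected_amplitude(self):
        base = EphysGenConfig(noise_sd=0, n_sweeps=1)
        cells = generate_io_dataset([base], [10.0, 20.0, 30.0],
                                    {10.0: 200.0, 20.0: 200.0, 30.0: 200.0},
                                    between_cell_cv=1e-6, seed=0)
        amps = [c.ground_truth.A1_true for c in cells]
        assert np.allclose(amps, amps[0], rtol=1e-3)

    def test_non_monotone_gain_rejected(self):
        base = EphysGenConfig()
        with pytest.raises(ValueError, match="monotone"):
            generate_io_dataset([base], [10.0, 20.0], {10.0: 300.0, 20.0: 200.0})

    def test_electrical_intensity_range(self):
        base = EphysGenConfig(noise_sd=0, n_sweeps=1)
        cells = generate_io_dataset([base], [10.0, 20.0, 30.0],
                                    lambda i: 10.0 * i, seed=1)
        assert sorted({c.intensity for c in cells}) == [10.0, 20.0, 30.0]


class TestContainers:
    def test_hdf5_round_trip(self, tmp_path):
        cfg = EphysGenConfig(noise_sd=10.0, n_sweeps=2, seed=3)
        cell = generate_ipsc_sweeps(cfg)
        cell.cell_id = "c7"
        cell.genotype = "Ts65Dn"
        path = str(tmp_path / "cells.h5")
        save_cells(path, [cell])
        (loaded,) = load_cells(path)
        assert loaded.cell_id == "c7"
        assert loaded.genotype == "Ts65Dn"
        assert loaded.ground_truth == cfg
        for sa, sb in zip(cell.sweeps, loaded.sweeps):
            assert np.array_equal(sa.trace.samples, sb.trace.samples)
            assert sa.stim_times == list(sb.stim_times)

    def test_long_csv_columns(self, tmp_path):
        import pandas as pd

        cfg = EphysGenConfig(noise_sd=0, n_sweeps=1)
        path = str(tmp_path / "long.csv")
        cells_to_long_csv(path, [generate_ipsc_sweeps(cfg)])
        df = pd.read_csv(path, nrows=5)
        assert list(df.columns) == ["cell_id", "sweep", "time_s", "current_pA"]
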