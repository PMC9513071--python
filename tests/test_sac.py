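"""Cable model oracles, synapse maps, drives, DSI."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from bcmotion import rf as rfm, sac, stimuli, synth
from bcmotion.errors import (
    CalibrationError,
    ConfigError,
    InvalidParameterError,
    UndefinedIndexError,
)


class TestConditionRF:
    def test_rank_one_rf_reconstructs_exactly(self):
        u = np.exp(-0.5 * ((np.arange(12) - 6) / 2.5) ** 2)
        v = np.sin(np.arange(8) / 2.0) * np.exp(-np.arange(8) / 4.0)
        rf = rfm.SpaceTimeRF(np.outer(u, v), dx=20.0, dt=0.05, origin_um=-120,
                             center_um=10.0)
        out = sac.condition_rf(rf, rank=1, mirror=False)
        # reconstruction equals the interpolated outer product (scale-free)
        uu = np.interp(out.space_centers_um, rf.space_centers_um, u)
        vv = np.interp(out.lags_s, rf.lags_s, v)
        expected = np.outer(uu, vv) / (20.0 * 1.6)
        np.testing.assert_allclose(out.weights, expected, atol=1e-9)

    def test_output_dimensions_scale_by_stated_factors(self, rds_rf):
        out = sac.condition_rf(rds_rf, mirror=False)
        assert out.n_space == round(rds_rf.n_space * 20)
        assert out.n_lag == round(rds_rf.n_lag * 1.6)

    def test_mirrored_output_is_symmetric(self, rds_rf):
        out = sac.condition_rf(rds_rf)
        np.testing.assert_allclose(out.weights, out.weights[::-1, :],
                                   atol=1e-12)

    def test_invalid_rank_raises(self, rds_rf):
        with pytest.raises(InvalidParameterError):
            sac.condition_rf(rds_rf, rank=0)
        with pytest.raises(InvalidParameterError):
            sac.condition_rf(rds_rf, rank=10**4)


class TestSynapseMap:
    def test_uniform_density_places_30_synapses(self):
        m = sac.build_synapse_map()
        assert m.total_synapses == 30
        assert m.positions_um.min() >= 0 and m.positions_um.max() <= 150

    def test_swapped_is_label_exchange_and_involution(self):
        m0 = sac.build_synapse_map(mode="original")
        m1 = sac.build_synapse_map(mode="swapped")
        np.testing.assert_array_equal(m1.positions_um, m0.positions_um)
        exchange = {"proximal": "distal", "distal": "proximal"}
        assert m1.identities == [exchange[i] for i in m0.identities]
        # applying the label exchange twice restores the original map
        assert [exchange[exchange[i]] for i in m0.identities] == m0.identities

    def test_synapse_count_conserved_across_modes(self):
        counts = {
            mode: sac.build_synapse_map(
                list(sac.DEFAULT_DENSITY_PER_10UM), mode=mode).total_synapses
            for mode in sac.WIRING_MODES
        }
        assert len(set(counts.values())) == 1

    def test_all_proximal_and_all_distal_are_single_type(self):
        for mode, expected in (("all_proximal", "proximal"),
                               ("all_distal", "distal")):
            m = sac.build_synapse_map(mode=mode)
            assert set(m.identities) == {expected}

    def test_bad_mode_or_profile_raises(self):
        with pytest.raises(ConfigError):
            sac.build_synapse_map(mode="scrambled")
        with pytest.raises(ConfigError):
            sac.build_synapse_map(density_per_10um=[2, 2])


@pytest.fixture(scope="module")
def small_rfs():
    base = synth.make_rf(synth.SyntheticRFParams(
        center_sigma_um=10, surround_sigma_um=30, surround_strength=0.3),
        dx=20.0, dt=0.05, extent_sigmas=3.0)
    rf = sac.condition_rf(base)
    return {"proximal": rf, "distal": rf}


class TestBCDrive:
    def test_zero_stimulus_gives_constant_baseline_drive(self, small_rfs):
        stim = stimuli.SpaceTimeStimulus(np.zeros((400, 50)), dx=1.0, dt=1e-3,
                                         origin_um=-125.0)
        m = sac.build_synapse_map()
        drv = sac.bc_drive(small_rfs, m, stim, baseline=0.4, scale=2.0)
        expected = np.broadcast_to(2.0 * 0.4 * m.counts[:, None],
                                   drv.currents_na.shape)
        np.testing.assert_allclose(drv.currents_na, expected)

    def test_drive_is_rectified_at_zero(self, small_rfs):
        stim = stimuli.make_moving_bar(20, 500, 150, +1, 0, 1.0, 1e-3,
                                       extent_um=(-200, 350))
        m = sac.build_synapse_map()
        drv = sac.bc_drive(small_rfs, m, stim, baseline=0.0)
        assert drv.currents_na.min() >= 0.0

    def test_single_synapse_impulse_rf_drive_is_hand_computable(self):
        w = np.zeros((5, 3))
        w[2, 0] = 1.0
        rf = rfm.SpaceTimeRF(w, dx=1.0, dt=1e-3, origin_um=-2.5, center_um=0.0)
        stim_vals = np.zeros((300, 4))
        stim_vals[75, 1] = 1.0  # flash at x=75.5-ish bin, frame 1
        stim = stimuli.SpaceTimeStimulus(stim_vals, dx=1.0, dt=1e-3,
                                         origin_um=0.0)
        m = sac.SynapseMap(np.array([75.5]), ["bc"], np.array([3]))
        drv = sac.bc_drive({"bc": rf}, m, stim, baseline=0.1, scale=2.0)
        # the recentered impulse RF sits exactly on the flashed bin:
        # drive = scale * n * (baseline + stim), rectified
        expected = 2.0 * 3 * (0.1 + stim_vals[75, :])
        np.testing.assert_allclose(drv.currents_na[0, :4], expected)

    def test_missing_identity_raises(self, small_rfs):
        stim = stimuli.SpaceTimeStimulus(np.zeros((10, 5)), dx=1.0, dt=1e-3)
        m = sac.SynapseMap(np.array([10.0]), ["unknown"], np.array([1]))
        with pytest.raises(ConfigError):
            sac.bc_drive(small_rfs, m, stim)


class TestCableOracles:
    def test_passive_steady_state_matches_cosh_solution(self):
        """Constant current at the sealed distal end of a passive uniform
        cable: the closed-form profile is cosh(x/lambda)/sinh(L/lambda)."""
        cfg = sac.SACConfig(include_soma=False, uniform_diam_um=0.2,
                            g_ca_scale=0.0)
        drv = sac.DriveSet(np.full((1, 5000), 0.002), np.array([149.9]), 1e-4)
        res = sac.simulate(cfg, drv, duration_s=0.5, record_every=10)
        v_end = res.v_mv[:, -1]
        r_cm = 0.1e-4
        r_a = cfg.r_i_ohm_cm / (np.pi * r_cm**2)
        lam = np.sqrt(cfg.r_m_ohm_cm2 * r_cm / (2 * cfg.r_i_ohm_cm))
        x = res.positions_um * 1e-4
        v_theory = cfg.e_leak_mv + (0.002e-9 * r_a * lam
                                    * np.cosh(x / lam)
                                    / np.sinh(150e-4 / lam)) * 1e3
        rel = np.abs(v_end - v_theory) / np.abs(v_theory - cfg.e_leak_mv).max()
        assert rel.max() < 0.01

    def test_isopotential_step_recovers_membrane_time_constant(self):
        """R_i -> 0 current step: exponential charging with
        tau_m = R_m * C_m = 21.7 ms."""
        cfg = sac.SACConfig(include_soma=False, uniform_diam_um=0.2,
                            g_ca_scale=0.0, r_i_ohm_cm=1e-6)
        drv = sac.DriveSet(np.full((1, 2500), 0.001), np.array([75.0]), 1e-4)
        res = sac.simulate(cfg, drv, duration_s=0.25, record_every=1)
        v = res.v_mv[0]
        t = res.times_s * 1e3
        v_inf, v0 = v[-1], v[0]
        y = (v_inf - v) / (v_inf - v0)
        mask = (y > 0.02) & (y < 0.98)
        tau = -1.0 / np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        assert tau == pytest.approx(21.7, rel=0.02)

    def test_ca_decay_time_constant_under_voltage_clamp(self):
        cfg = sac.SACConfig()
        clamp = np.concatenate([np.full(1500, -20.0), np.full(2500, -60.0)])
        res = sac.simulate(cfg, duration_s=0.4, v_clamp_mv=clamp,
                           record_every=1)
        ca = res.ca_m[-1]
        t = res.times_s * 1e3
        i0 = 1510  # 1 ms after the clamp switch (gating settled)
        y = ca[i0:i0 + 250] - ca[-1]
        mask = y > y[0] * 0.02
        tau = -1.0 / np.polyfit(t[i0:i0 + 250][mask], np.log(y[mask]), 1)[0]
        assert tau == pytest.approx(5.0, rel=0.05)

    def test_zero_drive_settles_to_nonlinear_rest(self):
        """With Ca channels on, the settled potential solves the coupled
        steady-state equations (independent fsolve oracle)."""
        cfg = sac.SACConfig()
        res = sac.simulate(cfg, duration_s=0.3, record_every=10)
        v_end = res.v_mv[:, -1]
        comp = sac._build_compartments(cfg)

        def residual(v):
            g_ca = comp.g_ca_us * sac._m_inf(v, cfg) ** 2
            out = (comp.g_leak_us * (v - cfg.e_leak_mv)
                   + g_ca * (v - cfg.e_ca_mv))
            ax = comp.g_axial_us * (v[1:] - v[:-1])  # current i -> i+1 is -ax
            out[:-1] -= ax
            out[1:] += ax
            return out

        v_star = fsolve(residual, np.full(len(v_end), cfg.e_leak_mv))
        assert np.abs(v_end - v_star).max() < 0.1

    def test_drive_scaling_never_decreases_peak_depolarization(self, small_rfs):
        stim = stimuli.make_moving_bar(20, 1000, 170, +1, 0, 1.0, 1e-3,
                                       extent_um=(-150, 300))
        m = sac.build_synapse_map()
        drv = sac.bc_drive(small_rfs, m, stim, baseline=0.05, scale=2e-4)
        cfg = sac.SACConfig()
        peaks = []
        for c in (1.0, 2.0, 4.0):
            res = sac.simulate(cfg, drv.scaled(c), record_every=10)
            peaks.append(res.v_mv.max(axis=1))
        assert np.all(peaks[1] >= peaks[0] - 1e-9)
        assert np.all(peaks[2] >= peaks[1] - 1e-9)

    def test_grid_convergence(self, small_rfs):
        stim = stimuli.make_moving_bar(20, 1000, 170, +1, 0, 1.0, 1e-3,
                                       extent_um=(-150, 300))
        m = sac.build_synapse_map()
        drv = sac.bc_drive(small_rfs, m, stim, baseline=0.05, scale=2e-4)
        coarse = sac.simulate(sac.SACConfig(), drv, record_every=10)
        fine = sac.simulate(sac.SACConfig(dt_ms=0.05, comp_len_um=0.5), drv,
                            record_every=20)
        rest_c = coarse.v_mv[-1, 0]
        rest_f = fine.v_mv[-1, 0]
        peak_c = coarse.v_mv[-1].max() - rest_c
        peak_f = fine.v_mv[-1].max() - rest_f
        assert peak_f == pytest.approx(peak_c, rel=0.01)


class TestDSI:
    def _result(self, v):
        cfg = sac.SACConfig()
        n = len(sac._build_compartments(cfg).positions_um)
        vm = np.tile(np.asarray(v, float), (n, 1))
        t = np.arange(vm.shape[1]) * 1e-3
        return sac.SACSimResult(vm, np.zeros_like(vm), t,
                                sac._build_compartments(cfg).positions_um, cfg)

    def test_identical_results_give_zero(self):
        r = self._result([-54.4, -50.0, -54.4])
        _, mean = sac.dsi(r, r)
        assert mean == pytest.approx(0.0)

    def test_silent_null_direction_gives_one(self):
        cf = self._result([-54.4, -44.4, -54.4])
        cp = self._result([-54.4, -54.4, -54.4])
        _, mean = sac.dsi(cf, cp)
        assert mean == pytest.approx(1.0)

    def test_two_to_one_ratio_gives_one_third(self):
        cf = self._result([-54.4, -34.4, -54.4])   # 20 mV depolarization
        cp = self._result([-54.4, -44.4, -54.4])   # 10 mV
        _, mean = sac.dsi(cf, cp)
        assert mean == pytest.approx(1.0 / 3.0)

    def test_no_depolarization_raises(self):
        r = self._result([-54.4, -60.0, -54.4])
        with pytest.raises(UndefinedIndexError):
            sac.dsi(r, r)


def test_wiring_manipulations_order_direction_selectivity():
    """Original wiring is the most direction selective; single-type wirings
    are weaker and swapping the type gradient reverses the preference.
    Uses the passive cable (DSI is scale-invariant there, so no calibration
    is needed)."""
    bundle = sac.default_bundle("on")
    cfg = sac.SACConfig(g_ca_scale=0.0)
    path = sac.PATH_VARIANTS["single_dendrite"]
    rfs = bundle.rfs_by_identity
    rf_half = max(rf.n_space * rf.dx / 2 for rf in rfs.values())
    extent = (path[0] - 20 - rf_half, path[1] + 20 + rf_half)
    dsis = {}
    for mode in sac.WIRING_MODES:
        syn_map = sac.build_synapse_map(bundle.density_per_10um,
                                        bundle.type_layout, mode=mode)
        res = {}
        for direction, tag in ((+1, "CF"), (-1, "CP")):
            stim = sac._protocol_stimulus(path, direction, 500.0, bundle,
                                          extent)
            preds = sac._synapse_predictions(rfs, syn_map, stim)
            baseline = bundle.baseline_frac * max(np.abs(p).max()
                                                  for p in preds)
            drv = sac._pad_settle(
                sac.bc_drive(rfs, syn_map, stim, baseline=baseline), 0.2)
            res[tag] = sac.simulate(cfg, drv, record_every=5, label=tag)
        _, dsis[mode] = sac.dsi(res["CF"], res["CP"], t_onset_s=0.2)
    assert dsis["original"] > 0
    assert dsis["original"] > dsis["all_proximal"]
    assert dsis["original"] > dsis["all_distal"]
    assert dsis["swapped"] < 0


class TestCalibration:
    def test_constant_distal_drive_calibrates_to_target(self):
        cfg = sac.SACConfig()
        drv = sac.DriveSet(np.full((1, 3000), 1.0), np.array([149.0]), 1e-4)
        scale = sac.calibrate_scale(cfg, drv)
        res = sac.simulate(cfg, drv.scaled(scale), record_every=5)
        assert res.v_mv[-1].max() == pytest.approx(-35.0, abs=0.5)

    def test_zero_drive_cannot_calibrate(self):
        cfg = sac.SACConfig()
        drv = sac.DriveSet(np.zeros((1, 100)), np.array([149.0]), 1e-4)
        with pytest.raises(CalibrationError):
            sac.calibrate_scale(cfg, drv)
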