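"""Convolution model, preference indices, surround manipulations."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from bcmotion import motion as mo, rf as rfm, stimuli as st, synth
from bcmotion.errors import (
    GridMismatchError,
    InvalidParameterError,
    UndefinedCorrelationError,
    UndefinedIndexError,
)


def brute_force_conv(rf, stim):
    """Independent dense triple-loop convolution (the oracle)."""
    n_out = stim.n_time + rf.n_lag - 1
    out = np.zeros(n_out)
    for x in range(rf.n_space):
        for t in range(n_out):
            for l in range(rf.n_lag):
                ts = t - l
                if 0 <= ts < stim.n_time:
                    out[t] += rf.weights[x, l] * stim.values[x, ts]
    return out


def _random_pair(rng, n_space=6, n_time=30, n_lag=8):
    rf = rfm.SpaceTimeRF(rng.normal(size=(n_space, n_lag)), dx=2.0, dt=0.01)
    stim = st.SpaceTimeStimulus(
        rng.uniform(-1, 1, size=(n_space, n_time)), dx=2.0, dt=0.01)
    return rf, stim


class TestConvPredict:
    def test_impulse_rf_reproduces_stimulus_row(self, rng):
        w = np.zeros((5, 6))
        w[2, 0] = 1.0
        rf = rfm.SpaceTimeRF(w, dx=2.0, dt=0.01)
        stim = st.SpaceTimeStimulus(rng.uniform(-1, 1, (5, 40)), dx=2.0, dt=0.01)
        pred = mo.conv_predict(rf, stim)
        np.testing.assert_allclose(pred.values[:40], stim.values[2], atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            rf, stim = _random_pair(rng)
            pred = mo.conv_predict(rf, stim)
            oracle = brute_force_conv(rf, stim)
            np.testing.assert_allclose(pred.values, oracle, rtol=1e-9,
                                       atol=1e-12)

    def test_linear_superposition(self, rng):
        rf1, stim = _random_pair(rng)
        rf2 = rfm.SpaceTimeRF(rng.normal(size=rf1.weights.shape), dx=2.0, dt=0.01)
        both = rf1.copy(weights=rf1.weights + rf2.weights)
        p = mo.conv_predict(both, stim).values
        p12 = mo.conv_predict(rf1, stim).values + mo.conv_predict(rf2, stim).values
        np.testing.assert_allclose(p, p12, rtol=1e-9, atol=1e-12)

    def test_grid_mismatch_without_resampling_raises(self, rng):
        rf, stim = _random_pair(rng)
        stim2 = st.SpaceTimeStimulus(stim.values, dx=3.0, dt=0.01)
        with pytest.raises(GridMismatchError):
            mo.conv_predict(rf, stim2, resample=False)

    def test_dt_resampling_conserves_response(self, rds_rf):
        stim_fine = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx,
                                       dt=1e-3)
        stim_coarse = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx,
                                         dt=5e-3)
        p_fine = mo.conv_predict(rds_rf, stim_fine)
        p_coarse = mo.conv_predict(rds_rf, stim_coarse)
        t = p_coarse.times_s
        fine_on_coarse = np.interp(t, p_fine.times_s, p_fine.values)
        r = np.corrcoef(fine_on_coarse, p_coarse.values)[0, 1]
        assert r > 0.99
        assert p_coarse.values.max() == pytest.approx(p_fine.values.max(),
                                                      rel=0.05)


class TestPreferenceIndex:
    @pytest.mark.parametrize("p1,p2,expected", [
        ([0, 2, 0], [0, 2, 0], 0.0),
        ([1, 3], [0, -1], 1.0),
        ([3, 0], [1, 0], 0.5),
    ])
    def test_known_values(self, p1, p2, expected):
        assert mo.preference_index(np.array(p1, float),
                                   np.array(p2, float)) == pytest.approx(expected)

    def test_undefined_when_both_peaks_zero(self):
        with pytest.raises(UndefinedIndexError):
            mo.preference_index(np.array([-1.0, 0.0]), np.array([0.0, -2.0]))


class TestRdsTuning:
    def test_rds_rf_prefers_originating_motion(self, rds_rf):
        tun = mo.rds_tuning(rds_rf, [100, 250, 500, 1000, 2000])
        assert np.all(tun.preference > 0)

    def test_surround_free_rf_has_no_preference(self, surround_free_rf):
        tun = mo.rds_tuning(surround_free_rf, [250, 500, 1000])
        assert np.all(np.abs(tun.preference) < 0.1)

    def test_laterally_symmetric_rf_has_no_side_preference(self, rds_rf):
        tun = mo.rds_tuning(rds_rf, [500], pairing="left_vs_right")
        assert abs(tun.preference[0]) < 1e-6

    def test_rds_rf_prefers_looming(self, rds_rf):
        tun = mo.rds_tuning(rds_rf, [400, 800], pairing="loom_vs_recede")
        assert np.all(tun.preference > 0)

    def test_off_rf_mirrors_on_preference(self, rds_rf):
        off = rds_rf.copy(weights=-rds_rf.weights, polarity=-1)
        t_on = mo.rds_tuning(rds_rf, [500]).preference[0]
        t_off = mo.rds_tuning(off, [500]).preference[0]
        assert t_off == pytest.approx(t_on)

    def test_empty_or_invalid_velocities_raise(self, rds_rf):
        with pytest.raises(InvalidParameterError):
            mo.rds_tuning(rds_rf, [])
        with pytest.raises(InvalidParameterError):
            mo.rds_tuning(rds_rf, [-100])


class TestScaleSurround:
    def test_identity_and_zero(self, rds_rf):
        same = mo.scale_surround(rds_rf, 1.0)
        np.testing.assert_array_equal(same.weights, rds_rf.weights)
        none = mo.scale_surround(rds_rf, 0.0)
        assert (none.weights * rds_rf.polarity).min() >= 0.0
        center_mask = rds_rf.weights * rds_rf.polarity > 0
        np.testing.assert_array_equal(none.weights[center_mask],
                                      rds_rf.weights[center_mask])

    def test_hand_built_matrix(self):
        w = np.array([[-0.2, 0.1, 0.0],
                      [0.5, 1.0, -0.4],
                      [-0.3, 0.2, 0.1]])
        rf = rfm.SpaceTimeRF(w, dx=2.0, dt=0.05, polarity=+1)
        out = mo.scale_surround(rf, 2.0)
        expected = np.array([[-0.4, 0.1, 0.0],
                             [0.5, 1.0, -0.8],
                             [-0.6, 0.2, 0.1]])
        np.testing.assert_allclose(out.weights, expected)

    def test_negative_factor_raises(self, rds_rf):
        with pytest.raises(InvalidParameterError):
            mo.scale_surround(rds_rf, -0.5)


class TestDecompose:
    def test_center_plus_surround_equals_full(self, rds_rf):
        stim = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx)
        c, s = mo.decompose_center_surround(rds_rf, stim)
        full = mo.conv_predict(rds_rf, stim)
        np.testing.assert_allclose(c.values + s.values, full.values,
                                   rtol=1e-9, atol=1e-12)

    def test_surround_free_rf_gives_null_surround_trace(self, surround_free_rf):
        stim = st.make_moving_bar(extent_um=(-120, 120), dx=surround_free_rf.dx)
        _, s = mo.decompose_center_surround(surround_free_rf, stim)
        # the separable RF's mass is confined to the fitted center region
        assert np.abs(s.values).max() < 0.05 * np.abs(
            mo.conv_predict(surround_free_rf, stim).values).max()

    def test_surround_trough_more_offset_for_outward_motion(self, rds_rf):
        """During outward (originating) motion the surround trough trails the
        center peak by more than during inward motion."""
        s_out, s_in = mo._stimulus_pair(rds_rf, 500.0, "originate_vs_terminate",
                                        100.0, 20.0, 1e-3, 0, 7, 20.0)
        offsets = {}
        for stim, key in ((s_out, "out"), (s_in, "in")):
            c, s = mo.decompose_center_surround(rds_rf, stim)
            offsets[key] = (np.argmin(s.values) - np.argmax(c.values)) * stim.dt
        assert offsets["out"] > offsets["in"]


class TestValidatePrediction:
    def test_self_and_anti_correlation(self, rds_rf):
        stim = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx)
        pred = mo.conv_predict(rds_rf, stim)
        assert mo.validate_prediction(pred, pred.values) == pytest.approx(1.0)
        assert mo.validate_prediction(pred, -pred.values) == pytest.approx(-1.0)

    def test_noisy_observation_within_attenuation_bound(self, rds_rf, rng):
        stim = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx)
        pred = mo.conv_predict(rds_rf, stim)
        snr = 2.0
        sd = np.std(pred.values) / snr
        obs = pred.values + sd * rng.normal(size=len(pred.values))
        r = mo.validate_prediction(pred, obs)
        expected = 1.0 / np.sqrt(1.0 + 1.0 / snr**2)  # analytic attenuation
        assert r == pytest.approx(expected, abs=0.05)

    def test_constant_observation_raises(self, rds_rf):
        stim = st.make_moving_bar(extent_um=(-120, 120), dx=rds_rf.dx)
        pred = mo.conv_predict(rds_rf, stim)
        with pytest.raises(UndefinedCorrelationError):
            mo.validate_prediction(pred, np.zeros(len(pred.values)))


class TestCoherenceScan:
    def test_amplitude_increases_with_coherence(self, rds_rf):
        df = mo.coherence_scan(rds_rf, n_orders=60, seed=2)
        rand = df[~df.ordered]
        rho = spearmanr(rand.k, rand.peak).statistic
        assert rho > 0

    @pytest.mark.parametrize("seed", [1, 3, 7])
    def test_ordered_sequence_beats_tested_random_orders(self, seed):
        """Apparent motion is stronger than interleaved random sequences:
        the ordered sequence beats randomly drawn test orders and sits in
        the top decile of the random-order amplitude distribution."""
        rf = synth.make_rf(synth.SyntheticRFParams(surround_strength=0.3))
        df = mo.coherence_scan(rf, n_orders=60, seed=seed)
        ordered_peak = df[df.ordered].peak.iloc[0]
        rand = df[~df.ordered]
        # the two 'experimentally tested' random sequences (first draws)
        assert ordered_peak > rand.peak.iloc[0]
        assert ordered_peak > rand.peak.iloc[1]
        assert ordered_peak >= np.quantile(rand.peak, 0.9)
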