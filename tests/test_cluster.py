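"""RF alignment, half-RF cropping, mixture clustering, stratification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bcmotion import cluster as cl, rf as rfm, synth
from bcmotion.errors import (
    FeatureMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)


def _shifted_copies(rf, shifts_bins):
    out = []
    for s in shifts_bins:
        w = np.zeros_like(rf.weights)
        if s >= 0:
            w[s:, :] = rf.weights[: rf.n_space - s, :]
        else:
            w[:s, :] = rf.weights[-s:, :]
        out.append(rf.copy(weights=w, center_um=rf.center_um + s * rf.dx))
    return out


class TestAlignCenters:
    def test_shifted_identical_rfs_realign(self, rds_rf):
        rfs = _shifted_copies(rds_rf, [-6, -3, 0, 3, 6])
        aligned = cl.align_centers(rfs)
        ref = aligned[2].weights
        mid = rds_rf.n_space // 2
        for a in aligned:
            # centers coincide at the grid middle; cores match exactly
            assert a.center_um == pytest.approx(
                a.origin_um + (mid + 0.5) * a.dx)
            core = slice(20, rds_rf.n_space - 20)
            np.testing.assert_allclose(a.weights[core], ref[core], atol=1e-12)

    def test_single_rf_returned_centered(self, rds_rf):
        out = cl.align_centers([rds_rf])
        assert len(out) == 1
        w = out[0].weights * out[0].polarity
        i0 = np.unravel_index(np.argmax(w), w.shape)[0]
        assert i0 == rds_rf.n_space // 2

    def test_two_shapes_form_two_preclusters(self):
        a = synth.make_rf(synth.SyntheticRFParams(surround_strength=0.1,
                                                  center_tau_s=0.03))
        b = synth.make_rf(synth.SyntheticRFParams(surround_strength=0.8,
                                                  surround_latency_s=0.08))
        rfs = _shifted_copies(a, [0, 2]) + _shifted_copies(b, [0, -2])
        aligned = cl.align_centers(rfs)
        mid = a.n_space // 2
        for x in aligned:
            w = x.weights * x.polarity
            assert abs(np.unravel_index(np.argmax(w), w.shape)[0] - mid) <= 1

    def test_empty_input_raises(self):
        with pytest.raises(InvalidParameterError):
            cl.align_centers([])


class TestCropHalf:
    def test_symmetric_rf_halves_coincide(self):
        # odd grid with the center exactly on the middle bin
        x = np.arange(41) - 20.0
        k = np.exp(-np.arange(10) / 3.0)
        w = np.outer(np.exp(-0.5 * (x / 6.0) ** 2), k)
        rf = rfm.SpaceTimeRF(w, dx=2.0, dt=0.05, origin_um=-41.0,
                             center_um=0.0)
        left = cl.crop_half(rf, side="left")
        right = cl.crop_half(rf, side="right")
        np.testing.assert_allclose(left, right, atol=1e-12)

    def test_vector_length(self, rds_rf):
        aligned = cl.align_centers([rds_rf])[0]
        v = cl.crop_half(aligned, side="right", width_bins=10)
        assert v.shape == (10 * aligned.n_lag,)

    def test_population_crop_common_width(self, rds_rf):
        rfs = cl.align_centers(_shifted_copies(rds_rf, [0, 4, -4]))
        mat = cl.crop_half_population(rfs)
        assert mat.shape[0] == 3
        assert mat.shape[1] % rds_rf.n_lag == 0


def _planted_vectors(n_types=2, rois=20, seed=0):
    rfs, table = synth.make_population(
        n_types=n_types, rois_per_type=rois, seed=seed,
        param_ranges={"surround_strength": (0.1, 0.8),
                      "surround_latency_s": (0.02, 0.08)},
    )
    aligned = cl.align_centers(rfs)
    vectors = cl.crop_half_population(aligned)
    return vectors, table["type"].to_numpy(), table["ipl_depth"].to_numpy()


class TestFitClusterModel:
    def test_recovers_two_planted_types(self):
        vectors, truth, depths = _planted_vectors(seed=5)
        model = cl.fit_cluster_model(vectors, depths, k_range=range(2, 7),
                                     seed=0)
        assert model.k_selected == 2
        assert adjusted_rand_score(truth, model.labels_) >= 0.95

    def test_works_without_depth_feature(self):
        vectors, truth, _ = _planted_vectors(seed=6)
        model = cl.fit_cluster_model(vectors, None, k_range=range(2, 7), seed=0)
        assert not model.depth_included
        assert model.k_selected == 2
        assert adjusted_rand_score(truth, model.labels_) >= 0.95

    def test_identical_vectors_select_minimum_k(self):
        vectors = np.ones((30, 40))
        model = cl.fit_cluster_model(vectors, None, k_range=range(2, 5), seed=0)
        assert model.k_selected == 2

    def test_deterministic_under_seed(self):
        vectors, _, depths = _planted_vectors(seed=7)
        m1 = cl.fit_cluster_model(vectors, depths, k_range=range(2, 5), seed=3)
        m2 = cl.fit_cluster_model(vectors, depths, k_range=range(2, 5), seed=3)
        assert m1.bic_curve == m2.bic_curve
        np.testing.assert_array_equal(m1.labels_, m2.labels_)

    def test_k_selected_minimizes_bic(self):
        vectors, _, depths = _planted_vectors(seed=8)
        model = cl.fit_cluster_model(vectors, depths, k_range=range(2, 6), seed=0)
        assert model.k_selected == min(model.bic_curve, key=model.bic_curve.get)

    def test_too_few_samples_raise(self):
        with pytest.raises(InsufficientDataError):
            cl.fit_cluster_model(np.ones((3, 10)), None, k_range=range(5, 8))


class TestPredictCluster:
    def test_training_vectors_keep_their_assignment(self):
        vectors, _, depths = _planted_vectors(seed=9)
        model = cl.fit_cluster_model(vectors, depths, k_range=range(2, 5), seed=0)
        labels, probs = cl.predict_cluster(model, vectors, depths)
        np.testing.assert_array_equal(labels, model.labels_)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_raises(self):
        vectors, _, depths = _planted_vectors(seed=10)
        model = cl.fit_cluster_model(vectors, depths, k_range=range(2, 5), seed=0)
        with pytest.raises(FeatureMismatchError):
            cl.predict_cluster(model, vectors[:, :10], depths)
        with pytest.raises(FeatureMismatchError):
            cl.predict_cluster(model, vectors, None)


class TestStratification:
    def test_identical_profiles_correlate_perfectly(self, rng):
        grid = np.linspace(0, 1, 101)
        p = cl.kde_profile(rng.uniform(0.4, 0.6, 200), "a", grid)
        q = cl.StratificationProfile(grid, p.density.copy(), "b")
        corr = cl.stratification_correlation([p], [q])
        assert corr.iloc[0, 0] == pytest.approx(1.0)

    def test_disjoint_bands_anticorrelate(self, rng):
        grid = np.linspace(0, 1, 101)
        a = cl.kde_profile(rng.normal(0.25, 0.03, 300), "a", grid)
        b = cl.kde_profile(rng.normal(0.75, 0.03, 300), "b", grid)
        corr = cl.stratification_correlation([a], [b])
        assert corr.iloc[0, 0] < 0

    def test_planted_band_matches_its_reference(self, rng):
        grid = np.linspace(0, 1, 101)
        refs = [cl.kde_profile(rng.normal(mu, 0.04, 400), f"ref{i}", grid)
                for i, mu in enumerate((0.2, 0.5, 0.8))]
        clus = cl.kde_profile(rng.normal(0.5, 0.05, 150), "c0", grid)
        corr = cl.stratification_correlation([clus], refs)
        assert corr.loc["c0"].idxmax() == "ref1"
        matches = cl.match_types(corr, threshold=0.7)
        assert matches["c0"] == "ref1"

    def test_zero_variance_profile_raises(self):
        grid = np.linspace(0, 1, 11)
        flat = cl.StratificationProfile(grid, np.ones(11), "flat")
        with pytest.raises(UndefinedCorrelationError):
            cl.stratification_correlation([flat], [flat])

    def test_mismatched_grids_raise(self, rng):
        a = cl.kde_profile(rng.uniform(0, 1, 50), "a", np.linspace(0, 1, 50))
        b = cl.kde_profile(rng.uniform(0, 1, 50), "b", np.linspace(0, 1, 80))
        with pytest.raises(InvalidParameterError):
            cl.stratification_correlation([a], [b])


def test_cluster_count_recovery_rate():
    """2-3 well-separated planted types: the BIC-selected k matches the
    planted count in >= 80% of seeded runs."""
    hits = 0
    runs = 10
    for seed in range(runs):
        n_types = 2 + seed % 2
        rfs, table = synth.make_population(
            n_types=n_types, rois_per_type=20, seed=seed,
            param_ranges={"surround_strength": (0.1, 0.8),
                          "surround_latency_s": (0.02, 0.08)},
        )
        vectors = cl.crop_half_population(cl.align_centers(rfs))
        model = cl.fit_cluster_model(vectors, table["ipl_depth"].to_numpy(),
                                     k_range=range(2, 7), seed=seed)
        hits += model.k_selected == n_types
    assert hits / runs >= 0.8
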