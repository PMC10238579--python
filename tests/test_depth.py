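"""PCA model contracts, eigenspectrum reconstruction, and the C1 depth variable."""

import numpy as np
import pytest

import sleepdepth as sd
from sleepdepth.depth import ORIENTATION_SPLIT_HZ, STAGE_NUMERIC


def toy_sv(values, f_start=1, resolution=1 / 30, gamma=0.5):
    values = np.asarray(values, dtype=float)
    return sd.SpectralVectors(
        values,
        gamma=gamma,
        freq_resolution=resolution,
        bin_indices=np.arange(f_start, f_start + values.shape[1]),
    )


@pytest.fixture(scope="module")
def random_model():
    rng = np.random.default_rng(0)
    sv = toy_sv(np.abs(rng.normal(1.0, 0.3, size=(40, 8))))
    return sv, sd.fit_spectral_pca(sv, n_components=5)


class TestFitSpectralPCA:
    def test_closed_form_two_bin_eigenvalues(self):
        # four points constructed so the sample covariance is [[2,1],[1,2]]
        u1 = np.array([1.0, 1.0]) / np.sqrt(2)
        u2 = np.array([1.0, -1.0]) / np.sqrt(2)
        a, b = np.sqrt(4.5), np.sqrt(1.5)
        data = np.vstack([a * u1, -a * u1, b * u2, -b * u2]) + 5.0
        model = sd.fit_spectral_pca(toy_sv(data), n_components=2)
        np.testing.assert_allclose(model.explained_variance, [3.0, 1.0], atol=1e-10)

    def test_single_direction_data(self):
        rng = np.random.default_rng(1)
        direction = np.array([0.5, -0.5, 0.5, -0.5])
        data = 3.0 + rng.normal(size=(30, 1)) * direction
        model = sd.fit_spectral_pca(toy_sv(data), n_components=3)
        np.testing.assert_allclose(
            np.abs(model.eigenspectra[0]), np.abs(direction), atol=1e-8
        )
        assert np.all(model.explained_variance[1:] < 1e-20 * model.explained_variance[0])

    def test_orthonormal_rows_and_descending_variance(self, random_model):
        _, model = random_model
        gram = model.eigenspectra @ model.eigenspectra.T
        np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_scores_uncorrelated(self, random_model):
        sv, model = random_model
        scores = sd.project(model, sv)
        corr = np.corrcoef(scores, rowvar=False)
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.max(np.abs(off)) < 1e-8

    def test_explained_variance_sums_to_total(self, random_model):
        sv, _ = random_model
        full = sd.fit_spectral_pca(sv, n_components=sv.n_bins)
        total = np.var(sv.values, axis=0, ddof=1).sum()
        assert full.explained_variance.sum() == pytest.approx(total, rel=1e-6)

    def test_too_few_epochs_is_error(self):
        with pytest.raises(ValueError):
            sd.fit_spectral_pca(toy_sv(np.ones((3, 5))), n_components=3)

    def test_orientation_rule_holds(self, random_model):
        _, model = random_model
        high = model.bin_indices * model.freq_resolution > ORIENTATION_SPLIT_HZ
        for row in model.eigenspectra:
            assert row[high].sum() - row[~high].sum() >= 0


class TestProjectReconstruct:
    def test_mean_spectrum_projects_to_zero(self, random_model):
        sv, model = random_model
        scores = sd.project(model, toy_sv(model.mean_spectrum[None, :]))
        np.testing.assert_allclose(scores, 0, atol=1e-8)

    def test_unit_eigenspectrum_displacement(self, random_model):
        _, model = random_model
        v = model.mean_spectrum + 2.5 * model.eigenspectra[1]
        scores = sd.project(model, toy_sv(v[None, :]))[0]
        expected = np.zeros(model.n_components)
        expected[1] = 2.5
        np.testing.assert_allclose(scores, expected, atol=1e-8)

    def test_roundtrip_on_random_coordinates(self, random_model):
        _, model = random_model
        rng = np.random.default_rng(2)
        coords = rng.normal(size=model.n_components)
        v = sd.reconstruct_spectrum(model, coords)
        back = sd.project(model, toy_sv(v[None, :]))[0]
        np.testing.assert_allclose(back, coords, atol=1e-10)

    def test_zero_coords_give_mean(self, random_model):
        _, model = random_model
        np.testing.assert_allclose(
            sd.reconstruct_spectrum(model, np.zeros(2)), model.mean_spectrum
        )

    def test_full_rank_reconstruction_exact(self):
        rng = np.random.default_rng(3)
        sv = toy_sv(np.abs(rng.normal(1, 0.3, size=(20, 6))))
        model = sd.fit_spectral_pca(sv, n_components=6)
        recon = np.vstack(
            [sd.reconstruct_spectrum(model, c) for c in sd.project(model, sv)]
        )
        np.testing.assert_allclose(recon, sv.values, atol=1e-8)

    def test_truncation_error_monotone(self, random_model):
        sv, model = random_model
        coords = sd.project(model, sv)
        errs = []
        for n in range(model.n_components + 1):
            recon = np.vstack(
                [sd.reconstruct_spectrum(model, c[:n]) for c in coords]
            )
            errs.append(np.sum((recon - sv.values) ** 2))
        assert np.all(np.diff(errs) <= 1e-9)

    def test_grid_mismatch_is_error(self, random_model):
        _, model = random_model
        with pytest.raises(ValueError, match="grid"):
            sd.project(model, toy_sv(np.ones((2, 4))))


class TestOrientationSemantics:
    def test_delta_boost_lowers_depth(self):
        """Injecting low-frequency (delta) power must decrease the C1 score."""
        rng = np.random.default_rng(4)
        n_bins = 150  # 5 Hz at 1/30 Hz resolution
        freqs = np.arange(1, n_bins + 1) / 30.0
        base = np.abs(rng.normal(1.0, 0.05, size=(200, n_bins)))
        delta_mask = freqs <= 3.0
        boost = rng.exponential(0.5, size=200)
        spectra = base + boost[:, None] * delta_mask - 0.3 * boost[:, None] * ~delta_mask
        sv = toy_sv(np.abs(spectra))
        model = sd.fit_spectral_pca(sv, n_components=2)
        # the delta-contrast component is the top variance direction here
        scores = sd.project(model, sv)
        corr = np.corrcoef(scores[:, 0], boost)[0, 1]
        assert corr < -0.9


class TestSleepDepth:
    def test_identical_recordings_identical_series(self, small_cohort, small_model_scores):
        model, _, _ = small_model_scores
        rec, hyp = small_cohort[0]
        er = sd.preprocess(rec, labels=hyp.stages)
        a = sd.sleep_depth(er, model)
        b = sd.sleep_depth(er, model)
        np.testing.assert_array_equal(a.values, b.values)

    def test_stage_means_ordered_by_depth(self, small_prepared, small_model_scores):
        model, _, _ = small_model_scores
        er, _ = small_prepared[0]
        ds = sd.sleep_depth(er, model)
        means = {
            s: ds.values[er.labels == s].mean()
            for s in ("W", "N3")
            if np.any(er.labels == s)
        }
        assert means["W"] > means["N3"]

    def test_gamma_mismatch_warns(self, small_prepared):
        er, _ = small_prepared[0]
        sv = sd.spectral_vectors(er, gamma=1.0)
        model = sd.fit_spectral_pca(sv, n_components=2)
        with pytest.warns(UserWarning, match="gamma"):
            sd.sleep_depth(er, model)

    def test_artifact_gaps_carried_in_epoch_indices(self, small_cohort, small_model_scores):
        model, _, _ = small_model_scores
        rec, hyp = small_cohort[0]
        flags = np.zeros(len(hyp), dtype=bool)
        flags[[5, 6, 7]] = True
        er = sd.preprocess(rec, labels=hyp.stages, artifact_flags=flags)
        ds = sd.sleep_depth(er, model)
        assert 5 not in ds.epoch_indices and len(ds) == len(hyp) - 3


class TestHypnogram:
    def test_numeric_mapping(self):
        hyp = sd.Hypnogram(["W", "REM", "N1", "N2", "N3"])
        np.testing.assert_array_equal(hyp.numeric, [0, -1, -2, -3, -4])
        assert STAGE_NUMERIC == {"W": 0, "REM": -1, "N1": -2, "N2": -3, "N3": -4}

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="N4"):
            sd.Hypnogram(["W", "N4"])


class TestDepthHypnogramCorrelation:
    def test_perfect_tracking_gives_one(self):
        hyp = sd.Hypnogram(["W", "N1", "N2", "N3", "N2", "W"])
        ds = sd.DepthSeries(hyp.numeric)
        assert sd.depth_hypnogram_correlation(ds, hyp) == pytest.approx(1.0)

    def test_sign_flip_still_one(self):
        hyp = sd.Hypnogram(["W", "N1", "N2", "N3"])
        ds = sd.DepthSeries(-hyp.numeric)
        assert sd.depth_hypnogram_correlation(ds, hyp) == pytest.approx(1.0)

    def test_constant_hypnogram_is_error(self):
        hyp = sd.Hypnogram(["W", "W", "W"])
        ds = sd.DepthSeries([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="constant"):
            sd.depth_hypnogram_correlation(ds, hyp)

    def test_gap_alignment_uses_epoch_indices(self):
        hyp = sd.Hypnogram(["W", "N1", "N2", "N3", "N3", "N2"])
        ds = sd.DepthSeries(
            hyp.numeric[[0, 2, 3, 5]], epoch_indices=[0, 2, 3, 5]
        )
        assert sd.depth_hypnogram_correlation(ds, hyp) == pytest.approx(1.0)

    def test_amplitude_invariance_of_correlation(self, small_cohort, small_model_scores):
        model, _, _ = small_model_scores
        rec, hyp = small_cohort[0]
        er1 = sd.preprocess(rec, labels=hyp.stages)
        rec_scaled = sd.Recording(3.0 * rec.signal, rec.sampling_rate)
        er2 = sd.preprocess(rec_scaled, labels=hyp.stages)
        r1 = sd.depth_hypnogram_correlation(sd.sleep_depth(er1, model), hyp)
        r2 = sd.depth_hypnogram_correlation(sd.sleep_depth(er2, model), hyp)
        assert r1 == pytest.approx(r2, abs=1e-10)
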