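"""Shared fixtures: synthetic cohorts at two scales and a globally fitted PCA."""

import numpy as np
import pytest

import sleepdepth as sd


@pytest.fixture(scope="session")
def cohort12():
    """Full-scale synthetic study: 12 subjects, 8-h nights at 128 Hz."""
    return sd.simulate_cohort(12, seed=0)


@pytest.fixture(scope="session")
def prepared12(cohort12):
    return [(sd.preprocess(rec, labels=hyp.stages), hyp) for rec, hyp in cohort12]


@pytest.fixture(scope="session")
def pooled12(prepared12):
    """Pooled gamma=1/2 spectral vectors and stage labels of the 12 subjects."""
    svs = [sd.spectral_vectors(er, gamma=0.5) for er, _ in prepared12]
    pooled = sd.SpectralVectors(
        np.vstack([sv.values for sv in svs]),
        gamma=0.5,
        freq_resolution=svs[0].freq_resolution,
        bin_indices=svs[0].bin_indices,
    )
    labels = np.concatenate([er.labels for er, _ in prepared12])
    return pooled, labels


@pytest.fixture(scope="session")
def model12(pooled12):
    pooled, _ = pooled12
    return sd.fit_spectral_pca(pooled, n_components=3)


@pytest.fixture(scope="session")
def small_cohort():
    """Cheap cohort for unit tests: 3 subjects, 2-h nights."""
    cfg = sd.SynthConfig(n_epochs=240, seed=1)
    return sd.simulate_cohort(3, cfg, seed=1)


@pytest.fixture(scope="session")
def small_prepared(small_cohort):
    return [(sd.preprocess(rec, labels=hyp.stages), hyp) for rec, hyp in small_cohort]


@pytest.fixture(scope="session")
def small_model_scores(small_prepared):
    svs = [sd.spectral_vectors(er, gamma=0.5) for er, _ in small_prepared]
    pooled = sd.SpectralVectors(
        np.vstack([sv.values for sv in svs]),
        gamma=0.5,
        freq_resolution=svs[0].freq_resolution,
        bin_indices=svs[0].bin_indices,
    )
    model = sd.fit_spectral_pca(pooled, n_components=3)
    labels = np.concatenate([er.labels for er, _ in small_prepared])
    return model, sd.project(model, pooled), labels
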