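"""PCA over spectral vectors and the continuous sleep-depth variable C1.

A PCA fitted to pooled spectral vectors yields *eigenspectra*: frequency-domain
loading patterns dV_i(f) such that any spectrum can be written as

    V(f) = V_mean(f) + sum_i  C_i * dV_i(f).

With the scaling exponent gamma = 1/2, the component with zero-based index 1
contrasts slow (< 3 Hz, delta-range) against fast (> 3 Hz) spectral content and
tracks sleep depth: its per-epoch score C1(k) rises when sleep becomes shallower
and correlates strongly with the hypnogram.

PCA leaves the sign of each eigenvector free.  To make "larger C1 = shallower
sleep" hold without supervision, every eigenspectrum is oriented so that its
summed loading above 3 Hz is at least its summed loading at or below 3 Hz
(ties broken by making the largest-magnitude loading positive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .spectra import EpochedRecording, SpectralVectors, spectral_vectors

__all__ = [
    "SpectralPCAModel",
    "DepthSeries",
    "Hypnogram",
    "STAGE_NUMERIC",
    "fit_spectral_pca",
    "project",
    "reconstruct_spectrum",
    "sleep_depth",
    "depth_hypnogram_correlation",
]

#: Numeric hypnogram mapping: Wake on top, deeper stages more negative.
STAGE_NUMERIC = {"W": 0, "REM": -1, "N1": -2, "N2": -3, "N3": -4}

#: Delta/rest boundary used by the orientation rule, in Hz.
ORIENTATION_SPLIT_HZ = 3.0


@dataclass
class Hypnogram:
    """Per-epoch sleep-stage labels with the standard numeric mapping."""

    stages: np.ndarray

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages)
        unknown = set(np.unique(self.stages)) - set(STAGE_NUMERIC)
        if unknown:
            raise ValueError(f"unknown stage label(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def numeric(self) -> np.ndarray:
        """Wake=0, REM=-1, N1=-2, N2=-3, N3=-4."""
        return np.array([STAGE_NUMERIC[s] for s in self.stages], dtype=float)


@dataclass
class DepthSeries:
    """C1 value per epoch, with original epoch positions for alignment."""

    values: np.ndarray
    epoch_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.epoch_indices is None:
            self.epoch_indices = np.arange(len(self.values))
        else:
            self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)
        if len(self.epoch_indices) != len(self.values):
            raise ValueError("epoch_indices and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SpectralPCAModel:
    """Mean spectrum plus ordered, orientation-fixed orthonormal eigenspectra."""

    mean_spectrum: np.ndarray
    eigenspectra: np.ndarray  # N_c x F, rows orthonormal
    explained_variance: np.ndarray  # descending
    gamma: float
    freq_resolution: float
    bin_indices: np.ndarray
    orientation_applied: bool = True

    @property
    def n_components(self) -> int:
        return self.eigenspectra.shape[0]

    @property
    def n_bins(self) -> int:
        return self.eigenspectra.shape[1]


def _orient_eigenspectra(
    components: np.ndarray, frequencies: np.ndarray
) -> np.ndarray:
    """Flip eigenvector signs so high-frequency loading mass dominates.

    For each row: (sum of loadings at > 3 Hz) - (sum at <= 3 Hz) must be >= 0;
    an exact tie is resolved by making the largest-magnitude loading positive.
    """
    high = frequencies > ORIENTATION_SPLIT_HZ
    oriented = components.copy()
    for i, row in enumerate(oriented):
        score = row[high].sum() - row[~high].sum()
        if score < 0:
            oriented[i] = -row
        elif score == 0 and row[np.argmax(np.abs(row))] < 0:
            oriented[i] = -row
    return oriented


def fit_spectral_pca(sv: SpectralVectors, n_components: int = 3) -> SpectralPCAModel:
    """Fit a PCA to pooled spectral vectors.

    Components are eigenvectors of the covariance of the spectral vectors
    (mean-centering only, no per-bin variance scaling), ordered by descending
    explained variance and indexed from zero, then sign-oriented.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if sv.n_epochs <= n_components:
        raise ValueError(
            f"need more epochs ({sv.n_epochs}) than components ({n_components})"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(sv.values)
    frequencies = sv.bin_indices * sv.freq_resolution
    eigenspectra = _orient_eigenspectra(pca.components_, frequencies)
    return SpectralPCAModel(
        mean_spectrum=pca.mean_,
        eigenspectra=eigenspectra,
        explained_variance=pca.explained_variance_,
        gamma=sv.gamma,
        freq_resolution=sv.freq_resolution,
        bin_indices=sv.bin_indices.copy(),
    )


def _check_grids(model: SpectralPCAModel, sv: SpectralVectors) -> None:
    if model.n_bins != sv.n_bins or not np.array_equal(
        model.bin_indices, sv.bin_indices
    ):
        raise ValueError("bin grids of model and spectral vectors do not match")


def project(model: SpectralPCAModel, sv: SpectralVectors) -> np.ndarray:
    """Component scores: inner products of centred spectra with the eigenspectra.

    Returns a K x N_c matrix; row k holds (C_0(k), ..., C_{N_c-1}(k)).
    """
    _check_grids(model, sv)
    return (sv.values - model.mean_spectrum) @ model.eigenspectra.T


def reconstruct_spectrum(model: SpectralPCAModel, coords: Sequence[float]) -> np.ndarray:
    """Mean spectrum plus coordinate-weighted eigenspectra.

    ``coords`` may be shorter than the model's component count (truncated
    reconstruction); all-zero coordinates return the mean spectrum.
    """
    coords = np.asarray(coords, dtype=float).ravel()
    if len(coords) > model.n_components:
        raise ValueError(
            f"{len(coords)} coordinates for a {model.n_components}-component model"
        )
    return model.mean_spectrum + coords @ model.eigenspectra[: len(coords)]


def sleep_depth(
    er: EpochedRecording,
    model: SpectralPCAModel,
    component: int = 1,
    f_max: float | None = None,
) -> DepthSeries:
    """Per-epoch sleep depth: the oriented score of PCA component 1 (zero-based).

    The recording must already be artifact-cleaned and z-scored; its spectral
    vectors are computed with the model's gamma.  Larger values mean shallower
    sleep.  A model trained with gamma != 1/2 triggers a warning, since the
    depth interpretation is established for the square-root scaling.
    """
    if model.gamma != 0.5:
        warnings.warn(
            f"model was fitted with gamma={model.gamma}; sleep depth is "
            "calibrated for gamma=0.5",
            UserWarning,
            stacklevel=2,
        )
    if f_max is None:
        f_max = model.bin_indices[-1] * model.freq_resolution
    sv = spectral_vectors(er, gamma=model.gamma, f_max=f_max)
    _check_grids(model, sv)
    scores = project(model, sv)
    if component >= scores.shape[1]:
        raise ValueError(
            f"component {component} not available in a "
            f"{model.n_components}-component model"
        )
    return DepthSeries(scores[:, component], epoch_indices=er.epoch_indices)


def depth_hypnogram_correlation(ds: DepthSeries, hyp: Hypnogram) -> float:
    """|Pearson r| between the depth series and the numeric hypnogram.

    The hypnogram is indexed by original epoch position, so artifact gaps in
    the depth series are handled by restricting to its ``epoch_indices``.
    """
    numeric = hyp.numeric[ds.epoch_indices]
    if len(numeric) != len(ds.values):
        raise ValueError("length mismatch between depth series and hypnogram")
    if np.ptp(ds.values) == 0 or np.ptp(numeric) == 0:
        raise ValueError("correlation undefined for a constant series")
    r, _ = stats.pearsonr(ds.values, numeric)
    return float(abs(r))
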