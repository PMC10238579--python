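"""Generic pre-processing of single-channel sleep EEG.

The pipeline unit is the 30-s epoch.  A full-night recording is segmented into
epochs, artifact-flagged epochs are dropped, the remaining samples are z-scored
with the pooled per-recording mean and standard deviation (suppressing
between-subject amplitude differences while keeping within-night stage
structure), and each epoch is Fourier transformed.  The modulus of the complex
amplitudes, raised to a scaling exponent ``gamma``, truncated at ``f_max``
(default 35 Hz) and with the DC bin excluded, forms the per-epoch *spectral
vector* V_k(f) that all downstream analysis operates on.

Conventions: unnormalized FFT (moduli scale with the epoch length T); bin ``f``
corresponds to frequency ``f / epoch_seconds`` Hz, so at 30-s epochs the
resolution is 1/30 Hz and the 35 Hz cutoff retains exactly 1050 bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EpochedRecording",
    "SpectralVectors",
    "segment_epochs",
    "remove_artifact_epochs",
    "zscore_recording",
    "preprocess",
    "spectral_vectors",
    "average_spectrum",
    "stage_average_spectra",
]

#: AASM stage vocabulary, shallow to deep (REM conventionally between W and N1).
STAGES = ("W", "REM", "N1", "N2", "N3")


@dataclass
class Recording:
    """A single-channel voltage trace at a fixed sampling rate."""

    signal: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    channel: str = "F4"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class EpochedRecording:
    """K epochs of T samples each, with optional stage labels and artifact flags.

    ``epoch_indices`` tracks each row's position in the original segmentation so
    that depth series stay alignable with the hypnogram after artifact removal.
    """

    epochs: np.ndarray
    sampling_rate: float
    epoch_seconds: float = 30.0
    labels: np.ndarray | None = None
    artifact_flags: np.ndarray | None = None
    epoch_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    recording_mean: float | None = None
    recording_sd: float | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.epochs = np.atleast_2d(np.asarray(self.epochs, dtype=float))
        K = self.epochs.shape[0]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != K:
                raise ValueError(f"{len(self.labels)} labels for {K} epochs")
        if self.artifact_flags is not None:
            self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
            if len(self.artifact_flags) != K:
                raise ValueError(f"{len(self.artifact_flags)} flags for {K} epochs")
        if self.epoch_indices is None:
            self.epoch_indices = np.arange(K)
        else:
            self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def samples_per_epoch(self) -> int:
        return self.epochs.shape[1]


@dataclass
class SpectralVectors:
    """Per-epoch gamma-scaled Fourier modulus vectors on a fixed bin grid."""

    values: np.ndarray  # K x F, all >= 0
    gamma: float
    freq_resolution: float  # Hz per bin (1/epoch_seconds)
    bin_indices: np.ndarray  # 1..F (DC excluded)
    epoch_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.bin_indices = np.asarray(self.bin_indices, dtype=int)
        if self.epoch_indices is None:
            self.epoch_indices = np.arange(self.values.shape[0])
        else:
            self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Bin centre frequencies in Hz."""
        return self.bin_indices * self.freq_resolution


def segment_epochs(
    rec: Recording,
    epoch_seconds: float = 30.0,
    labels: Sequence | None = None,
    artifact_flags: Sequence | None = None,
) -> EpochedRecording:
    """Cut a recording into consecutive fixed-length epochs.

    A trailing partial epoch is dropped (logged).  At 256 Hz a 30-s epoch has
    7680 samples; at 128 Hz, 3840.
    """
    T = int(round(epoch_seconds * rec.sampling_rate))
    n = len(rec.signal)
    if n < T:
        raise ValueError(f"signal has {n} samples, shorter than one epoch ({T})")
    K = n // T
    if n % T:
        logger.info("dropping trailing partial epoch (%d samples)", n % T)
    epochs = rec.signal[: K * T].reshape(K, T)
    lab = None if labels is None else np.asarray(labels)[:K]
    flags = None if artifact_flags is None else np.asarray(artifact_flags)[:K]
    return EpochedRecording(
        epochs,
        sampling_rate=rec.sampling_rate,
        epoch_seconds=epoch_seconds,
        labels=lab,
        artifact_flags=flags,
        subject_id=rec.subject_id,
    )


def remove_artifact_epochs(er: EpochedRecording) -> EpochedRecording:
    """Drop artifact-flagged epochs, preserving order and original indices."""
    if er.artifact_flags is None:
        return er
    keep = ~er.artifact_flags
    if not keep.any():
        raise ValueError("all epochs are artifact-flagged")
    return EpochedRecording(
        er.epochs[keep],
        sampling_rate=er.sampling_rate,
        epoch_seconds=er.epoch_seconds,
        labels=None if er.labels is None else er.labels[keep],
        artifact_flags=np.zeros(int(keep.sum()), dtype=bool),
        epoch_indices=er.epoch_indices[keep],
        recording_mean=er.recording_mean,
        recording_sd=er.recording_sd,
        subject_id=er.subject_id,
    )


def zscore_recording(er: EpochedRecording) -> EpochedRecording:
    """Z-score with the pooled mean/sd over ALL retained samples of the recording.

    This suppresses amplitude differences between subjects and devices while
    retaining the relative stage-to-stage variation within the night.  Must run
    after artifact removal so the statistics are not contaminated.
    """
    mu = float(er.epochs.mean())
    sd = float(er.epochs.std())
    if sd == 0:
        raise ValueError("constant recording: pooled standard deviation is zero")
    return EpochedRecording(
        (er.epochs - mu) / sd,
        sampling_rate=er.sampling_rate,
        epoch_seconds=er.epoch_seconds,
        labels=er.labels,
        artifact_flags=er.artifact_flags,
        epoch_indices=er.epoch_indices,
        recording_mean=mu,
        recording_sd=sd,
        subject_id=er.subject_id,
    )


def preprocess(
    rec: Recording,
    labels: Sequence | None = None,
    artifact_flags: Sequence | None = None,
    epoch_seconds: float = 30.0,
) -> EpochedRecording:
    """Segment, drop artifact epochs, and z-score with the pooled statistics."""
    er = segment_epochs(
        rec, epoch_seconds=epoch_seconds, labels=labels, artifact_flags=artifact_flags
    )
    return zscore_recording(remove_artifact_epochs(er))


def spectral_vectors(
    er: EpochedRecording, gamma: float = 0.5, f_max: float = 35.0
) -> SpectralVectors:
    """Gamma-scaled Fourier modulus of each epoch, DC excluded, cut at f_max.

    Retains bins 1..F with ``F = floor(f_max * epoch_seconds)``; bin ``f`` maps
    to frequency ``f / epoch_seconds`` Hz.  No taper and no per-epoch
    detrending are applied: the input is expected to be recording-z-scored.

    ``gamma`` < 0.5 is allowed but warned against, as very small exponents can
    be detrimental downstream.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if gamma < 0.5:
        warnings.warn(
            f"gamma={gamma} < 0.5 can be detrimental to downstream clustering",
            UserWarning,
            stacklevel=2,
        )
    nyquist = er.sampling_rate / 2.0
    if f_max >= nyquist:
        raise ValueError(f"f_max={f_max} Hz must be below Nyquist ({nyquist} Hz)")
    F = int(np.floor(f_max * er.epoch_seconds))
    spectrum = np.abs(np.fft.rfft(er.epochs, axis=1))  # unnormalized convention
    values = spectrum[:, 1 : F + 1] ** gamma
    return SpectralVectors(
        values,
        gamma=gamma,
        freq_resolution=1.0 / er.epoch_seconds,
        bin_indices=np.arange(1, F + 1),
        epoch_indices=er.epoch_indices,
    )


def average_spectrum(
    sv: SpectralVectors, subset: Sequence[int] | None = None
) -> np.ndarray:
    """Per-bin arithmetic mean spectrum over all (or a subset of) epochs."""
    if subset is None:
        return sv.values.mean(axis=0)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty epoch subset")
    return sv.values[subset].mean(axis=0)


def stage_average_spectra(
    sv: SpectralVectors, labels: Sequence
) -> Mapping[str, np.ndarray]:
    """Mean spectral vector per sleep stage (absent stages are omitted)."""
    labels = np.asarray(labels)
    if len(labels) != sv.n_epochs:
        raise ValueError(f"{len(labels)} labels for {sv.n_epochs} epochs")
    out = {}
    for stage in STAGES:
        rows = np.flatnonzero(labels == stage)
        if rows.size:
            out[stage] = sv.values[rows].mean(axis=0)
    return out
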