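"""Cross-device harmonization and post-hoc synchronization of depth series.

Two EEG devices recording the same subject produce systematically different
average spectra.  Harmonization computes a frequency-dependent filter function
A(f) — the per-bin ratio of the reference device's epoch-averaged spectrum to
the target's — and multiplies each of the target's epoch spectral vectors by
it; afterwards the two epoch-averaged spectra agree exactly.  A single PCA
fitted to the reference spectra then yields comparable C1 depth series from
both devices, and an unknown start-time offset between the machines is
recovered as the integer epoch shift maximizing |Pearson| between the two
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .depth import DepthSeries, SpectralPCAModel, fit_spectral_pca, project
from .spectra import (
    Recording,
    SpectralVectors,
    average_spectrum,
    preprocess,
    spectral_vectors,
)

__all__ = [
    "FilterFunction",
    "AlignmentResult",
    "CrossDeviceResult",
    "filter_function",
    "apply_filter",
    "cross_device_depth",
    "align_depth_series",
]


@dataclass
class FilterFunction:
    """Per-bin spectral ratio reference/target; strictly positive."""

    values: np.ndarray
    reference_id: str = ""
    target_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("filter values must be finite and positive")


@dataclass
class AlignmentResult:
    """Best integer epoch shift and the full |Pearson|-vs-shift curve."""

    best_shift: int
    correlation_curve: np.ndarray
    shift_range: np.ndarray

    @property
    def peak_correlation(self) -> float:
        return float(self.correlation_curve[self.shift_range == self.best_shift][0])


@dataclass
class CrossDeviceResult:
    """Depth series from both devices plus the artifacts used to obtain them."""

    depth_ref: DepthSeries
    depth_target: DepthSeries
    filter: FilterFunction
    model: SpectralPCAModel


def filter_function(
    ref_avg: np.ndarray,
    target_avg: np.ndarray,
    reference_id: str = "",
    target_id: str = "",
) -> FilterFunction:
    """A(f): per-bin ratio of reference to target epoch-averaged spectra.

    Zero or negative target bins are an error (naming the offending bins)
    rather than being epsilon-patched, which would silently corrupt A(f).
    """
    ref_avg = np.asarray(ref_avg, dtype=float).ravel()
    target_avg = np.asarray(target_avg, dtype=float).ravel()
    if ref_avg.shape != target_avg.shape:
        raise ValueError("bin grids of the two average spectra do not match")
    bad = np.flatnonzero(target_avg <= 0)
    if bad.size:
        raise ValueError(
            f"target average spectrum not strictly positive at bin(s) "
            f"{bad[:10].tolist()}"
        )
    return FilterFunction(ref_avg / target_avg, reference_id, target_id)


def apply_filter(sv: SpectralVectors, filt: FilterFunction) -> SpectralVectors:
    """Multiply every epoch's spectral vector elementwise by the filter."""
    if len(filt.values) != sv.n_bins:
        raise ValueError(
            f"filter has {len(filt.values)} bins, spectra have {sv.n_bins}"
        )
    return SpectralVectors(
        sv.values * filt.values,
        gamma=sv.gamma,
        freq_resolution=sv.freq_resolution,
        bin_indices=sv.bin_indices,
        epoch_indices=sv.epoch_indices,
    )


def cross_device_depth(
    rec_ref: Recording,
    rec_target: Recording,
    gamma: float = 0.5,
    f_max: float = 35.0,
    n_components: int = 3,
) -> CrossDeviceResult:
    """Comparable C1 depth series from two devices recording the same subject.

    The target's spectra are harmonized to the reference via the filter
    function; one PCA is fitted on the reference spectra only and both devices
    are projected through it.  Sampling rates must already match (resampling
    is the caller's responsibility).
    """
    if rec_ref.sampling_rate != rec_target.sampling_rate:
        raise ValueError(
            f"sampling rates differ: {rec_ref.sampling_rate} vs "
            f"{rec_target.sampling_rate} Hz"
        )
    er_ref = preprocess(rec_ref)
    er_target = preprocess(rec_target)
    sv_ref = spectral_vectors(er_ref, gamma=gamma, f_max=f_max)
    sv_target = spectral_vectors(er_target, gamma=gamma, f_max=f_max)
    filt = filter_function(
        average_spectrum(sv_ref),
        average_spectrum(sv_target),
        reference_id=rec_ref.subject_id,
        target_id=rec_target.subject_id,
    )
    sv_target = apply_filter(sv_target, filt)
    model = fit_spectral_pca(sv_ref, n_components=n_components)
    ds_ref = DepthSeries(
        project(model, sv_ref)[:, 1], epoch_indices=er_ref.epoch_indices
    )
    ds_target = DepthSeries(
        project(model, sv_target)[:, 1], epoch_indices=er_target.epoch_indices
    )
    return CrossDeviceResult(ds_ref, ds_target, filt, model)


def align_depth_series(
    a: DepthSeries | np.ndarray,
    b: DepthSeries | np.ndarray,
    max_shift: int = 120,
) -> AlignmentResult:
    """Find the integer epoch shift of ``b`` relative to ``a`` by |Pearson|.

    A positive ``best_shift`` s means ``b`` lags ``a`` by s epochs, i.e.
    ``b[k + s]`` shows the same sleep as ``a[k]``.  Each candidate shift is
    scored on the overlapping segment only; shifts whose overlap is constant
    give NaN.  Ties are broken by smallest |shift|, then negative before
    positive.
    """
    xa = a.values if isinstance(a, DepthSeries) else np.asarray(a, dtype=float)
    xb = b.values if isinstance(b, DepthSeries) else np.asarray(b, dtype=float)
    shifts = np.arange(-max_shift, max_shift + 1)
    curve = np.full(len(shifts), np.nan)
    for idx, s in enumerate(shifts):
        lo = max(0, -s)
        hi = min(len(xa), len(xb) - s)
        if hi - lo < 3:
            raise ValueError(
                f"overlap of {max(hi - lo, 0)} epochs at shift {s}; need >= 3"
            )
        seg_a, seg_b = xa[lo:hi], xb[lo + s : hi + s]
        if np.ptp(seg_a) == 0 or np.ptp(seg_b) == 0:
            continue
        curve[idx] = abs(stats.pearsonr(seg_a, seg_b)[0])
    if np.all(np.isnan(curve)):
        raise ValueError("correlation undefined at every shift (constant series)")
    peak = np.nanmax(curve)
    # tie-break: smallest |shift|, then negative before positive
    order = sorted(range(len(shifts)), key=lambda i: (abs(shifts[i]), shifts[i] > 0))
    best = next(i for i in order if curve[i] == peak)
    return AlignmentResult(int(shifts[best]), curve, shifts)
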