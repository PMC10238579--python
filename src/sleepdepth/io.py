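"""File formats: EDF recordings, hypnogram CSV, model and spectra persistence.

EDF (European Data Format) reading goes through MNE.  Writing uses a minimal
built-in EDF writer (16-bit samples, one data record per second) sufficient for
single-channel synthetic fixtures; signals are stored in microvolt units with
symmetric physical scaling.

Hypnograms travel as CSV with header ``epoch_index,stage,artifact`` (stage in
{W, REM, N1, N2, N3}, artifact in {0, 1}).  PCA models and spectral vectors are
persisted as small plain-text files with a key-value header.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .depth import Hypnogram, SpectralPCAModel, STAGE_NUMERIC
from .gdv import LabeledPointSet
from .spectra import Recording, SpectralVectors

__all__ = [
    "read_recording",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram",
    "save_model",
    "load_model",
    "save_spectral_vectors",
    "load_spectral_vectors",
    "write_depth_csv",
    "read_points_table",
]


# --------------------------------------------------------------------------- EDF


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: Recording, channel: str | None = None) -> None:
    """Write a single-channel recording as a minimal EDF file.

    Uses 1-s data records, so the sampling rate must be a positive integer.
    Samples are interpreted as microvolts and quantized to 16 bits over a
    symmetric physical range.
    """
    sr = rec.sampling_rate
    if sr != int(sr) or sr <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    sr = int(sr)
    n_records = len(rec.signal) // sr
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s data record")
    signal = np.asarray(rec.signal[: n_records * sr], dtype=float)
    import math

    raw_max = float(np.max(np.abs(signal))) or 1.0
    # round UP to few significant digits so +/- both fit the 8-char fields
    phys_max = None
    for precision in (6, 5, 4, 3, 2, 1):
        scale = 10.0 ** (math.floor(math.log10(raw_max)) - precision + 1)
        candidate = math.ceil(raw_max / scale) * scale
        if len(f"{-candidate:g}") <= 8 and len(f"{candidate:g}") <= 8:
            phys_max = candidate
            break
    if phys_max is None:
        raise ValueError(f"cannot represent physical range {raw_max} in EDF header")
    digital = np.round(signal / phys_max * 32767).astype("<i2")
    label = channel or rec.channel or "EEG"

    header = _io.BytesIO()
    header.write(_edf_field(0, 8))  # version
    header.write(_edf_field(rec.subject_id or "X", 80))  # patient id
    header.write(_edf_field("synthetic sleep EEG", 80))  # recording id
    header.write(_edf_field("01.01.01", 8))
    header.write(_edf_field("00.00.00", 8))
    header.write(_edf_field(256 + 256, 8))  # header bytes: fixed + 1 signal
    header.write(_edf_field("", 44))
    header.write(_edf_field(n_records, 8))
    header.write(_edf_field(1, 8))  # record duration, seconds
    header.write(_edf_field(1, 4))  # number of signals
    header.write(_edf_field(label, 16))
    header.write(_edf_field("", 80))  # transducer
    header.write(_edf_field("uV", 8))
    header.write(_edf_field(f"{-phys_max:g}", 8))
    header.write(_edf_field(f"{phys_max:g}", 8))
    header.write(_edf_field(-32768, 8))
    header.write(_edf_field(32767, 8))
    header.write(_edf_field("", 80))  # prefiltering
    header.write(_edf_field(sr, 8))  # samples per record
    header.write(_edf_field("", 32))

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        fh.write(digital.tobytes())


def read_recording(path, channel: str | None = None) -> Recording:
    """Read one channel of an EDF file into a Recording (no resampling).

    Samples are returned in microvolts.  A missing channel raises an error
    listing the channels present in the file.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        if len(raw.ch_names) != 1:
            raise ValueError(
                f"file has {len(raw.ch_names)} channels; specify one of "
                f"{raw.ch_names}"
            )
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in file; available: {raw.ch_names}"
        )
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return Recording(
        data,
        sampling_rate=float(raw.info["sfreq"]),
        subject_id=str(Path(path).stem),
        channel=channel,
    )


# -------------------------------------------------------------------- hypnogram


def write_hypnogram(path, hyp: Hypnogram, artifact_flags: Sequence | None = None) -> None:
    flags = (
        np.zeros(len(hyp), dtype=int)
        if artifact_flags is None
        else np.asarray(artifact_flags, dtype=int)
    )
    pd.DataFrame(
        {"epoch_index": np.arange(len(hyp)), "stage": hyp.stages, "artifact": flags}
    ).to_csv(path, index=False)


def read_hypnogram(path) -> tuple[Hypnogram, np.ndarray]:
    """Read a hypnogram CSV; returns (Hypnogram, artifact flags).

    Validates the stage vocabulary (reporting the offending row) and requires
    epoch indices to be exactly 0..K-1 with no duplicates or gaps.
    """
    df = pd.read_csv(path)
    required = {"epoch_index", "stage", "artifact"}
    if not required.issubset(df.columns):
        raise ValueError(f"hypnogram CSV must have columns {sorted(required)}")
    stages = df["stage"].astype(str).to_numpy()
    for row, s in enumerate(stages):
        if s not in STAGE_NUMERIC:
            raise ValueError(f"unknown stage token {s!r} at row {row}")
    idx = df["epoch_index"].to_numpy()
    if not np.array_equal(np.sort(idx), np.arange(len(df))):
        raise ValueError("epoch_index must be 0..K-1 without duplicates or gaps")
    order = np.argsort(idx)
    return Hypnogram(stages[order]), df["artifact"].to_numpy()[order].astype(bool)


# ------------------------------------------------------------ model persistence


def save_model(path, model: SpectralPCAModel) -> None:
    """Portable plain-text model file: key-value header, then numeric rows."""
    with open(path, "w") as fh:
        fh.write("# sleepdepth spectral PCA model\n")
        fh.write(f"gamma {model.gamma!r}\n")
        fh.write(f"freq_resolution {model.freq_resolution!r}\n")
        fh.write(f"f_start {int(model.bin_indices[0])}\n")
        fh.write(f"n_bins {model.n_bins}\n")
        fh.write(f"n_components {model.n_components}\n")
        fh.write(f"orientation_applied {int(model.orientation_applied)}\n")
        fh.write("explained_variance " + _row(model.explained_variance) + "\n")
        fh.write("mean_spectrum " + _row(model.mean_spectrum) + "\n")
        for row in model.eigenspectra:
            fh.write("eigenspectrum " + _row(row) + "\n")


def _row(values: np.ndarray) -> str:
    return " ".join(f"{v:.17g}" for v in np.asarray(values, float).ravel())


def load_model(path) -> SpectralPCAModel:
    meta: dict = {}
    eigenspectra = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            key, _, rest = line.partition(" ")
            if key == "eigenspectrum":
                eigenspectra.append(np.fromstring(rest, sep=" "))
            elif key in ("explained_variance", "mean_spectrum"):
                meta[key] = np.fromstring(rest, sep=" ")
            else:
                meta[key] = rest.strip()
    f_start = int(meta["f_start"])
    n_bins = int(meta["n_bins"])
    return SpectralPCAModel(
        mean_spectrum=meta["mean_spectrum"],
        eigenspectra=np.vstack(eigenspectra),
        explained_variance=meta["explained_variance"],
        gamma=float(meta["gamma"]),
        freq_resolution=float(meta["freq_resolution"]),
        bin_indices=np.arange(f_start, f_start + n_bins),
        orientation_applied=bool(int(meta["orientation_applied"])),
    )


# ------------------------------------------------------------- spectral vectors


def save_spectral_vectors(path, sv: SpectralVectors) -> None:
    """Delimited-text container: header comments, then epoch_index + bins."""
    header = (
        f"gamma {sv.gamma!r}\n"
        f"freq_resolution {sv.freq_resolution!r}\n"
        f"f_start {int(sv.bin_indices[0])}\n"
        f"n_bins {sv.n_bins}"
    )
    data = np.column_stack([sv.epoch_indices, sv.values])
    np.savetxt(path, data, header=header, fmt="%.10g")


def load_spectral_vectors(path) -> SpectralVectors:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    f_start = int(meta["f_start"])
    n_bins = int(meta["n_bins"])
    return SpectralVectors(
        data[:, 1:],
        gamma=float(meta["gamma"]),
        freq_resolution=float(meta["freq_resolution"]),
        bin_indices=np.arange(f_start, f_start + n_bins),
        epoch_indices=data[:, 0].astype(int),
    )


# ------------------------------------------------------------------ small CSVs


def write_depth_csv(path, ds) -> None:
    pd.DataFrame({"epoch_index": ds.epoch_indices, "C1": ds.values}).to_csv(
        path, index=False
    )


def read_points_table(path) -> LabeledPointSet:
    """Labeled numeric table: delimited text, header row, last column = label."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("points table needs at least one feature column + label")
    return LabeledPointSet(
        df.iloc[:, :-1].to_numpy(dtype=float), df.iloc[:, -1].to_numpy()
    )
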