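"""Synthetic polysomnography with the statistical structure the pipeline assumes.

Real overnight EEG with specialist-scored hypnograms is not publicly
deposited, so this module generates stand-in data carrying the features the
method exploits:

* a Markov-chain hypnogram over the AASM stages, starting in Wake;
* per-epoch colored-noise EEG whose band powers follow a stage-dependent
  profile on top of a 1/f background — deeper NREM stages have progressively
  more power below 3 Hz (delta range), while REM's profile sits near N1's and
  breaks the monotone ordering, as in real sleep;
* optionally a *gradual* delta-power ramp within constant-stage runs after a
  switch to a deeper stage, emulating the continuous descent of sleep depth
  that step-like hypnograms cannot express;
* per-epoch broadband gain jitter (vigilance/arousal-like amplitude
  fluctuations) that gives the spectral PCA a dominant amplitude component
  ahead of the delta-vs-fast contrast;
* a second "device" view of the same night: a smooth spectral gain curve and
  an integer epoch offset, for harmonization and lag-recovery experiments.

Everything is bit-reproducible under a fixed seed.  The generator makes no
attempt at physiological waveform detail (spindles, K-complexes, EOG/EMG).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .depth import STAGE_NUMERIC, Hypnogram
from .spectra import STAGES, Recording

__all__ = [
    "SynthConfig",
    "DEFAULT_TRANSITIONS",
    "DEFAULT_BAND_POWERS",
    "default_device_gain",
    "simulate_hypnogram",
    "simulate_recording",
    "simulate_cohort",
    "simulate_device_pair",
]

#: Frequency bands in Hz: delta, theta, alpha, sigma, beta.
BANDS = {
    "delta": (0.5, 3.0),
    "theta": (3.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 16.0),
    "beta": (16.0, 35.0),
}

#: Row-stochastic stage transition matrix, rows/columns in STAGES order
#: (W, REM, N1, N2, N3).  Dwell times are geometric with mean 1/(1-p_stay).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.90, 0.01, 0.08, 0.01, 0.00],  # W
        [0.05, 0.88, 0.05, 0.02, 0.00],  # REM
        [0.05, 0.02, 0.85, 0.08, 0.00],  # N1
        [0.02, 0.03, 0.04, 0.86, 0.05],  # N2
        [0.01, 0.01, 0.00, 0.08, 0.90],  # N3
    ]
)

#: Relative band power (delta, theta, alpha, sigma, beta) per stage.  Delta
#: rises monotonically over W < N1 < N2 < N3; REM sits near N1 and does not
#: follow the ordering in the other bands.
DEFAULT_BAND_POWERS = {
    "W": (0.6, 0.8, 1.5, 0.5, 1.0),
    "REM": (1.3, 1.0, 0.7, 0.4, 0.7),
    "N1": (1.5, 1.2, 0.8, 0.5, 0.5),
    "N2": (3.0, 1.0, 0.6, 1.0, 0.4),
    "N3": (7.0, 0.8, 0.4, 0.5, 0.25),
}


def default_device_gain(freq_hz: np.ndarray) -> np.ndarray:
    """A smooth, positive, low-pass-like spectral gain for a second device."""
    f = np.asarray(freq_hz, dtype=float)
    return 0.4 + 1.2 * np.exp(-f / 18.0)


@dataclass
class SynthConfig:
    """Parameters of the synthetic night.

    ``epoch_gain_sd`` is the standard deviation of the per-epoch log-normal
    broadband gain; ``background_weight`` scales the 1/f floor relative to the
    band bumps.  ``descent_epochs`` sets how many epochs a full-range delta
    ramp takes when ``continuous_descent`` is on.
    """

    n_epochs: int = 960  # 8 h of 30-s epochs
    epoch_seconds: float = 30.0
    sampling_rate: float = 128.0
    stage_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    stage_band_powers: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BAND_POWERS.items()}
    )
    background_slope: float = 1.0
    background_weight: float = 0.3
    epoch_gain_sd: float = 0.4
    continuous_descent: bool = True
    descent_epochs: int = 20
    amplitude_scale: float = 1.0
    device_gain: Callable[[np.ndarray], np.ndarray] | None = None
    epoch_offset: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_transition_matrix = np.asarray(
            self.stage_transition_matrix, dtype=float
        )
        m = self.stage_transition_matrix
        if m.shape != (5, 5) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("stage_transition_matrix must be 5x5 row-stochastic")
        for stage in STAGES:
            powers = np.asarray(self.stage_band_powers[stage], dtype=float)
            if powers.shape != (5,) or np.any(powers <= 0):
                raise ValueError(f"band powers for {stage} must be 5 positive values")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")


def simulate_hypnogram(cfg: SynthConfig, n_epochs: int | None = None) -> Hypnogram:
    """Markov-chain stage sequence of length ``n_epochs``, starting in Wake."""
    n = cfg.n_epochs if n_epochs is None else n_epochs
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    cum = np.cumsum(cfg.stage_transition_matrix, axis=1)
    state = 0  # W
    states = np.empty(n, dtype=int)
    draws = rng.random(n)
    for k in range(n):
        states[k] = state
        state = int(np.searchsorted(cum[state], draws[k], side="right"))
    return Hypnogram(np.array(STAGES)[states])


def _delta_trajectory(cfg: SynthConfig, hyp: Hypnogram) -> np.ndarray:
    """Per-epoch delta-band power with optional gradual deepening.

    Switches to a shallower stage (lower delta target) jump immediately —
    awakenings are abrupt.  Switches to a deeper stage (higher delta target)
    start a linear climb toward the target, taking up to ``descent_epochs``
    steps for the full Wake-to-N3 range, so sleep depth descends gradually
    within constant-stage runs.
    """
    targets = np.array(
        [cfg.stage_band_powers[s][0] for s in hyp.stages], dtype=float
    )
    if not cfg.continuous_descent:
        return targets
    lo = min(v[0] for v in cfg.stage_band_powers.values())
    hi = max(v[0] for v in cfg.stage_band_powers.values())
    step = (hi - lo) / max(cfg.descent_epochs, 1)
    out = np.empty_like(targets)
    current = targets[0]
    for k, target in enumerate(targets):
        if target <= current:
            current = target  # shallower (or equal): immediate jump
        else:
            current = min(target, current + step)  # deeper: gradual climb
        out[k] = current
    return out


def _band_bumps(freq: np.ndarray) -> np.ndarray:
    """5 x F indicator matrix of the band definitions on a frequency grid."""
    bumps = np.zeros((len(BANDS), len(freq)))
    for i, (lo, hi) in enumerate(BANDS.values()):
        bumps[i] = ((freq >= lo) & (freq < hi)).astype(float)
    return bumps


def simulate_recording(cfg: SynthConfig, hyp: Hypnogram) -> Recording:
    """Colored-noise EEG whose per-epoch band powers follow the hypnogram.

    Each epoch is synthesized in the frequency domain: complex Gaussian
    Fourier coefficients with amplitude sqrt(power profile), where the profile
    is the stage's band-power table over a 1/f background, the delta band
    follows :func:`_delta_trajectory`, and the whole epoch is multiplied by a
    log-normal broadband gain.  Bit-identical under the same seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    T = int(round(cfg.epoch_seconds * cfg.sampling_rate))
    n_bins = T // 2 + 1
    freq = np.arange(n_bins) / cfg.epoch_seconds
    bumps = _band_bumps(freq)
    with np.errstate(divide="ignore"):
        background = cfg.background_weight * np.where(
            freq > 0, np.maximum(freq, 0.5) ** (-cfg.background_slope), 0.0
        )
    background[0] = 0.0  # no DC

    # Per-stage profile without the (time-varying) delta contribution.
    nondelta = {
        s: background + np.asarray(p[1:]) @ bumps[1:]
        for s, p in cfg.stage_band_powers.items()
    }
    delta_power = _delta_trajectory(cfg, hyp)
    gains = np.exp(rng.normal(0.0, cfg.epoch_gain_sd, size=len(hyp)))

    power = np.stack([nondelta[s] for s in hyp.stages])
    power += delta_power[:, None] * bumps[0]
    amp = gains[:, None] * np.sqrt(power)

    coeffs = amp * (
        rng.standard_normal((len(hyp), n_bins))
        + 1j * rng.standard_normal((len(hyp), n_bins))
    ) / np.sqrt(2.0)
    coeffs[:, 0] = 0.0
    if T % 2 == 0:
        coeffs[:, -1] = coeffs[:, -1].real
    signal = np.fft.irfft(coeffs, n=T, axis=1).ravel() * cfg.amplitude_scale
    return Recording(
        signal, sampling_rate=cfg.sampling_rate, subject_id=f"synth-{cfg.seed}"
    )


def simulate_cohort(
    n_subjects: int, cfg: SynthConfig | None = None, seed: int = 0
) -> list[tuple[Recording, Hypnogram]]:
    """Independent synthetic subjects with jittered generator parameters.

    Between-subject variability: each band power is multiplied by a log-normal
    factor (sd 0.2), the broadband amplitude by a uniform factor in [0.5, 2]
    — exactly the nuisance that the per-recording z-scoring is meant to
    suppress — and the epoch gain jitter by a uniform factor in [0.7, 1.4].
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if cfg is None:
        cfg = SynthConfig(seed=seed)
    meta_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    child_seeds = meta_rng.integers(0, 2**31 - 1, size=n_subjects)
    cohort = []
    for s in range(n_subjects):
        jitter = np.exp(meta_rng.normal(0.0, 0.2, size=(5, 5)))
        powers = {
            stage: tuple(np.asarray(cfg.stage_band_powers[stage]) * jitter[i])
            for i, stage in enumerate(STAGES)
        }
        sub_cfg = replace(
            cfg,
            stage_band_powers=powers,
            amplitude_scale=cfg.amplitude_scale * meta_rng.uniform(0.5, 2.0),
            epoch_gain_sd=cfg.epoch_gain_sd * meta_rng.uniform(0.7, 1.4),
            seed=int(child_seeds[s]),
        )
        hyp = simulate_hypnogram(sub_cfg)
        rec = simulate_recording(sub_cfg, hyp)
        rec.subject_id = f"synth-subject-{s:02d}"
        cohort.append((rec, hyp))
    return cohort


def simulate_device_pair(
    cfg: SynthConfig,
) -> tuple[Recording, Recording, Hypnogram, int]:
    """The same synthetic night seen by two devices.

    The reference device records ``cfg.n_epochs`` epochs.  The second device
    started ``cfg.epoch_offset`` epochs earlier, so its epoch ``k + offset``
    shows the reference's epoch ``k``, and its signal passes through the
    spectral gain curve ``cfg.device_gain``.  Returns (reference recording,
    second-device recording, hypnogram of the reference epochs, true offset).
    """
    if cfg.device_gain is None or cfg.epoch_offset is None:
        raise ValueError("device_gain and epoch_offset must be set")
    offset = int(cfg.epoch_offset)
    if offset < 0:
        raise ValueError("epoch_offset must be >= 0")
    T = int(round(cfg.epoch_seconds * cfg.sampling_rate))
    total = cfg.n_epochs + offset
    hyp_full = simulate_hypnogram(cfg, n_epochs=total)
    base = simulate_recording(cfg, hyp_full)

    ref_signal = base.signal[offset * T : total * T]
    target_raw = base.signal[: cfg.n_epochs * T]

    # Apply the device's spectral gain over the whole target signal.
    spectrum = np.fft.rfft(target_raw)
    freqs = np.fft.rfftfreq(len(target_raw), d=1.0 / cfg.sampling_rate)
    gain = np.asarray(cfg.device_gain(freqs), dtype=float)
    if np.any(gain <= 0) or not np.all(np.isfinite(gain)):
        raise ValueError("device_gain must be positive and finite")
    target_signal = np.fft.irfft(spectrum * gain, n=len(target_raw))

    ref = Recording(ref_signal, cfg.sampling_rate, subject_id="device-ref")
    target = Recording(target_signal, cfg.sampling_rate, subject_id="device-target")
    hyp_ref = Hypnogram(hyp_full.stages[offset:total])
    return ref, target, hyp_ref, offset
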