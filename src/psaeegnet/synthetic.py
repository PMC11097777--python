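"""Synthetic RSVP EEG with an oddball P300, for end-to-end testing.

The generator emulates the statistical structure the classifier assumes
rather than any particular dataset: stimuli arrive at 10 Hz, a small
fraction are targets, and each target adds a positive centro-parietal
deflection peaking ~300 ms after onset on top of coloured background
activity. The background is spatially-correlated 1/f ("pink") noise plus a
10 Hz alpha oscillation with random per-channel phase plus white sensor
noise. Target responses vary trial to trial: latency is jittered
(truncated normal) and amplitude scaled by a lognormal factor with mean 1.
Consecutive 1 s epochs overlap at 10 Hz stimulation, so responses superpose
linearly, exactly as in real RSVP; an independent-epoch mode spaces stimuli
one epoch apart for unit tests that need i.i.d. trials.

This is phenomenological, not biophysical: no dipole forward model, no
artifacts, and the default signal-to-noise level is a convention, chosen so
that learnability and null behaviour are both observable at test scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

from .preprocessing import (ContinuousRecording, EpochSet, FilterSpec,
                            bandpass, extract_epochs)


@dataclass
class NoiseConfig:
    """Background noise model (amplitudes in microvolts RMS)."""

    one_over_f_exponent: float = 1.0
    one_over_f_rms: float = 4.0
    alpha_amplitude: float = 2.0
    white_sd: float = 1.0


@dataclass
class SimConfig:
    """Generative parameters of one synthetic RSVP subject.

    Defaults follow the paradigm: 62 channels at 250 Hz, 10 Hz stimulation,
    rare targets (2%, inside the 1-4% oddball range), P300 peaking at
    300 ms with 5 microvolt nominal amplitude, 30 ms latency jitter and a
    60 ms Gaussian width. ``overlap=False`` spaces stimuli one epoch apart.
    """

    n_channels: int = 62
    sampling_rate: float = 250.0
    stimulus_rate: float = 10.0
    n_stimuli: int = 2000
    target_prob: float = 0.02
    p300_amplitude: float = 5.0
    p300_latency_ms: float = 300.0
    latency_jitter_sd_ms: float = 30.0
    p300_width_ms: float = 60.0
    amplitude_lognorm_sigma: float = 0.3
    topography: np.ndarray | None = None
    peak_channels: tuple[int, ...] = (28, 29, 30)   # 0-based rows, "centro-parietal"
    topography_decay: float = 6.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spatial_mixing: float = 0.3
    epoch_ms: tuple[float, float] = (0.0, 1000.0)
    overlap: bool = True
    seed: int = 0

    @property
    def epoch_samples(self) -> int:
        return int(round((self.epoch_ms[1] - self.epoch_ms[0]) / 1000.0
                         * self.sampling_rate))

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.stimulus_rate <= 0:
            raise ValueError("rates must be positive")
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be >= 0 (0 is the null model)")
        if not 0.0 <= self.target_prob <= 1.0:
            raise ValueError("target_prob must be a probability")
        if not 0.0 <= self.spatial_mixing < 1.0:
            raise ValueError("spatial_mixing must lie in [0, 1)")
        epoch_len_ms = self.epoch_ms[1] - self.epoch_ms[0]
        if self.p300_latency_ms + 3 * self.p300_width_ms > epoch_len_ms:
            raise ValueError("P300 template (latency + 3 widths) leaks outside "
                             "the epoch window")

    def resolved_topography(self) -> np.ndarray:
        """Per-channel gain in [0, 1], peaking (gain 1) on peak_channels."""
        if self.topography is not None:
            topo = np.asarray(self.topography, dtype=float)
            if topo.shape != (self.n_channels,):
                raise ValueError("topography must have one gain per channel")
            if topo.max() <= 0:
                raise ValueError("topography must have a positive peak")
            return topo / topo.max()
        ch = np.arange(self.n_channels)
        dist = np.min(np.abs(ch[:, None] - np.asarray(self.peak_channels)[None, :]),
                      axis=1)
        return np.exp(-dist / self.topography_decay)


def p300_template(config: SimConfig) -> np.ndarray:
    """Unit-peak Gaussian deflection over one epoch (epoch_samples long)."""
    config.validate()
    fs = config.sampling_rate
    t_ms = (np.arange(config.epoch_samples) / fs) * 1000.0 + config.epoch_ms[0]
    w = max(config.p300_width_ms, 1e-9)
    return np.exp(-0.5 * ((t_ms - config.p300_latency_ms) / w) ** 2)


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                exponent: float, fs: float) -> np.ndarray:
    """Rows of unit-RMS 1/f^exponent noise, shaped in the frequency domain."""
    white = rng.standard_normal((n_rows, n_samples))
    spec = sp_fft.rfft(white, axis=-1)
    freqs = sp_fft.rfftfreq(n_samples, 1.0 / fs)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = sp_fft.irfft(spec * scale, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _truncated_normal_scalar(rng, sd: float, clip: float = 3.0) -> float:
    while True:
        z = rng.standard_normal()
        if abs(z) <= clip:
            return z * sd


def simulate_recording(config: SimConfig | None = None) -> ContinuousRecording:
    """Generate one continuous multichannel recording with stimulus events."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    epoch_len = config.epoch_samples
    isi = epoch_len if not config.overlap else int(round(fs / config.stimulus_rate))
    warm = int(fs)
    n_samples = warm + config.n_stimuli * isi + epoch_len + int(fs)

    # background: spatially mixed pink noise + alpha + white sensor noise
    nz = config.noise
    pink = _pink_noise(rng, config.n_channels + 1, n_samples,
                       nz.one_over_f_exponent, fs)
    shared = pink[-1]
    m = config.spatial_mixing
    data = nz.one_over_f_rms * (np.sqrt(1 - m) * pink[:-1]
                                + np.sqrt(m) * shared[None, :])
    t = np.arange(n_samples) / fs
    phases = rng.uniform(0, 2 * np.pi, config.n_channels)
    data += nz.alpha_amplitude * np.sin(
        2 * np.pi * 10.0 * t[None, :] + phases[:, None])
    data += nz.white_sd * rng.standard_normal((config.n_channels, n_samples))

    # stimulus stream and target responses
    event_samples = warm + isi * np.arange(config.n_stimuli)
    labels = (rng.random(config.n_stimuli) < config.target_prob).astype(int)
    topo = config.resolved_topography()
    sigma = config.amplitude_lognorm_sigma
    w_samp = config.p300_width_ms / 1000.0 * fs
    support = int(np.ceil(4 * w_samp))
    for s, lab in zip(event_samples, labels):
        if not lab or config.p300_amplitude == 0:
            continue
        jitter_ms = _truncated_normal_scalar(rng, config.latency_jitter_sd_ms)
        amp = config.p300_amplitude * rng.lognormal(-0.5 * sigma ** 2, sigma)
        centre = s + (config.p300_latency_ms + jitter_ms) / 1000.0 * fs
        lo = max(int(np.floor(centre - support)), 0)
        hi = min(int(np.ceil(centre + support)) + 1, n_samples)
        bump = np.exp(-0.5 * ((np.arange(lo, hi) - centre) / w_samp) ** 2)
        data[:, lo:hi] += amp * topo[:, None] * bump[None, :]

    events = [(int(s), int(l)) for s, l in zip(event_samples, labels)]
    return ContinuousRecording(data.astype(np.float32), fs, events)


def simulate_subject(config: SimConfig | None = None,
                     filter_spec: FilterSpec | None = None) -> EpochSet:
    """Recording -> bandpass (2-30 Hz zero phase) -> 0-1000 ms epochs."""
    config = config or SimConfig()
    rec = simulate_recording(config)
    rec = bandpass(rec, filter_spec or FilterSpec())
    return extract_epochs(rec, config.epoch_ms)
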