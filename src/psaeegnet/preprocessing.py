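"""Continuous-recording preprocessing: channel selection, bandpass, epoching.

The pipeline mirrors standard RSVP/P300 practice: select the analysis
montage from the raw channel set, bandpass the continuous signal with a
zero-phase Butterworth filter (2-30 Hz by default, so the filter is applied
before epoching and edge transients never touch the epochs), then cut
fixed-length single-trial epochs around each stimulus event. Amplitudes are
microvolts throughout. Channel indices are 1-based at the interface
(matching electrode numbering conventions) and converted internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: default montage: 62 of 64 electrodes (channels 33 and 43 dropped), 1-based
DEFAULT_KEEP_CHANNELS: tuple[int, ...] = tuple(
    i for i in range(1, 65) if i not in (33, 43))

#: analysis epoch relative to stimulus onset, milliseconds
DEFAULT_WINDOW_MS: tuple[float, float] = (0.0, 1000.0)


@dataclass
class ContinuousRecording:
    """Multichannel recording with stimulus events.

    data: (channels, samples) array in microvolts.
    events: ordered (sample_index, label) pairs; label 1 = target, 0 = nontarget.
    channel_ids: 1-based identifiers of the rows of ``data``.
    """

    data: np.ndarray
    sampling_rate: float
    events: list[tuple[int, int]] = field(default_factory=list)
    channel_ids: tuple[int, ...] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = tuple(range(1, self.data.shape[0] + 1))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match channel count")
        samples = [s for s, _ in self.events]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("event sample indices must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class FilterSpec:
    """Butterworth bandpass specification (zero-phase by default)."""

    low_hz: float = 2.0
    high_hz: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= nyq:
            raise ValueError(
                f"upper passband edge {self.high_hz} Hz must be below the "
                f"Nyquist frequency {nyq} Hz")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class EpochSet:
    """Labelled single-trial epochs: (trials, channels, samples), microvolts."""

    epochs: np.ndarray
    labels: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials, channels, samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.labels.size and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (nontarget) or 1 (target)")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, idx) -> "EpochSet":
        return EpochSet(self.epochs[idx], self.labels[idx], self.sampling_rate)


def select_channels(recording: ContinuousRecording,
                    keep: tuple[int, ...] = DEFAULT_KEEP_CHANNELS) -> ContinuousRecording:
    """Keep the given 1-based channel ids, in the given order."""
    id_to_row = {cid: i for i, cid in enumerate(recording.channel_ids)}
    rows = []
    for cid in keep:
        if cid not in id_to_row:
            raise IndexError(f"channel {cid} not present in recording")
        rows.append(id_to_row[cid])
    return ContinuousRecording(recording.data[rows], recording.sampling_rate,
                               list(recording.events), tuple(keep))


def bandpass(recording: ContinuousRecording,
             spec: FilterSpec = FilterSpec()) -> ContinuousRecording:
    """Butterworth bandpass, each channel independently.

    zero_phase applies the filter forward and backward (sosfiltfilt), which
    doubles the effective order and removes group delay so ERP latencies
    are preserved.
    """
    spec.validate(recording.sampling_rate)
    sos = signal.butter(spec.order, (spec.low_hz, spec.high_hz),
                        btype="bandpass", fs=recording.sampling_rate,
                        output="sos")
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, recording.data, axis=-1)
    else:
        out = signal.sosfilt(sos, recording.data, axis=-1)
    return ContinuousRecording(out.astype(recording.data.dtype, copy=False),
                               recording.sampling_rate, list(recording.events),
                               recording.channel_ids)


def extract_epochs(recording: ContinuousRecording,
                   window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
                   baseline_ms: tuple[float, float] | None = None) -> EpochSet:
    """Cut one epoch per event over the half-open window [start, end) ms.

    At 250 Hz the default 0-1000 ms window yields exactly 250 samples.
    Overlapping windows are allowed (RSVP stimuli arrive faster than the
    epoch length). Optional baseline correction subtracts the per-channel
    mean of ``baseline_ms`` from each epoch; off by default.
    """
    start_ms, end_ms = window_ms
    if start_ms < 0:
        raise ValueError("window start must be >= 0 ms relative to the event")
    fs = recording.sampling_rate
    off = int(round(start_ms / 1000.0 * fs))
    n = int(round((end_ms - start_ms) / 1000.0 * fs))
    if n <= 0:
        raise ValueError("window must have positive length")
    epochs = np.empty((len(recording.events), recording.n_channels, n),
                      dtype=recording.data.dtype)
    labels = np.empty(len(recording.events), dtype=np.int8)
    for i, (sample, label) in enumerate(recording.events):
        a = sample + off
        if a < 0 or a + n > recording.n_samples:
            raise ValueError(
                f"epoch window [{a}, {a + n}) for event {i} at sample {sample} "
                f"exceeds recording bounds (0, {recording.n_samples})")
        epochs[i] = recording.data[:, a:a + n]
        labels[i] = 1 if int(label) else 0
    out = EpochSet(epochs, labels, fs)
    if baseline_ms is not None and len(out):
        b0 = int(round(baseline_ms[0] / 1000.0 * fs)) - off
        b1 = int(round(baseline_ms[1] / 1000.0 * fs)) - off
        if not (0 <= b0 < b1 <= n):
            raise ValueError("baseline window must lie inside the epoch window")
        out.epochs = out.epochs - out.epochs[:, :, b0:b1].mean(axis=2, keepdims=True)
    return out


def bandpass_epochs(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Filter already-cut epochs. Prefer filtering the continuous recording:
    short epochs give edge artifacts, hence the warning."""
    warnings.warn("filtering cut epochs introduces edge artifacts; filter the "
                  "continuous recording before epoching where possible",
                  stacklevel=2)
    rec = ContinuousRecording(
        epochs.epochs.reshape(-1, epochs.n_samples), epochs.sampling_rate)
    filt = bandpass(rec, spec)
    return EpochSet(filt.data.reshape(epochs.epochs.shape), epochs.labels,
                    epochs.sampling_rate)
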