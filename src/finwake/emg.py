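"""EMG conditioning, spike detection and burst grouping.

Conditioning is a zero-phase (forward-backward) 10th-order Butterworth
bandpass mirroring the analog recording chain (100 Hz low cutoff, 3000 Hz
high cutoff) with the upper edge clamped below Nyquist for the configured
digital rate.  Zero-phase filtering matters here: burst onsets feed 0.2 s
association windows downstream and must not be delayed by filter group delay.

The published spike rule — keep signals that are at least 25% of the mean
spike amplitude of the electrode — is circular (the spikes define the mean
that defines the spikes).  It is resolved with a two-pass construction:
pass 1 collects candidate peaks above a robust (MAD-based) noise floor,
whose mean absolute amplitude defines the electrode's mean spike amplitude;
pass 2 keeps candidates at or above ``rel_threshold`` (default 0.25) times
that mean.  Both knobs are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EmgRecording

NYQUIST_MARGIN = 0.45  # upper band edge clamp, as a fraction of the sampling rate


@dataclass
class SpikeTrain:
    channel: str
    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.amplitudes = np.asarray(self.amplitudes, float)

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class EmgBurst:
    """One grouped episode of muscle activity."""

    channel: str
    onset: float
    offset: float
    n_spikes: int
    mean_spike_amplitude: float

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("burst requires onset < offset")
        if self.n_spikes < 1:
            raise ValueError("burst requires n_spikes >= 1")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def bandpass_filter(
    rec: EmgRecording,
    order: int = 10,
    band: tuple[float, float] = (100.0, 3000.0),
) -> EmgRecording:
    """Zero-phase Butterworth bandpass of the stated order on every channel.

    The upper edge is clamped to ``NYQUIST_MARGIN * rate`` with a warning when
    the request exceeds it; a band that is infeasible after clamping raises.
    Output length is preserved (filtfilt padding).
    """
    if order < 2 or order % 2 != 0:
        raise ValueError("order must be an even integer >= 2")
    low, high = band
    limit = NYQUIST_MARGIN * rec.rate
    if high > limit:
        warnings.warn(
            f"bandpass high edge {high} Hz clamped to {limit:.1f} Hz "
            f"(0.45 x sampling rate {rec.rate} Hz)",
            stacklevel=2,
        )
        high = limit
    if not 0 < low < high:
        raise ValueError(f"infeasible band ({low}, {high}) Hz after clamping")
    sos = signal.butter(order // 2, [low, high], btype="bandpass",
                        fs=rec.rate, output="sos")
    out = {name: signal.sosfiltfilt(sos, sig) for name, sig in rec.channels.items()}
    return EmgRecording(times=rec.times.copy(), channels=out, rate=rec.rate)


def detect_spikes(
    rec: EmgRecording,
    channel: str,
    rel_threshold: float = 0.25,
    noise_k: float = 5.0,
    refractory: float = 0.002,
) -> SpikeTrain:
    """Two-pass spike detection on a filtered channel.

    Pass 1: candidate peaks of the rectified signal exceeding ``noise_k``
    times the MAD-based noise s.d., separated by at least ``refractory``
    seconds.  Pass 2: keep candidates whose amplitude is at least
    ``rel_threshold`` times the mean candidate amplitude.  A flat channel or
    one with no candidates returns an empty train (not an error).  Spike
    times are scale-invariant: scaling the channel by any positive constant
    scales floor, amplitudes and mean together.
    """
    x = rec.channel(channel)
    med = np.median(x)
    sigma = np.median(np.abs(x - med)) / 0.6745
    floor = noise_k * sigma
    if not np.isfinite(floor):
        return SpikeTrain(channel, np.empty(0), np.empty(0))
    distance = max(1, int(round(refractory * rec.rate)))
    peaks, props = signal.find_peaks(np.abs(x), height=max(floor, 0.0),
                                     distance=distance)
    if peaks.size == 0:
        return SpikeTrain(channel, np.empty(0), np.empty(0))
    amps = props["peak_heights"]
    mean_amp = float(np.mean(amps))
    keep = amps >= rel_threshold * mean_amp
    return SpikeTrain(channel, rec.times[peaks[keep]], amps[keep])


def group_bursts(
    spikes: SpikeTrain,
    max_gap: float = 0.05,
    refractory: float = 0.002,
) -> list[EmgBurst]:
    """Group spikes into bursts: consecutive inter-spike intervals <= max_gap.

    Burst onset/offset are the first/last spike times; a singleton spike
    forms a one-sample burst with offset = onset + one refractory period.
    """
    t = spikes.times
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    bursts: list[EmgBurst] = []
    i = 0
    n = t.size
    while i < n:
        j = i
        while j + 1 < n and (t[j + 1] - t[j]) <= max_gap:
            j += 1
        amps = spikes.amplitudes[i: j + 1]
        onset = float(t[i])
        offset = float(t[j]) if j > i else onset + refractory
        bursts.append(
            EmgBurst(
                channel=spikes.channel,
                onset=onset,
                offset=offset,
                n_spikes=j - i + 1,
                mean_spike_amplitude=float(np.mean(amps)) if amps.size else float("nan"),
            )
        )
        i = j + 1
    return bursts


def detect_bursts(
    rec: EmgRecording,
    channels=None,
    rel_threshold: float = 0.25,
    noise_k: float = 5.0,
    refractory: float = 0.002,
    max_gap: float = 0.05,
) -> list[EmgBurst]:
    """Spike detection + burst grouping over several channels of a filtered
    recording, returned as one flat list sorted by onset."""
    if channels is None:
        channels = list(rec.channels)
    out: list[EmgBurst] = []
    for ch in channels:
        train = detect_spikes(rec, ch, rel_threshold=rel_threshold,
                              noise_k=noise_k, refractory=refractory)
        out.extend(group_bursts(train, max_gap=max_gap, refractory=refractory))
    out.sort(key=lambda b: (b.onset, b.channel))
    return out
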