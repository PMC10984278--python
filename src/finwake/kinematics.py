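"""Kinematic series: smoothing, the fin-extension metric, COM velocity and
body-wave summary metrics.

The smoothing filter is a centred moving average whose window is a fraction
(default 20%) of the frame rate, applied before any derivative is taken.  At
the series edges the window shrinks to the available samples, which preserves
length at the cost of a conservative estimate of extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .io import PoseTrack


@dataclass
class Series:
    """A uniformly sampled scalar signal with a units tag."""

    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.max(np.abs(dt - dt[0])) > 1e-9 + 1e-6 * abs(dt[0]):
                raise ValueError("series must be uniformly sampled")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        if self.n < 2:
            raise ValueError("need >= 2 samples to define dt")
        return float(self.times[1] - self.times[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt


@dataclass
class BodyWaveMetrics:
    """Summary of the whole-body lateral oscillation over a bout.

    lateral_displacement and wavelength are in body lengths (L);
    tailbeat_frequency in Hz; net_drift in cm (positive downstream).
    ``wavelength`` is inf for rigid-body sway (zero phase slope) and NaN when
    no oscillation is detected.
    """

    lateral_displacement: float
    wavelength: float
    tailbeat_frequency: float
    net_drift: float
    has_transient_highfreq_tailbeats: bool
    oscillation_detected: bool
    rigid_body: bool = False
    traveling_wave: bool = False
    phase_slope: float = float("nan")
    phase_slope_se: float = float("nan")


def smooth_array(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges.

    The nominal window of ``window`` samples spans indices
    [i - (window-1)//2, i + window//2] and is clipped to the series; the
    output at i is the mean of the available (non-NaN) samples in that span,
    or NaN when the whole span is missing.  Output length equals input length.
    """
    values = np.asarray(values, float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n < window:
        raise ValueError(f"series of length {n} shorter than window {window}")
    half_lo = (window - 1) // 2
    half_hi = window // 2
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(valid.astype(np.int64))))
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi + 1, n)
    counts = ccnt[hi] - ccnt[lo]
    sums = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def smooth_series(series: Series, frame_rate: float | None = None,
                  window_fraction: float = 0.2) -> Series:
    """Moving-average smooth a Series; window = round(window_fraction * rate).

    With the 150 frames/s camera and the default fraction this is a 30-frame
    window.
    """
    rate = frame_rate if frame_rate is not None else series.rate
    window = max(1, int(round(window_fraction * rate)))
    return Series(series.times, smooth_array(series.values, window), series.units)


def fin_extension_distance(track: PoseTrack, side: str, L: float) -> Series:
    """Fin extension: perpendicular distance from the fin tip (point 3) to the
    infinite line through the fin-base points (1 and 5), in body lengths.

    Non-negative by construction.  Frames where the base points are closer
    than 1e-6 cm (degenerate base) or where any of the three points is
    untracked are NaN.
    """
    side = side.lower()
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    prefix = "Lfin" if side == "left" else "Rfin"
    p1 = track.xy(f"{prefix}_1")
    p3 = track.xy(f"{prefix}_3")
    p5 = track.xy(f"{prefix}_5")
    base = p5 - p1
    blen = np.hypot(base[:, 0], base[:, 1])
    rel = p3 - p1
    cross = base[:, 0] * rel[:, 1] - base[:, 1] * rel[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.abs(cross) / blen
    dist = np.where(blen < 1e-6, np.nan, dist)
    return Series(track.times, dist / L, units="L")


def com_velocity(track: PoseTrack, frame_rate: float | None = None,
                 window_fraction: float = 0.2) -> tuple[Series, Series]:
    """Forward (x) and lateral (y) COM velocity in cm/s.

    The COM is proxied by the third midline point.  Its position is smoothed
    first, then differentiated (central differences in the interior,
    one-sided at the endpoints).  Positive forward velocity is downstream;
    upstream motion toward the cylinder is negative.
    """
    if track.n_frames < 3:
        raise ValueError("need at least 3 frames for a velocity estimate")
    rate = frame_rate if frame_rate is not None else track.frame_rate
    window = max(1, int(round(window_fraction * rate)))
    xy = track.xy("midline_3")
    xs = smooth_array(xy[:, 0], window)
    ys = smooth_array(xy[:, 1], window)
    dt = 1.0 / rate
    forward = np.gradient(xs, dt)
    lateral = np.gradient(ys, dt)
    t = track.times
    return (Series(t, forward, "cm/s"), Series(t, lateral, "cm/s"))


def _dominant_frequency(values: np.ndarray, fs: float, f_min: float = 0.5,
                        peak_factor: float = 20.0) -> tuple[float, float, bool]:
    """Dominant spectral peak of a detrended signal.

    Returns (frequency, peak power, detected).  Detection requires the peak
    to exceed ``peak_factor`` times the median spectral power above f_min —
    a flat (noise-only or constant) spectrum has no admissible peak.
    """
    x = values - np.nanmean(values)
    x = np.where(np.isfinite(x), x, 0.0)
    if np.std(x) < 1e-9:  # numerically constant signal: nothing oscillates
        return float("nan"), 0.0, False
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(max(8 * n, 1024))))
    freqs, power = signal.periodogram(x, fs=fs, nfft=nfft)
    band = freqs >= f_min
    if not band.any() or not np.any(power[band] > 0):
        return float("nan"), 0.0, False
    fb, pb = freqs[band], power[band]
    k = int(np.argmax(pb))
    med = np.median(pb)
    detected = pb[k] > peak_factor * med and pb[k] > 0
    return float(fb[k]), float(pb[k]), bool(detected)


def body_wave_metrics(
    track: PoseTrack,
    L: float,
    shedding_frequency: float | None = None,
    rigid_wavelength_L: float = 20.0,
    highfreq_fraction: float = 0.1,
    highfreq_ratio: float = 1.5,
) -> BodyWaveMetrics:
    """Body-wave summary from the seven midline points.

    tailbeat_frequency: dominant spectral peak of the tail-tip lateral signal.
    lateral_displacement: peak-to-peak tail-tip lateral excursion / L (after
    removing a linear trend).  wavelength: 2*pi * (mean arclength spacing) /
    (per-point phase slope at the dominant frequency), in L, assuming the
    seven midline points are evenly spaced along the body (spacing L/6).
    net_drift: x displacement of midline point 3 over the bout (cm).
    has_transient_highfreq_tailbeats: more than ``highfreq_fraction`` of the
    bout shows tail energy above ``highfreq_ratio`` times the reference
    frequency (shedding frequency when given, else the dominant tail-beat
    frequency) exceeding the dominant-band energy.

    Rigid-body sway (all points in phase) yields an effectively zero phase
    slope: wavelength is reported as +inf with ``rigid_body`` set, which
    trivially exceeds any wavelength threshold.
    """
    if track.n_frames < 2:
        raise ValueError("need at least 2 frames")
    fs = track.frame_rate
    duration = track.n_frames / fs
    if duration < 1.0:
        raise ValueError("need at least 1 s of data for body-wave metrics")
    t = track.times
    tail = track.xy("midline_7")[:, 1]
    # remove linear trend so slow lateral drift does not inflate the excursion
    ok = np.isfinite(tail)
    if ok.sum() >= 2:
        coeffs = np.polyfit(t[ok], tail[ok], 1)
        tail_d = tail - np.polyval(coeffs, t)
    else:
        tail_d = tail
    pkpk = float(np.nanmax(tail_d) - np.nanmin(tail_d)) if ok.any() else float("nan")

    com_x = track.xy("midline_3")[:, 0]
    finite_x = com_x[np.isfinite(com_x)]
    net_drift = float(finite_x[-1] - finite_x[0]) if finite_x.size >= 2 else float("nan")

    f_dom, _, detected = _dominant_frequency(tail_d, fs)

    wavelength = float("nan")
    rigid = False
    traveling = False
    slope = float("nan")
    slope_se = float("nan")
    if detected:
        # complex amplitude of each midline point at the dominant frequency
        phases = []
        carrier = np.exp(-2j * np.pi * f_dom * t)
        for i in range(1, 8):
            y = track.xy(f"midline_{i}")[:, 1]
            y = y - np.nanmean(y)
            y = np.where(np.isfinite(y), y, 0.0)
            phases.append(np.angle(np.sum(y * carrier)))
        phi = np.unwrap(np.array(phases))
        idx = np.arange(7, dtype=float)
        reg = stats.linregress(idx, phi)
        slope = float(reg.slope)  # rad per point
        slope_se = float(reg.stderr)
        spacing = L / 6.0  # mean arclength spacing of the 7 midline points
        rigid_slope = 2 * np.pi * spacing / (rigid_wavelength_L * L)
        if abs(slope) < rigid_slope:
            rigid = True
            wavelength = float("inf")
        else:
            wavelength = float(2 * np.pi * spacing / abs(slope) / L)
        traveling = (not rigid) and np.isfinite(slope_se) and abs(slope) > 2 * slope_se

    has_highfreq = False
    f_ref = shedding_frequency if shedding_frequency is not None else f_dom
    if detected and np.isfinite(f_ref) and f_ref > 0:
        nper = min(track.n_frames, max(16, int(round(0.5 * fs))))
        freqs, _, spec = signal.spectrogram(
            np.where(np.isfinite(tail_d), tail_d, 0.0), fs=fs,
            nperseg=nper, noverlap=nper // 2,
        )
        cut = highfreq_ratio * f_ref
        hi = freqs > cut
        lo = (freqs >= 0.5) & (freqs <= cut)
        if hi.any() and lo.any() and spec.shape[1] > 0:
            e_hi = spec[hi].sum(axis=0)
            e_lo = spec[lo].sum(axis=0)
            frac = float(np.mean(e_hi > e_lo))
            has_highfreq = frac > highfreq_fraction

    return BodyWaveMetrics(
        lateral_displacement=pkpk / L,
        wavelength=wavelength,
        tailbeat_frequency=f_dom,
        net_drift=net_drift,
        has_transient_highfreq_tailbeats=has_highfreq,
        oscillation_detected=detected,
        rigid_body=rigid,
        traveling_wave=traveling,
        phase_slope=slope,
        phase_slope_se=slope_se,
    )
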