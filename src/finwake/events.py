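"""Fin-extension events, left-right synchronicity, behaviour-bout
classification and event localisation relative to the cylinder.

An extension event is a maximal run of frames whose (smoothed) fin-extension
value is at or above the threshold, default 0.05 L.  Runs separated by gaps
shorter than ``merge_gap`` frames are merged first, then runs shorter than
``min_duration`` frames are discarded — both suppress single-frame tracking
jitter at 150 frames/s.  Intervals are half-open [onset, offset): the offset
is the time of the first sample after the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PoseTrack
from .kinematics import BodyWaveMetrics, Series

SUCTION_X = (0.0, 15.0)   # cm downstream of cylinder
SUCTION_Y = 3.0           # cm lateral half-width
WAKE_X = (15.0, 30.0)     # cm downstream


@dataclass
class ExtensionEvent:
    """One fin-extension episode."""

    side: str
    onset: float
    offset: float
    t_max: float
    peak_extension: float
    onset_frame: int
    offset_frame: int  # exclusive
    t_max_frame: int
    position_at_max: tuple[float, float] | None = None
    zone: str | None = None

    def __post_init__(self):
        if not self.onset <= self.t_max < self.offset:
            raise ValueError("require onset <= t_max < offset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class BehaviorBout:
    """A classified stretch of swimming: karman_gait, braking or other."""

    label: str
    start: float
    end: float
    criteria_flags: dict[str, bool]

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("require start < end")


@dataclass
class SynchronicityResult:
    """Greedy left/right pairing plus per-event labels."""

    pairs: list[tuple[int, int, float]]  # (left index, right index, overlap s)
    left_labels: list[str]
    right_labels: list[str]


def _runs(mask: np.ndarray) -> list[list[int]]:
    """[start, stop) index pairs of True runs."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append([i, j])
            i = j
        else:
            i += 1
    return out


def detect_extension_events(
    extension: Series,
    side: str = "left",
    threshold: float = 0.05,
    min_duration: int = 3,
    merge_gap: int = 2,
) -> list[ExtensionEvent]:
    """Threshold the extension series into ExtensionEvents.

    A frame belongs to an event when its value is >= ``threshold`` (L units);
    NaN (untracked) frames never do.  Runs separated by gaps of fewer than
    ``merge_gap`` frames are merged, then runs shorter than ``min_duration``
    frames are discarded.  t_max is the argmax within the run (earliest
    sample on ties).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = extension.values
    n = len(values)
    if n == 0:
        return []
    dt = extension.dt if n > 1 else 0.0
    above = np.zeros(n, bool)
    finite = np.isfinite(values)
    above[finite] = values[finite] >= threshold

    runs = _runs(above)
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    kept = [r for r in merged if (r[1] - r[0]) >= min_duration]

    events = []
    for start, stop in kept:
        seg = values[start:stop]
        imax = start + int(np.nanargmax(seg))
        offset = extension.times[stop] if stop < n else extension.times[-1] + dt
        events.append(
            ExtensionEvent(
                side=side,
                onset=float(extension.times[start]),
                offset=float(offset),
                t_max=float(extension.times[imax]),
                peak_extension=float(values[imax]),
                onset_frame=start,
                offset_frame=stop,
                t_max_frame=imax,
            )
        )
    return events


def _check_sorted_disjoint(events: list[ExtensionEvent], side: str) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset < a.onset:
            raise ValueError(f"{side} events must be sorted by onset")
        if b.onset < a.offset:
            raise ValueError(f"overlapping events within the {side} list")


def label_synchronicity(
    left_events: list[ExtensionEvent],
    right_events: list[ExtensionEvent],
    overlap_fraction: float = 0.5,
) -> SynchronicityResult:
    """Pair left and right events and label each synchronous/asynchronous.

    A left/right pair is synchronous when their overlap duration is at least
    ``overlap_fraction`` times the duration of the *shorter* event (the
    strictest symmetric reading of "50% overlap").  Pairing is greedy by
    largest overlap, each event in at most one pair; unpaired events are
    asynchronous.
    """
    _check_sorted_disjoint(left_events, "left")
    _check_sorted_disjoint(right_events, "right")
    candidates = []
    for i, le in enumerate(left_events):
        for j, re in enumerate(right_events):
            ov = min(le.offset, re.offset) - max(le.onset, re.onset)
            if ov <= 0:
                continue
            shorter = min(le.duration, re.duration)
            if ov >= overlap_fraction * shorter:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_l: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for ov, i, j in candidates:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        pairs.append((i, j, float(ov)))
    left_labels = ["synchronous" if i in used_l else "asynchronous"
                   for i in range(len(left_events))]
    right_labels = ["synchronous" if j in used_r else "asynchronous"
                    for j in range(len(right_events))]
    return SynchronicityResult(pairs=pairs, left_labels=left_labels,
                               right_labels=right_labels)


def classify_bout(
    metrics: BodyWaveMetrics,
    forward_velocity: Series,
    L: float,
    drift_tol: float = 0.1,
    v_tol: float = 1.0,
    rise_window: float = 0.5,
    min_bout: float = 1.0,
) -> BehaviorBout:
    """Classify a bout as Kármán gaiting, braking or other.

    Kármán-gait flags: (1) station holding, |net drift| <= drift_tol (in L)
    over the bout; (2) a travelling wave along the body (phase slope
    significantly nonzero); (3) tail lateral peak-to-peak displacement
    > 0.5 L; (4) body wavelength > 1 L; (5) no transient small-amplitude
    high-frequency tail beats.  Braking flags: (1) net upstream drift;
    (2) an upstream surge immediately arrested — forward velocity below
    -v_tol followed within ``rise_window`` s by a value above +v_tol;
    (3) no sustained periodic tail oscillation; (4) no whole-body
    undulation (tail displacement <= 0.5 L).  All five / all four flags must
    hold for the respective label; everything else is "other".
    """
    t = forward_velocity.times
    if len(t) < 2 or (t[-1] - t[0]) < min_bout:
        raise ValueError(f"bout shorter than {min_bout} s")

    drift_L = metrics.net_drift / L
    kg = {
        "kg_station_holding": bool(abs(drift_L) <= drift_tol),
        "kg_traveling_wave": bool(metrics.traveling_wave),
        "kg_lateral_displacement": bool(metrics.lateral_displacement > 0.5),
        "kg_long_wavelength": bool(np.isfinite(metrics.wavelength) and metrics.wavelength > 1.0
                                   or metrics.wavelength == float("inf")),
        "kg_no_highfreq_tailbeats": bool(not metrics.has_transient_highfreq_tailbeats),
    }

    v = forward_velocity.values
    win = max(1, int(round(rise_window * forward_velocity.rate)))
    excursion = False
    below = np.where(np.isfinite(v) & (v < -v_tol))[0]
    for i in below:
        seg = v[i + 1: i + 1 + win]
        seg = seg[np.isfinite(seg)]
        if seg.size and np.max(seg) > v_tol:
            excursion = True
            break
    br = {
        "br_upstream_drift": bool(drift_L < -drift_tol),
        "br_accel_decel": bool(excursion),
        "br_no_sustained_oscillation": bool(not metrics.oscillation_detected),
        "br_no_undulation": bool(metrics.lateral_displacement <= 0.5),
    }

    if all(kg.values()):
        label = "karman_gait"
    elif all(br.values()):
        label = "braking"
    else:
        label = "other"
    return BehaviorBout(label=label, start=float(t[0]), end=float(t[-1]),
                        criteria_flags={**kg, **br})


def event_position(
    event: ExtensionEvent,
    track: PoseTrack,
    landmark: str = "midline_1",
    suction_x: tuple[float, float] = SUCTION_X,
    suction_y: float = SUCTION_Y,
    wake_x: tuple[float, float] = WAKE_X,
) -> tuple[float, float, str]:
    """Landmark (default: snout) position at the time of maximal extension,
    relative to the cylinder, plus a zone label.

    suction_zone: x in (0, 15] cm downstream and |y| <= 3 cm laterally — the
    low-pressure region right behind the cylinder where braking occurs;
    wake: x in (15, 30] cm, where Kármán gaiting concentrates; everything
    else (including upstream of the cylinder) is outside.  Bounds are
    configurable.
    """
    frame = event.t_max_frame
    if not 0 <= frame < track.n_frames:
        raise ValueError("event t_max outside the track")
    x, y = track.xy(landmark)[frame]
    if suction_x[0] < x <= suction_x[1] and abs(y) <= suction_y:
        zone = "suction_zone"
    elif wake_x[0] < x <= wake_x[1]:
        zone = "wake"
    else:
        zone = "outside"
    return float(x), float(y), zone
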