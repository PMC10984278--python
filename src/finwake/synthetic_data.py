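"""Synthetic trials with planted ground truth.

The generator emulates the statistical structure the analysis assumes, for a
trout (L ~ 21.7 cm) holding station behind a 5 cm D-section cylinder at flow
speeds of 45-85 cm/s:

* Kármán gaiting — midline point i at arclength s_i oscillates laterally as
  A(s_i) * sin(2*pi*f*t - 2*pi*s_i/lambda) about a drifting COM, with a
  linear head-to-tail amplitude envelope (0.02 L -> 0.28 L, so the tail
  peak-to-peak excursion is 0.56 L), wavelength 1.2 L and f at the vortex
  shedding frequency St*U/D.
* Braking — an upstream surge arrested at the moment of maximal fin
  extension: the forward COM velocity ramps linearly from an upstream plateau
  to a downstream plateau across the flip, with the plateaus solved so that
  the 0.2 s pre/post window means equal the requested values exactly.
* Fin-extension events — fin point 3 moves perpendicular to the base line so
  the extension metric follows a piecewise ramp: a linear segment spanning
  the smoothing window is centred on each threshold crossing (the moving
  average is exact on interior linear segments, so planted onsets/offsets
  survive the 20%-of-frame-rate smoothing), with a triangular peak at the
  event midpoint.  Planted peaks must exceed twice the detection threshold
  for this construction.
* EMG bursts — trains of 2 ms biphasic spikes at the stated rate and
  amplitude added to Gaussian baseline noise.

Noise is independent Gaussian per coordinate per frame (pose) and per sample
(EMG).  All randomness derives from one seed via deterministic sub-streams
(pose noise, EMG noise, spike jitter), so identical configs give bit-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .io import BODYPARTS, EMG_CHANNELS, EmgRecording, PoseTrack, TrialMeta
from .kinematics import Series

import pandas as pd

DEFAULT_STROUHAL = 0.25  # D-section cylinder; gives 2.25-4.25 Hz over 45-85 cm/s
DETECTION_THRESHOLD_L = 0.05
FIN_BASE_LENGTH_L = 0.08
FIN_WALL_OFFSET_L = 0.05


def shedding_frequency(U: float, D: float, strouhal: float = DEFAULT_STROUHAL) -> float:
    """Vortex shedding frequency f = St * U / D (Hz; U in cm/s, D in cm)."""
    if U <= 0 or D <= 0:
        raise ValueError("U and D must be positive")
    return strouhal * U / D


@dataclass(frozen=True)
class PlantedEvent:
    side: str
    onset: float
    offset: float
    peak: float  # L units

    @property
    def t_max(self) -> float:
        return 0.5 * (self.onset + self.offset)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class PlantedBurst:
    channel: str
    onset: float
    offset: float
    amplitude: float = 10.0
    rate: float = 100.0  # spikes/s


@dataclass
class SynthConfig:
    """Full description of one synthetic trial (see module docstring)."""

    meta: TrialMeta
    behavior: str = "karman_gait"  # karman_gait | braking | still
    duration: float = 4.0
    head_amplitude_L: float = 0.02
    tail_amplitude_L: float = 0.28
    body_wavelength_L: float = 1.2
    shedding_freq: float | None = None  # Hz; None -> St * U / D
    strouhal: float = DEFAULT_STROUHAL
    com_drift: tuple[float, float] = (0.0, 0.0)  # cm/s (x, y)
    start_head_x: float | None = None  # cm downstream; None -> behaviour default
    # braking velocity profile (cm/s); plateaus are solved from pre/post
    braking_pre_velocity: float = -4.0
    braking_post_velocity: float = 3.0
    braking_flip_time: float = 1.7
    braking_ramp_halfwidth: float = 0.2
    braking_surge_start: float = 0.4
    braking_surge_ramp: float = 0.3
    braking_recovery_hold: float = 0.4
    braking_recovery_ramp: float = 0.3
    velocity_window: float = 0.2
    extension_ramp_halfwidth: float = 0.1  # s; half the smoothing window
    detection_threshold_L: float = DETECTION_THRESHOLD_L
    planted_events: tuple[PlantedEvent, ...] = ()
    planted_bursts: tuple[PlantedBurst, ...] = ()
    pose_noise_sd: float = 0.05  # cm
    emg_noise_sd: float = 0.5   # amplifier units
    seed: int = 0

    def __post_init__(self):
        if self.behavior not in ("karman_gait", "braking", "still"):
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.planted_events = tuple(self.planted_events)
        self.planted_bursts = tuple(self.planted_bursts)
        r = self.extension_ramp_halfwidth
        per_side: dict[str, list[PlantedEvent]] = {"left": [], "right": []}
        for ev in self.planted_events:
            if ev.side not in ("left", "right"):
                raise ValueError(f"event side must be left/right, got {ev.side!r}")
            if not ev.onset < ev.offset:
                raise ValueError("event onset must precede offset")
            if not 0 < ev.peak <= 0.3:
                raise ValueError("peak extension must lie in (0, 0.3] L")
            if ev.peak <= 2 * self.detection_threshold_L:
                raise ValueError(
                    "planted peak must exceed twice the detection threshold "
                    "for the exact-crossing ramp profile")
            if ev.onset - r < 0 or ev.offset + r > self.duration:
                raise ValueError("event (including ramp aprons) outside [0, duration)")
            if ev.duration <= 2 * r:
                raise ValueError("event shorter than twice the ramp halfwidth")
            per_side[ev.side].append(ev)
        for side, evs in per_side.items():
            evs.sort(key=lambda e: e.onset)
            for a, b in zip(evs, evs[1:]):
                if b.onset - r < a.offset + r:
                    raise ValueError(f"overlapping planted events on the {side} fin")
        by_ch: dict[str, list[PlantedBurst]] = {}
        for b in self.planted_bursts:
            if b.channel not in EMG_CHANNELS:
                raise ValueError(f"unknown EMG channel {b.channel!r}")
            if not 0 <= b.onset < b.offset <= self.duration:
                raise ValueError("burst outside [0, duration)")
            if b.amplitude <= 0 or b.rate <= 0:
                raise ValueError("burst amplitude and rate must be positive")
            by_ch.setdefault(b.channel, []).append(b)
        for ch, bs in by_ch.items():
            bs.sort(key=lambda b: b.onset)
            for a, b in zip(bs, bs[1:]):
                if b.onset < a.offset:
                    raise ValueError(f"overlapping planted bursts on {ch}")

    @property
    def frequency(self) -> float:
        if self.shedding_freq is not None:
            return self.shedding_freq
        return shedding_frequency(self.meta.flow_speed_U,
                                  self.meta.cylinder_diameter_D, self.strouhal)

    def to_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k not in ("meta", "planted_events", "planted_bursts")}
        d["com_drift"] = list(self.com_drift)
        d["shedding_freq"] = self.frequency
        d["start_head_x"] = self._head_x0()
        return {
            "meta": self.meta.to_dict(),
            "trial": d,
            "planted_events": {
                f"event_{i}": dataclasses.asdict(ev)
                for i, ev in enumerate(self.planted_events)
            },
            "planted_bursts": {
                f"burst_{i}": dataclasses.asdict(b)
                for i, b in enumerate(self.planted_bursts)
            },
        }

    def _head_x0(self) -> float:
        if self.start_head_x is not None:
            return self.start_head_x
        return 13.0 if self.behavior == "braking" else 17.5


@dataclass
class VelocityWindowTruth:
    """True pre/post window means around one planted event's t_max."""

    side: str
    t_max: float
    pre_forward: float
    post_forward: float
    pre_lateral: float
    post_lateral: float


@dataclass
class GroundTruth:
    behavior: str
    events: tuple[PlantedEvent, ...]
    bursts: tuple[PlantedBurst, ...]
    forward_velocity: Series
    lateral_velocity: Series
    velocity_windows: list[VelocityWindowTruth]
    shedding_freq: float
    config: SynthConfig


def _braking_velocity_nodes(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear forward-velocity profile for a braking trial.

    Plateaus v1/v2 are solved so the true means over the 0.2 s windows
    on either side of the flip equal the requested pre/post velocities:
    with a linear ramp spanning [flip-h, flip+h] and h equal to the window
    length, mean over [flip-w, flip) is (v1+v2)/2 - (v2-v1)/4.
    """
    pre, post = cfg.braking_pre_velocity, cfg.braking_post_velocity
    v1 = (3.0 * pre - post) / 2.0
    v2 = (3.0 * post - pre) / 2.0
    h = cfg.braking_ramp_halfwidth
    f = cfg.braking_flip_time
    nodes_t = [0.0, cfg.braking_surge_start,
               cfg.braking_surge_start + cfg.braking_surge_ramp,
               f - h, f + h,
               f + h + cfg.braking_recovery_hold,
               f + h + cfg.braking_recovery_hold + cfg.braking_recovery_ramp,
               cfg.duration]
    nodes_v = [0.0, 0.0, v1, v1, v2, v2, 0.0, 0.0]
    t = np.array(nodes_t)
    if np.any(np.diff(t) < 0) or t[-2] > cfg.duration:
        raise ValueError("braking velocity profile does not fit in the trial duration")
    return t, np.array(nodes_v)


def _extension_profile(t: np.ndarray, ev: PlantedEvent, thr: float, r: float) -> np.ndarray:
    """Planted extension time course: linear threshold crossings centred at
    onset/offset (segment halfwidth r), triangular peak at the midpoint."""
    e = np.zeros_like(t)
    rise = (t >= ev.onset - r) & (t < ev.onset + r)
    e[rise] = 2 * thr * (t[rise] - (ev.onset - r)) / (2 * r)
    fall = (t > ev.offset - r) & (t <= ev.offset + r)
    e[fall] = 2 * thr * ((ev.offset + r) - t[fall]) / (2 * r)
    inner = (t >= ev.onset + r) & (t <= ev.offset - r)
    half_inner = 0.5 * ev.duration - r
    mid = ev.t_max
    e[inner] = 2 * thr + (ev.peak - 2 * thr) * (1.0 - np.abs(t[inner] - mid) / half_inner)
    return e


def _window_mean(times: np.ndarray, values: np.ndarray, lo: float, hi: float,
                 closed: str) -> float:
    eps = 1e-9
    if closed == "left":   # [lo, hi)
        mask = (times >= lo - eps) & (times < hi - eps)
    else:                  # (lo, hi]
        mask = (times > lo + eps) & (times <= hi + eps)
    return float(np.mean(values[mask])) if mask.any() else float("nan")


def simulate_trial(config: SynthConfig) -> tuple[PoseTrack, EmgRecording, GroundTruth]:
    """Generate (PoseTrack, EmgRecording, GroundTruth) for one trial."""
    meta = config.meta
    L = meta.body_length_L
    fr = meta.frame_rate
    n = int(round(config.duration * fr))
    t = np.arange(n) / fr
    ss = np.random.SeedSequence(config.seed)
    rng_pose, rng_emg, rng_misc = (np.random.default_rng(s) for s in ss.spawn(3))

    f = config.frequency
    lam = config.body_wavelength_L * L
    s_arc = np.arange(7) * L / 6.0          # midline arclengths, snout -> tail
    s_com = s_arc[2]                        # midline point 3 proxies the COM

    # --- COM path and true velocities -------------------------------------
    drift_x, drift_y = config.com_drift
    head_x0 = config._head_x0()
    x0 = head_x0 + s_com
    if config.behavior == "braking":
        nodes_t, nodes_v = _braking_velocity_nodes(config)
        vx = np.interp(t, nodes_t, nodes_v)
        x_path = x0 + cumulative_trapezoid(vx, t, initial=0.0)
    else:
        vx = np.full(n, drift_x)
        x_path = x0 + drift_x * t
    y_path = drift_y * t
    vy_path = np.full(n, drift_y)

    # --- midline -----------------------------------------------------------
    phase0 = rng_misc.uniform(0.0, 2 * np.pi)
    xs = np.empty((n, 7))
    ys = np.empty((n, 7))
    if config.behavior == "karman_gait":
        amps = (config.head_amplitude_L
                + (config.tail_amplitude_L - config.head_amplitude_L) * s_arc / L) * L
    else:
        amps = np.zeros(7)
    for i in range(7):
        xs[:, i] = x_path + (s_arc[i] - s_com)
        ys[:, i] = y_path + amps[i] * np.sin(2 * np.pi * f * t
                                             - 2 * np.pi * s_arc[i] / lam + phase0)
    # true COM (midline point 3) lateral velocity, analytic
    vy = vy_path + amps[2] * 2 * np.pi * f * np.cos(
        2 * np.pi * f * t - 2 * np.pi * s_com / lam + phase0)

    # --- fins ---------------------------------------------------------------
    thr = config.detection_threshold_L
    r = config.extension_ramp_halfwidth
    ext = {"left": np.zeros(n), "right": np.zeros(n)}
    for ev in config.planted_events:
        ext[ev.side] += _extension_profile(t, ev, thr, r)

    tangent = np.stack([xs[:, 3] - xs[:, 1], ys[:, 3] - ys[:, 1]], axis=1)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal_right = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    root = np.stack([xs[:, 2], ys[:, 2]], axis=1)

    fin_points: dict[str, np.ndarray] = {}
    half_base = 0.5 * FIN_BASE_LENGTH_L * L
    for side, prefix in (("left", "Lfin"), ("right", "Rfin")):
        sgn = 1.0 if side == "right" else -1.0
        n_side = sgn * normal_right
        centre = root + FIN_WALL_OFFSET_L * L * n_side
        e = ext[side][:, None] * L * n_side
        fin_points[f"{prefix}_1"] = centre - half_base * tangent
        fin_points[f"{prefix}_5"] = centre + half_base * tangent
        fin_points[f"{prefix}_3"] = centre + e
        fin_points[f"{prefix}_2"] = centre - 0.25 * half_base * tangent + 0.7 * e
        fin_points[f"{prefix}_4"] = centre + 0.25 * half_base * tangent + 0.7 * e

    cols = {}
    for i in range(7):
        part = f"midline_{i + 1}"
        cols[(part, "x")] = xs[:, i]
        cols[(part, "y")] = ys[:, i]
        cols[(part, "likelihood")] = np.ones(n)
    for part, pts in fin_points.items():
        cols[(part, "x")] = pts[:, 0]
        cols[(part, "y")] = pts[:, 1]
        cols[(part, "likelihood")] = np.ones(n)
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    if config.pose_noise_sd > 0:
        for part in BODYPARTS:
            frame[(part, "x")] += rng_pose.normal(0, config.pose_noise_sd, n)
            frame[(part, "y")] += rng_pose.normal(0, config.pose_noise_sd, n)
    track = PoseTrack(frame, fr)

    # --- EMG ----------------------------------------------------------------
    m = int(round(config.duration * meta.emg_rate))
    te = np.arange(m) / meta.emg_rate
    channels = {ch: rng_emg.normal(0.0, config.emg_noise_sd, m) for ch in EMG_CHANNELS}
    w = max(2, int(round(0.002 * meta.emg_rate)))
    spike_wave = np.sin(2 * np.pi * np.arange(w) / w)  # one-period biphasic, 2 ms
    for burst in config.planted_bursts:
        isi = 1.0 / burst.rate
        k = 0
        while True:
            ts = burst.onset + k * isi
            if k > 0:
                ts += rng_misc.uniform(-1.0, 1.0) * 0.001
            if ts > burst.offset:
                break
            i0 = int(round(ts * meta.emg_rate))
            i1 = min(i0 + w, m)
            if i0 < m:
                channels[burst.channel][i0:i1] += burst.amplitude * spike_wave[: i1 - i0]
            k += 1
    rec = EmgRecording(times=te, channels=channels, rate=meta.emg_rate)

    # --- ground truth -------------------------------------------------------
    wdw = config.velocity_window
    windows = []
    for ev in config.planted_events:
        tm = ev.t_max
        windows.append(VelocityWindowTruth(
            side=ev.side,
            t_max=tm,
            pre_forward=_window_mean(t, vx, tm - wdw, tm, "left"),
            post_forward=_window_mean(t, vx, tm, tm + wdw, "right"),
            pre_lateral=_window_mean(t, vy, tm - wdw, tm, "left"),
            post_lateral=_window_mean(t, vy, tm, tm + wdw, "right"),
        ))
    truth = GroundTruth(
        behavior=config.behavior,
        events=config.planted_events,
        bursts=config.planted_bursts,
        forward_velocity=Series(t, vx, "cm/s"),
        lateral_velocity=Series(t, vy, "cm/s"),
        velocity_windows=windows,
        shedding_freq=f,
        config=config,
    )
    return track, rec, truth


# ---------------------------------------------------------------------------
# cohort-level sampling under the study conditions

#: published event counts set the synchrony rates the cohort sampler plants
KG_SYNC_PROB = 35.0 / 272.0        # Kármán gaiting: asynchronous ~87% of events
BRAKING_SYNC_PROB = 9.0 / 13.0     # braking: synchronous ~69% of events
#: activation-pattern mix for Kármán-gait extensions (over half proceed
#: without ipsilateral muscle activity)
KG_PATTERN_PROBS = {"passive": 0.5, "active": 0.35, "resistive": 0.15}

FLOW_SPEEDS = (45.0, 55.0, 65.0, 75.0, 85.0)  # cm/s, experimental range
BRAKING_FLOW_SPEEDS = (65.0, 75.0, 85.0)      # braking observed only at high speeds


def default_meta(seed: int = 0, flow_speed: float = 65.0) -> TrialMeta:
    return TrialMeta(body_length_L=21.7, flow_speed_U=flow_speed,
                     cylinder_diameter_D=5.0, frame_rate=150.0, emg_rate=4000.0,
                     fish_id="synthetic", trial_id=f"trial_{seed}")


def _kg_event_bursts(side: str, t_max: float, onset: float, pattern: str,
                     amplitude: float = 10.0) -> list[PlantedBurst]:
    pre = "L" if side == "left" else "R"
    if pattern == "active":
        return [
            PlantedBurst(f"{pre}_abductor", t_max - 0.15, t_max - 0.02, amplitude),
            PlantedBurst(f"{pre}_adductor", t_max + 0.02, t_max + 0.15, amplitude),
        ]
    if pattern == "resistive":
        return [PlantedBurst(f"{pre}_adductor", onset + 0.05, t_max - 0.02, amplitude)]
    return []  # passive: the vortex moves the fin, no muscle activity


def sample_trial_config(behavior: str, seed: int,
                        meta: TrialMeta | None = None) -> SynthConfig:
    """Randomised per-trial configuration under the study conditions.

    Kármán-gait trials plant two fin-extension events (synchronous with the
    published ~13% rate) with a passive/active/resistive EMG pattern mix;
    braking trials plant one sustained extension (synchronous with the
    published ~69% rate) with abductor recruitment at extension and adductor
    activity while the fin is held against the flow, co-occurring with the
    velocity flip.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF17)))
    if meta is None:
        speeds = BRAKING_FLOW_SPEEDS if behavior == "braking" else FLOW_SPEEDS
        meta = default_meta(seed, flow_speed=float(rng.choice(speeds)))

    if behavior == "still":
        return SynthConfig(meta=meta, behavior="still", duration=2.0, seed=seed)

    events: list[PlantedEvent] = []
    bursts: list[PlantedBurst] = []
    if behavior == "karman_gait":
        for centre in (1.0, 2.6):
            c = centre + rng.uniform(-0.15, 0.15)
            onset, offset = c - 0.3, c + 0.3
            side = str(rng.choice(["left", "right"]))
            sync = rng.random() < KG_SYNC_PROB
            pattern = str(rng.choice(list(KG_PATTERN_PROBS),
                                     p=list(KG_PATTERN_PROBS.values())))
            sides = ("left", "right") if sync else (side,)
            for s in sides:
                ev = PlantedEvent(s, onset, offset, peak=0.15)
                events.append(ev)
                bursts.extend(_kg_event_bursts(s, ev.t_max, onset, pattern))
        return SynthConfig(meta=meta, behavior="karman_gait", duration=4.0,
                           planted_events=tuple(events),
                           planted_bursts=tuple(bursts), seed=seed)

    if behavior == "braking":
        onset, offset = 1.2, 2.2
        sync = rng.random() < BRAKING_SYNC_PROB
        sides = ("left", "right") if sync else (str(rng.choice(["left", "right"])),)
        for s in sides:
            ev = PlantedEvent(s, onset, offset, peak=0.22)
            events.append(ev)
            pre = "L" if s == "left" else "R"
            # abductors extend the fin; adductors hold it out against the flow
            bursts.append(PlantedBurst(f"{pre}_abductor", onset - 0.1, onset + 0.25))
            bursts.append(PlantedBurst(f"{pre}_adductor", ev.t_max - 0.15, offset + 0.1))
        return SynthConfig(meta=meta, behavior="braking", duration=3.5,
                           braking_flip_time=0.5 * (onset + offset),
                           planted_events=tuple(events),
                           planted_bursts=tuple(bursts), seed=seed)

    raise ValueError(f"unknown behavior {behavior!r}")


def sample_velocity_change_pairs(
    n: int,
    pre_mean: float,
    post_mean: float,
    sd: float = 3.5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-level (pre, post) velocity window means for a planted cohort.

    Event-to-event scatter is Gaussian with s.d. ``sd`` (cm/s), consistent
    with the published standard errors (~0.3 cm/s at n ~ 10^2 events).  With
    pre_mean == post_mean this is the null cohort used to calibrate the
    pre/post test.
    """
    if rng is None:
        rng = np.random.default_rng()
    pre = pre_mean + rng.normal(0.0, sd, n)
    post = post_mean + rng.normal(0.0, sd, n)
    return pre, post
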