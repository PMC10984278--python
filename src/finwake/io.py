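"""Reading and writing pose tracks, EMG recordings, configs and result tables.

Coordinate convention
---------------------
The D-section cylinder centre is the origin (0, 0); x increases downstream,
y is lateral with positive toward the fish's right in the ventral view.
Forward (upstream) body motion therefore has negative x-velocity.  Frames are
0-based, the time of frame k is k / frame_rate, and all intervals are
half-open [onset, offset).

Pose files use the DeepLabCut CSV dialect: three header rows (scorer,
bodyparts, coords) followed by one row per frame with x, y, likelihood
triplets per bodypart, in pixels.  Reading converts to centimetres via an
affine transform ``cm = px * pixel_to_cm - cylinder_origin`` (origin given in
cm); writing applies the exact inverse, so a read/write round trip is lossless
to floating-point precision.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MIDLINE_PARTS = tuple(f"midline_{i}" for i in range(1, 8))
LFIN_PARTS = tuple(f"Lfin_{i}" for i in range(1, 6))
RFIN_PARTS = tuple(f"Rfin_{i}" for i in range(1, 6))
BODYPARTS = MIDLINE_PARTS + LFIN_PARTS + RFIN_PARTS

EMG_CHANNELS = ("L_abductor", "L_adductor", "R_abductor", "R_adductor")

#: column dictionaries for the tidy result tables written by write_results
EVENT_COLUMNS = (
    "fish_id", "trial_id", "side", "onset", "offset", "duration", "t_max",
    "peak_extension", "x_at_max", "y_at_max", "zone", "synchronicity",
)
BOUT_COLUMNS = (
    "fish_id", "trial_id", "label", "start", "end",
    "kg_station_holding", "kg_traveling_wave", "kg_lateral_displacement",
    "kg_long_wavelength", "kg_no_highfreq_tailbeats",
    "br_upstream_drift", "br_accel_decel", "br_no_sustained_oscillation",
    "br_no_undulation",
)
BURST_COLUMNS = (
    "fish_id", "trial_id", "channel", "onset", "offset", "duration",
    "n_spikes", "mean_spike_amplitude",
)
COUPLING_COLUMNS = (
    "fish_id", "trial_id", "side", "t_max", "behavior", "synchronicity",
    "pre_forward", "post_forward", "pre_lateral", "post_lateral",
    "onset_ipsi_abductor", "onset_ipsi_adductor",
    "onset_contra_abductor", "onset_contra_adductor",
    "offset_ipsi_abductor", "offset_ipsi_adductor",
    "offset_contra_abductor", "offset_contra_adductor",
    "abduction_pattern", "adduction_pattern",
    "co_contraction_abduction", "co_contraction_adduction",
    "burst_durations",
)


class FormatError(ValueError):
    """Raised when an input file violates the declared format contract."""


@dataclass(frozen=True)
class TrialMeta:
    """Per-trial metadata: geometry, rates and identifiers.

    Lengths are in cm, speeds in cm/s, rates in 1/s. ``cylinder_origin`` is
    the cylinder centre in the calibrated (cm) image coordinates; after the
    reader's affine transform the centre maps to (0, 0).
    """

    body_length_L: float
    flow_speed_U: float
    cylinder_diameter_D: float = 5.0
    frame_rate: float = 150.0
    emg_rate: float = 4000.0
    cylinder_origin: tuple[float, float] = (0.0, 0.0)
    fish_id: str = "fish"
    trial_id: str = "trial"

    def __post_init__(self):
        if self.body_length_L <= 0:
            raise ValueError("body_length_L must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.emg_rate <= 0:
            raise ValueError("emg_rate must be positive")
        if not 0.0 <= self.flow_speed_U <= 200.0:
            raise ValueError("flow_speed_U outside valid range [0, 200] cm/s")
        if self.cylinder_diameter_D <= 0:
            raise ValueError("cylinder_diameter_D must be positive")

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialMeta":
        d = dict(d)
        if "cylinder_origin" in d:
            d["cylinder_origin"] = tuple(float(v) for v in d["cylinder_origin"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cylinder_origin"] = list(self.cylinder_origin)
        return d


class PoseTrack:
    """Time-indexed labelled 2-D points with tracking likelihoods.

    ``data`` holds one row per frame and a two-level column index
    (bodypart, coord) with coord in {x, y, likelihood}; x and y are in cm in
    the cylinder-centred frame.  Missing values are explicit NaN, never
    dropped rows.
    """

    def __init__(self, data: pd.DataFrame, frame_rate: float):
        if frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if data.index.has_duplicates:
            raise FormatError("duplicate frame index in pose data")
        missing = [p for p in BODYPARTS if p not in data.columns.get_level_values(0)]
        if missing:
            raise FormatError(f"missing bodypart column(s): {', '.join(missing)}")
        # canonical column order
        cols = pd.MultiIndex.from_product([BODYPARTS, ("x", "y", "likelihood")])
        data = data.reindex(columns=cols)
        lik = data.loc[:, (slice(None), "likelihood")].to_numpy(float)
        finite = lik[np.isfinite(lik)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("likelihoods must lie in [0, 1]")
        self.data = data.reset_index(drop=True)
        self.frame_rate = float(frame_rate)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def xy(self, part: str) -> np.ndarray:
        """(n_frames, 2) array of x, y for one bodypart, in cm."""
        return self.data[part][["x", "y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        return self.data[(part, "likelihood")].to_numpy(float)

    def clean(self, likelihood_floor: float = 0.9, max_gap: int = 5) -> "PoseTrack":
        """Mark low-likelihood points untracked and bridge short gaps.

        Points with likelihood below ``likelihood_floor`` are treated as
        untracked: runs of at most ``max_gap`` frames bounded by tracked
        samples are linearly interpolated, longer (or edge) runs become NaN
        so downstream event detection excludes them.  This is the automated
        surrogate for the manual outlier correction done on real tracks.
        """
        data = self.data.copy()
        for part in BODYPARTS:
            bad = self.likelihood(part) < likelihood_floor
            if not bad.any():
                continue
            for coord in ("x", "y"):
                vals = data[(part, coord)].to_numpy(float).copy()
                data[(part, coord)] = _interpolate_gaps(vals, bad, max_gap)
        return PoseTrack(data, self.frame_rate)


def _interpolate_gaps(values: np.ndarray, bad: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly bridge bad-runs of length <= max_gap; longer runs become NaN."""
    out = values.copy()
    n = len(values)
    i = 0
    while i < n:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j < n and bad[j]:
            j += 1
        # run [i, j)
        if i > 0 and j < n and (j - i) <= max_gap:
            x0, x1 = values[i - 1], values[j]
            frac = np.arange(1, j - i + 1) / (j - i + 1)
            out[i:j] = x0 + frac * (x1 - x0)
        else:
            out[i:j] = np.nan
        i = j
    return out


@dataclass
class EmgRecording:
    """Four-channel EMG voltage time series, uniformly sampled."""

    times: np.ndarray
    channels: dict[str, np.ndarray]
    rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        n = len(self.times)
        for name, sig in self.channels.items():
            sig = np.asarray(sig, float)
            if len(sig) != n:
                raise ValueError(f"channel {name} length {len(sig)} != times length {n}")
            self.channels[name] = sig
        if n > 1:
            dt = np.diff(self.times)
            if np.max(np.abs(dt - 1.0 / self.rate)) > 1e-6:
                raise FormatError("non-uniform EMG sampling beyond 1e-6 s tolerance")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


# ---------------------------------------------------------------------------
# pose CSV (DeepLabCut dialect)

def read_pose_csv(
    path,
    meta: TrialMeta,
    pixel_to_cm: float,
    name_map: Mapping[str, str] | None = None,
    scorer: str | None = None,
) -> PoseTrack:
    """Read a DeepLabCut-dialect pose CSV and return a calibrated PoseTrack.

    The file stores pixel coordinates; output is in cm with the cylinder
    centre at (0, 0): ``cm = px * pixel_to_cm - meta.cylinder_origin``.
    ``name_map`` optionally maps file bodypart labels to the canonical names.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except Exception as exc:  # malformed header structure
        raise FormatError(f"cannot parse pose CSV {path}: {exc}") from exc
    if raw.columns.nlevels != 3:
        raise FormatError("pose CSV must have 3 header rows (scorer/bodyparts/coords)")
    raw.columns = raw.columns.droplevel(0)  # drop scorer level
    if name_map:
        raw.columns = pd.MultiIndex.from_tuples(
            [(name_map.get(bp, bp), coord) for bp, coord in raw.columns]
        )
    present = set(raw.columns.get_level_values(0))
    missing = [p for p in BODYPARTS if p not in present]
    if missing:
        raise FormatError(f"missing bodypart column(s): {', '.join(missing)}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise FormatError(f"duplicate frame index: {dup}")

    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        raise FormatError(f"non-numeric cell in pose CSV at data row {row}")

    ox, oy = meta.cylinder_origin
    data = {}
    for part in BODYPARTS:
        data[(part, "x")] = num[(part, "x")].to_numpy(float) * pixel_to_cm - ox
        data[(part, "y")] = num[(part, "y")].to_numpy(float) * pixel_to_cm - oy
        data[(part, "likelihood")] = num[(part, "likelihood")].to_numpy(float)
    frame = pd.DataFrame(data)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return PoseTrack(frame, meta.frame_rate)


def write_pose_csv(
    track: PoseTrack,
    path,
    meta: TrialMeta,
    pixel_to_cm: float,
    scorer: str = "finwake",
) -> None:
    """Write a PoseTrack as a DeepLabCut-dialect CSV (pixels), inverting the
    affine calibration used by :func:`read_pose_csv`."""
    ox, oy = meta.cylinder_origin
    cols = {}
    for part in BODYPARTS:
        xy = track.xy(part)
        cols[(scorer, part, "x")] = (xy[:, 0] + ox) / pixel_to_cm
        cols[(scorer, part, "y")] = (xy[:, 1] + oy) / pixel_to_cm
        cols[(scorer, part, "likelihood")] = track.likelihood(part)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["scorer", "bodyparts", "coords"])
    out.index.name = "coords"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# EMG CSV (plain: time column + one column per channel)

def read_emg_csv(path, meta: TrialMeta, channels: Sequence[str] = EMG_CHANNELS) -> EmgRecording:
    """Read a plain-CSV EMG export (time + 4 channel columns)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise FormatError("EMG CSV needs a time column and at least one channel")
    if "time" not in frame.columns:
        raise FormatError("EMG CSV missing 'time' column")
    missing = [c for c in channels if c not in frame.columns]
    if missing:
        raise FormatError(f"missing EMG channel(s): {', '.join(missing)}")
    times = frame["time"].to_numpy(float)
    if len(times) > 1:
        dt = np.diff(times)
        if np.max(np.abs(dt - 1.0 / meta.emg_rate)) > 1e-6:
            raise FormatError("non-uniform EMG sampling beyond 1e-6 s tolerance")
    sig = {c: frame[c].to_numpy(float) for c in channels}
    return EmgRecording(times=times, channels=sig, rate=meta.emg_rate)


def write_emg_csv(rec: EmgRecording, path) -> None:
    frame = pd.DataFrame({"time": rec.times})
    for name, sig in rec.channels.items():
        frame[name] = sig
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result tables

def write_results(
    out_dir,
    events: pd.DataFrame | None = None,
    bouts: pd.DataFrame | None = None,
    bursts: pd.DataFrame | None = None,
    coupling: pd.DataFrame | None = None,
    summary: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write tidy result CSVs (one row per entity) into ``out_dir``.

    Absent tables are written header-only so the output layout is always the
    same; rewriting is idempotent (plain overwrite).  Returns the paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    tables = {
        "events.csv": (events, EVENT_COLUMNS),
        "bouts.csv": (bouts, BOUT_COLUMNS),
        "bursts.csv": (bursts, BURST_COLUMNS),
        "coupling.csv": (coupling, COUPLING_COLUMNS),
        "summary.csv": (summary, ("table", "behavior", "quantity", "value")),
    }
    paths = {}
    for fname, (frame, columns) in tables.items():
        if frame is None:
            frame = pd.DataFrame(columns=list(columns))
        path = os.path.join(out_dir, fname)
        frame.to_csv(path, index=False)
        paths[fname] = path
    return paths


# ---------------------------------------------------------------------------
# config plumbing (TOML)

def load_config(path) -> dict:
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)} to TOML")


def dump_toml(config: Mapping, path) -> None:
    """Minimal TOML emitter for the flat/nested dicts this package produces."""

    def emit(table: Mapping, prefix: str, lines: list[str]) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, Mapping)}
        subs = {k: v for k, v in table.items() if isinstance(v, Mapping)}
        if prefix and scalars:
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_value(v)}")
        if scalars:
            lines.append("")
        for k, v in subs.items():
            emit(v, f"{prefix}.{k}" if prefix else k, lines)

    lines: list[str] = []
    emit(config, "", lines)
    with open(path, "w") as fh:
        fh.write("\n".join(lines).rstrip() + "\n")
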