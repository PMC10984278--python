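"""End-to-end per-trial analysis: track cleaning, fin-extension events,
synchrony, bout classification, EMG bursts and coupling records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coupling as cp
from . import emg as emg_mod
from . import events as ev_mod
from . import kinematics as kin
from .io import (BOUT_COLUMNS, BURST_COLUMNS, COUPLING_COLUMNS, EVENT_COLUMNS,
                 EmgRecording, PoseTrack, TrialMeta)


@dataclass
class AnalysisParams:
    """Every tunable knob of the per-trial analysis, with the defaults used
    throughout (see docs/methods.md for rationale and units)."""

    likelihood_floor: float = 0.9
    max_interp_gap: int = 5
    window_fraction: float = 0.2          # smoothing window as fraction of frame rate
    extension_threshold: float = 0.05     # L units
    min_event_frames: int = 3
    merge_gap_frames: int = 2
    overlap_fraction: float = 0.5
    velocity_window: float = 0.2          # s
    drift_tol: float = 0.1                # L
    v_tol: float = 1.0                    # cm/s
    rise_window: float = 0.5              # s
    emg_order: int = 10
    emg_band: tuple[float, float] = (100.0, 3000.0)
    rel_threshold: float = 0.25
    noise_k: float = 5.0
    refractory: float = 0.002             # s
    max_gap: float = 0.05                 # s
    event_landmark: str = "midline_1"
    alpha: float = 0.05


@dataclass
class TrialAnalysis:
    meta: TrialMeta
    events: list[ev_mod.ExtensionEvent]
    sync: ev_mod.SynchronicityResult
    bout: ev_mod.BehaviorBout
    metrics: kin.BodyWaveMetrics
    forward: kin.Series
    lateral: kin.Series
    extension: dict[str, kin.Series]
    bursts: list[emg_mod.EmgBurst]
    records: list[cp.CouplingRecord]


def analyze_trial(
    track: PoseTrack,
    rec: EmgRecording | None,
    meta: TrialMeta,
    params: AnalysisParams | None = None,
    shedding_frequency: float | None = None,
) -> TrialAnalysis:
    """Run the full per-trial pipeline.

    Pose: clean -> fin-extension metric -> smooth -> threshold events;
    COM velocity from the smoothed third midline point; body-wave metrics and
    bout classification; event positions relative to the cylinder.
    EMG (when provided): zero-phase bandpass -> two-pass spike detection ->
    burst grouping.  Events are then joined to velocity changes, bursts and
    activation patterns.
    """
    p = params or AnalysisParams()
    L = meta.body_length_L
    clean = track.clean(p.likelihood_floor, p.max_interp_gap)

    extension = {}
    per_side_events = {}
    for side in ("left", "right"):
        raw = kin.fin_extension_distance(clean, side, L)
        smoothed = kin.smooth_series(raw, meta.frame_rate, p.window_fraction)
        extension[side] = smoothed
        per_side_events[side] = ev_mod.detect_extension_events(
            smoothed, side=side, threshold=p.extension_threshold,
            min_duration=p.min_event_frames, merge_gap=p.merge_gap_frames)

    sync = ev_mod.label_synchronicity(per_side_events["left"],
                                      per_side_events["right"],
                                      p.overlap_fraction)

    forward, lateral = kin.com_velocity(clean, meta.frame_rate, p.window_fraction)
    metrics = kin.body_wave_metrics(clean, L, shedding_frequency=shedding_frequency)
    bout = ev_mod.classify_bout(metrics, forward, L, drift_tol=p.drift_tol,
                                v_tol=p.v_tol, rise_window=p.rise_window)

    events_with_sync = []
    for side, labels in (("left", sync.left_labels), ("right", sync.right_labels)):
        for event, label in zip(per_side_events[side], labels):
            x, y, zone = ev_mod.event_position(event, clean, landmark=p.event_landmark)
            event.position_at_max = (x, y)
            event.zone = zone
            events_with_sync.append((event, label))
    events_with_sync.sort(key=lambda es: (es[0].onset, es[0].side))

    bursts: list[emg_mod.EmgBurst] = []
    if rec is not None:
        filtered = emg_mod.bandpass_filter(rec, order=p.emg_order, band=p.emg_band)
        bursts = emg_mod.detect_bursts(filtered, rel_threshold=p.rel_threshold,
                                       noise_k=p.noise_k, refractory=p.refractory,
                                       max_gap=p.max_gap)

    records = cp.build_coupling_records(
        events_with_sync, bout.label, forward, lateral, bursts,
        window=p.velocity_window, fish_id=meta.fish_id, trial_id=meta.trial_id)

    return TrialAnalysis(
        meta=meta, events=[e for e, _ in events_with_sync], sync=sync, bout=bout,
        metrics=metrics, forward=forward, lateral=lateral, extension=extension,
        bursts=bursts, records=records)


# ---------------------------------------------------------------------------
# tidy result frames (column dictionaries in finwake.io)

def events_frame(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        sync_by_event = {id(r.event): r.synchronicity for r in a.records}
        for e in a.events:
            x, y = e.position_at_max if e.position_at_max else (np.nan, np.nan)
            rows.append(dict(
                fish_id=a.meta.fish_id, trial_id=a.meta.trial_id, side=e.side,
                onset=e.onset, offset=e.offset, duration=e.duration,
                t_max=e.t_max, peak_extension=e.peak_extension,
                x_at_max=x, y_at_max=y, zone=e.zone,
                synchronicity=sync_by_event.get(id(e), ""),
            ))
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def bouts_frame(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        row = dict(fish_id=a.meta.fish_id, trial_id=a.meta.trial_id,
                   label=a.bout.label, start=a.bout.start, end=a.bout.end)
        row.update(a.bout.criteria_flags)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(BOUT_COLUMNS))


def bursts_frame(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for b in a.bursts:
            rows.append(dict(
                fish_id=a.meta.fish_id, trial_id=a.meta.trial_id,
                channel=b.channel, onset=b.onset, offset=b.offset,
                duration=b.duration, n_spikes=b.n_spikes,
                mean_spike_amplitude=b.mean_spike_amplitude,
            ))
    return pd.DataFrame(rows, columns=list(BURST_COLUMNS))


def coupling_frame(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    rows = []
    for a in analyses:
        for r in a.records:
            row = dict(
                fish_id=r.fish_id, trial_id=r.trial_id, side=r.event.side,
                t_max=r.event.t_max, behavior=r.behavior,
                synchronicity=r.synchronicity,
                pre_forward=r.velocity.pre_forward,
                post_forward=r.velocity.post_forward,
                pre_lateral=r.velocity.pre_lateral,
                post_lateral=r.velocity.post_lateral,
                abduction_pattern=r.activation.abduction,
                adduction_pattern=r.activation.adduction,
                co_contraction_abduction=r.activation.co_contraction_abduction,
                co_contraction_adduction=r.activation.co_contraction_adduction,
                burst_durations=";".join(f"{d:.4f}" for d in r.association.burst_durations),
            )
            for role, flag in r.association.onset.items():
                row[f"onset_{role}"] = flag
            for role, flag in r.association.offset.items():
                row[f"offset_{role}"] = flag
            rows.append(row)
    return pd.DataFrame(rows, columns=list(COUPLING_COLUMNS))


def all_records(analyses: list[TrialAnalysis]) -> list[cp.CouplingRecord]:
    return [r for a in analyses for r in a.records]
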