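"""Joining kinematic events to velocity changes and EMG bursts.

For each fin-extension event the body velocity is averaged over 0.2 s windows
on either side of the time of maximal extension (pre: [t_max - w, t_max),
post: (t_max, t_max + w]); muscle activity is attributed to the event when a
burst overlaps those windows; and each movement phase (abduction up to t_max,
adduction after) is classified as active, passive or resistive from which
ipsilateral muscle was recruited during it:

    agonist only            -> active_*    (abductor drives abduction, ...)
    no ipsilateral activity -> passive_*   (vortex-driven fin movement)
    antagonist only         -> resistive_* (muscle opposing the movement)
    both                    -> active_* with a co-contraction flag

The pre/post comparison is a one-sample Kolmogorov-Smirnov normality check on
the standardised paired differences followed by a paired two-tailed Student's
t-test (pre and post are measured on the same event, so the paired form is
the default; an unpaired variant is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .emg import EmgBurst
from .events import ExtensionEvent
from .kinematics import Series

MUSCLE_ROLES = ("ipsi_abductor", "ipsi_adductor", "contra_abductor", "contra_adductor")
ACTIVATION_PATTERNS = (
    "active_abduction", "active_adduction",
    "passive_abduction", "passive_adduction",
    "resistive_abduction", "resistive_adduction",
)


@dataclass
class VelocityChange:
    pre_forward: float
    post_forward: float
    pre_lateral: float
    post_lateral: float
    truncated: bool = False


@dataclass
class MuscleAssociation:
    """Per-muscle activity flags in the onset/offset windows of one event."""

    onset: dict[str, bool]
    offset: dict[str, bool]
    burst_durations: list[float]

    @property
    def onset_any(self) -> bool:
        return any(self.onset.values())

    @property
    def offset_any(self) -> bool:
        return any(self.offset.values())

    @property
    def onset_ipsi_any(self) -> bool:
        return self.onset["ipsi_abductor"] or self.onset["ipsi_adductor"]

    @property
    def offset_ipsi_any(self) -> bool:
        return self.offset["ipsi_abductor"] or self.offset["ipsi_adductor"]


@dataclass
class PhaseActivation:
    """Activation-pattern labels for the abduction and adduction phases."""

    abduction: str | None
    adduction: str | None
    co_contraction_abduction: bool = False
    co_contraction_adduction: bool = False


@dataclass
class PrePostTestResult:
    n: int
    pre_mean: float
    post_mean: float
    ks_stat: float
    ks_p: float
    t_stat: float
    t_p: float
    significant: bool
    degenerate: bool = False
    paired: bool = True
    alpha: float = 0.05


@dataclass
class CouplingRecord:
    """One ExtensionEvent joined to its velocity change, bursts, synchronicity
    label and activation patterns."""

    event: ExtensionEvent
    behavior: str
    synchronicity: str
    velocity: VelocityChange
    association: MuscleAssociation
    activation: PhaseActivation
    fish_id: str = ""
    trial_id: str = ""


def _window_mean(series: Series, lo: float, hi: float, closed: str,
                 min_coverage: float = 0.5) -> tuple[float, bool]:
    """Mean over a half-open window; NaN when < min_coverage of the expected
    samples are available, flagged truncated when some are missing."""
    t, v = series.times, series.values
    eps = 1e-9
    if closed == "left":
        mask = (t >= lo - eps) & (t < hi - eps)
    else:
        mask = (t > lo + eps) & (t <= hi + eps)
    expected = max(1, int(round((hi - lo) * series.rate)))
    vals = v[mask]
    vals = vals[np.isfinite(vals)]
    coverage = len(vals) / expected
    if coverage < min_coverage:
        return float("nan"), True
    return float(np.mean(vals)), coverage < 1.0 - eps


def velocity_change(
    event: ExtensionEvent,
    forward: Series,
    lateral: Series,
    window: float = 0.2,
) -> VelocityChange:
    """Pre/post velocity means around maximal extension.

    pre = mean over [t_max - window, t_max), post = mean over
    (t_max, t_max + window].  Windows with >= 50% of their samples inside the
    series are computed and flagged truncated; emptier windows are NaN.
    """
    tm = event.t_max
    if not (forward.times[0] <= tm <= forward.times[-1]):
        raise ValueError("event t_max outside the velocity series")
    pre_f, tr1 = _window_mean(forward, tm - window, tm, "left")
    post_f, tr2 = _window_mean(forward, tm, tm + window, "right")
    pre_l, tr3 = _window_mean(lateral, tm - window, tm, "left")
    post_l, tr4 = _window_mean(lateral, tm, tm + window, "right")
    return VelocityChange(pre_f, post_f, pre_l, post_l,
                          truncated=tr1 or tr2 or tr3 or tr4)


def pre_post_test(
    pre,
    post,
    paired: bool = True,
    alpha: float = 0.05,
) -> PrePostTestResult:
    """KS normality check on the standardised paired differences, then a
    two-tailed Student's t-test on pre vs post velocities."""
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 finite (pre, post) pairs")
    d = post - pre
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        equal = bool(np.all(d == 0.0))
        return PrePostTestResult(
            n=n, pre_mean=float(pre.mean()), post_mean=float(post.mean()),
            ks_stat=float("nan"), ks_p=float("nan"),
            t_stat=0.0 if equal else float("nan"),
            t_p=1.0 if equal else float("nan"),
            significant=not equal, degenerate=True, paired=paired, alpha=alpha,
        )
    z = (d - d.mean()) / sd
    ks_stat, ks_p = stats.kstest(z, "norm")
    if paired:
        t_stat, t_p = stats.ttest_1samp(d, 0.0)
    else:
        t_stat, t_p = stats.ttest_ind(post, pre)
    return PrePostTestResult(
        n=n, pre_mean=float(pre.mean()), post_mean=float(post.mean()),
        ks_stat=float(ks_stat), ks_p=float(ks_p),
        t_stat=float(t_stat), t_p=float(t_p),
        significant=bool(t_p < alpha), degenerate=False, paired=paired, alpha=alpha,
    )


def _burst_role(burst: EmgBurst, event_side: str) -> str:
    side, muscle = burst.channel.split("_", 1)
    ipsi = (side == "L") == (event_side == "left")
    return f"{'ipsi' if ipsi else 'contra'}_{muscle}"


def _overlaps(burst: EmgBurst, lo: float, hi: float) -> bool:
    return min(burst.offset, hi) - max(burst.onset, lo) > 1e-12


def muscle_association(
    event: ExtensionEvent,
    bursts: list[EmgBurst],
    window: float = 0.2,
) -> MuscleAssociation:
    """Per-muscle activity flags for the onset window [t_max - w, t_max) and
    the offset window (t_max, t_max + w], plus the overlapping bursts'
    durations.  Flags are monotone in the window length."""
    tm = event.t_max
    onset = {r: False for r in MUSCLE_ROLES}
    offset = {r: False for r in MUSCLE_ROLES}
    durations: list[float] = []
    for b in bursts:
        role = _burst_role(b, event.side)
        hit = False
        if _overlaps(b, tm - window, tm):
            onset[role] = True
            hit = True
        if _overlaps(b, tm, tm + window):
            offset[role] = True
            hit = True
        if hit:
            durations.append(b.duration)
    return MuscleAssociation(onset=onset, offset=offset, burst_durations=durations)


def _phase_pattern(phase: str, abd: bool, add: bool) -> tuple[str, bool]:
    agonist = abd if phase == "abduction" else add
    antagonist = add if phase == "abduction" else abd
    if agonist and antagonist:
        return f"active_{phase}", True
    if agonist:
        return f"active_{phase}", False
    if antagonist:
        return f"resistive_{phase}", False
    return f"passive_{phase}", False


def classify_activation_pattern(
    event: ExtensionEvent,
    bursts: list[EmgBurst],
) -> PhaseActivation:
    """Classify the abduction phase [onset, t_max] and the adduction phase
    [t_max, offset] from overlapping ipsilateral muscle activity (see module
    docstring for the truth table).  Zero-length phases are unclassified."""
    ipsi = [b for b in bursts if _burst_role(b, event.side).startswith("ipsi")]

    def phase_flags(lo: float, hi: float) -> tuple[bool, bool]:
        abd = any(_overlaps(b, lo, hi) for b in ipsi if b.channel.endswith("abductor"))
        add = any(_overlaps(b, lo, hi) for b in ipsi if b.channel.endswith("adductor"))
        return abd, add

    abduction = adduction = None
    co_abd = co_add = False
    if event.t_max > event.onset:
        abduction, co_abd = _phase_pattern("abduction",
                                           *phase_flags(event.onset, event.t_max))
    if event.offset > event.t_max:
        adduction, co_add = _phase_pattern("adduction",
                                           *phase_flags(event.t_max, event.offset))
    return PhaseActivation(abduction=abduction, adduction=adduction,
                           co_contraction_abduction=co_abd,
                           co_contraction_adduction=co_add)


def build_coupling_records(
    events_with_sync: list[tuple[ExtensionEvent, str]],
    behavior: str,
    forward: Series,
    lateral: Series,
    bursts: list[EmgBurst],
    window: float = 0.2,
    fish_id: str = "",
    trial_id: str = "",
) -> list[CouplingRecord]:
    """Assemble one CouplingRecord per (event, synchronicity label)."""
    records = []
    for event, sync in events_with_sync:
        records.append(CouplingRecord(
            event=event,
            behavior=behavior,
            synchronicity=sync,
            velocity=velocity_change(event, forward, lateral, window),
            association=muscle_association(event, bursts, window),
            activation=classify_activation_pattern(event, bursts),
            fish_id=fish_id,
            trial_id=trial_id,
        ))
    return records


def records_from_frame(frame: pd.DataFrame) -> list[CouplingRecord]:
    """Rebuild the CouplingRecords a coupling.csv holds (event timing fields
    beyond side/t_max are not stored there, so the event carries a nominal
    zero-length placeholder interval around t_max)."""
    from types import SimpleNamespace

    records = []
    for _, row in frame.iterrows():
        onset = {r: bool(row[f"onset_{r}"]) for r in MUSCLE_ROLES}
        offset = {r: bool(row[f"offset_{r}"]) for r in MUSCLE_ROLES}
        dur_cell = row.get("burst_durations", "")
        durations = ([float(x) for x in str(dur_cell).split(";") if x]
                     if isinstance(dur_cell, str) and dur_cell else [])
        records.append(CouplingRecord(
            event=SimpleNamespace(side=row["side"], t_max=row["t_max"]),
            behavior=row["behavior"],
            synchronicity=row["synchronicity"],
            velocity=VelocityChange(row["pre_forward"], row["post_forward"],
                                    row["pre_lateral"], row["post_lateral"]),
            association=MuscleAssociation(onset=onset, offset=offset,
                                          burst_durations=durations),
            activation=PhaseActivation(
                abduction=row.get("abduction_pattern"),
                adduction=row.get("adduction_pattern"),
                co_contraction_abduction=bool(row.get("co_contraction_abduction", False)),
                co_contraction_adduction=bool(row.get("co_contraction_adduction", False)),
            ),
            fish_id=str(row.get("fish_id", "")),
            trial_id=str(row.get("trial_id", "")),
        ))
    return records


# ---------------------------------------------------------------------------
# cohort summaries

@dataclass
class CouplingSummary:
    synchronicity: pd.DataFrame
    activity: pd.DataFrame
    durations: pd.DataFrame
    velocity_tests: dict[str, PrePostTestResult]

    def to_frame(self) -> pd.DataFrame:
        """Flatten into the tidy (table, behavior, quantity, value) layout of
        summary.csv."""
        rows = []
        for _, r in self.synchronicity.iterrows():
            for col in ("n_events", "n_synchronous", "frac_synchronous", "frac_asynchronous"):
                rows.append(("synchronicity", r["behavior"], col, r[col]))
        for _, r in self.activity.iterrows():
            for col in ("frac_any", "frac_ipsi", "frac_contra", "frac_none"):
                rows.append((f"activity_{r['window']}", r["behavior"], col, r[col]))
        for _, r in self.durations.iterrows():
            for col in ("n_bursts", "mean_duration", "sem_duration"):
                rows.append(("emg_duration", r["behavior"], col, r[col]))
        for name, res in self.velocity_tests.items():
            for col, val in (("n", res.n), ("pre_mean", res.pre_mean),
                             ("post_mean", res.post_mean), ("ks_p", res.ks_p),
                             ("t_stat", res.t_stat), ("t_p", res.t_p),
                             ("significant", float(res.significant))):
                rows.append(("velocity_test", name, col, val))
        return pd.DataFrame(rows, columns=["table", "behavior", "quantity", "value"])


def summarize_coupling(records: list[CouplingRecord], alpha: float = 0.05) -> CouplingSummary:
    """Cohort summary: synchrony counts and fractions per behaviour, fractions
    of events with muscle activity in the onset/offset windows, mean +/- s.e.m.
    burst durations, and the pre/post velocity tests (forward velocity for
    braking events; lateral velocity split by extended side for Kármán
    gaiting)."""
    behaviors = sorted({r.behavior for r in records})

    sync_rows = []
    act_rows = []
    dur_rows = []
    for beh in behaviors:
        grp = [r for r in records if r.behavior == beh]
        n = len(grp)
        n_sync = sum(r.synchronicity == "synchronous" for r in grp)
        sync_rows.append({
            "behavior": beh, "n_events": n, "n_synchronous": n_sync,
            "n_asynchronous": n - n_sync,
            "frac_synchronous": n_sync / n if n else float("nan"),
            "frac_asynchronous": (n - n_sync) / n if n else float("nan"),
        })
        for wname in ("onset", "offset"):
            anyf = [getattr(r.association, f"{wname}_any") for r in grp]
            ipsi = [getattr(r.association, f"{wname}_ipsi_any") for r in grp]
            contra = [
                r.association.onset["contra_abductor"] or r.association.onset["contra_adductor"]
                if wname == "onset"
                else r.association.offset["contra_abductor"] or r.association.offset["contra_adductor"]
                for r in grp
            ]
            act_rows.append({
                "behavior": beh, "window": wname, "n_events": n,
                "frac_any": float(np.mean(anyf)) if n else float("nan"),
                "frac_ipsi": float(np.mean(ipsi)) if n else float("nan"),
                "frac_contra": float(np.mean(contra)) if n else float("nan"),
                "frac_none": float(np.mean(~np.asarray(anyf))) if n else float("nan"),
            })
        durations = [d for r in grp for d in r.association.burst_durations]
        dur_rows.append({
            "behavior": beh, "n_bursts": len(durations),
            "mean_duration": float(np.mean(durations)) if durations else float("nan"),
            "sem_duration": float(np.std(durations, ddof=1) / np.sqrt(len(durations)))
            if len(durations) > 1 else float("nan"),
        })

    tests: dict[str, PrePostTestResult] = {}
    braking = [r for r in records if r.behavior == "braking"]
    pairs = [(r.velocity.pre_forward, r.velocity.post_forward) for r in braking]
    pairs = [(a, b) for a, b in pairs if np.isfinite(a) and np.isfinite(b)]
    if len(pairs) >= 2:
        pre, post = zip(*pairs)
        tests["braking_forward"] = pre_post_test(pre, post, alpha=alpha)
    for side in ("left", "right"):
        kg = [r for r in records if r.behavior == "karman_gait" and r.event.side == side]
        pairs = [(r.velocity.pre_lateral, r.velocity.post_lateral) for r in kg]
        pairs = [(a, b) for a, b in pairs if np.isfinite(a) and np.isfinite(b)]
        if len(pairs) >= 2:
            pre, post = zip(*pairs)
            tests[f"karman_gait_lateral_{side}"] = pre_post_test(pre, post, alpha=alpha)

    return CouplingSummary(
        synchronicity=pd.DataFrame(sync_rows),
        activity=pd.DataFrame(act_rows),
        durations=pd.DataFrame(dur_rows),
        velocity_tests=tests,
    )
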