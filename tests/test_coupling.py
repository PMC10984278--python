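"""Velocity windows, pre/post statistics, muscle association, activation
patterns and cohort summaries."""

import numpy as np
import pytest

from finwake.coupling import (classify_activation_pattern, muscle_association,
                              pre_post_test, summarize_coupling,
                              velocity_change, CouplingRecord,
                              MuscleAssociation, PhaseActivation,
                              VelocityChange)
from finwake.emg import EmgBurst
from finwake.events import ExtensionEvent
from finwake.kinematics import Series


def make_event(onset=1.0, offset=2.0, t_max=1.5, side="left"):
    return ExtensionEvent(side=side, onset=onset, offset=offset, t_max=t_max,
                          peak_extension=0.15, onset_frame=int(onset * 150),
                          offset_frame=int(offset * 150),
                          t_max_frame=int(t_max * 150))


def vel(values, rate=150.0):
    values = np.asarray(values, float)
    return Series(np.arange(len(values)) / rate, values, "cm/s")


class TestVelocityChange:
    def test_constant_position_zero(self):
        e = make_event()
        out = velocity_change(e, vel(np.zeros(450)), vel(np.zeros(450)))
        assert out.pre_forward == 0.0 and out.post_forward == 0.0

    def test_constant_velocity(self):
        e = make_event()
        out = velocity_change(e, vel(np.full(450, 3.0)), vel(np.zeros(450)))
        assert out.pre_forward == pytest.approx(3.0)
        assert out.post_forward == pytest.approx(3.0)
        assert not out.truncated

    def test_step_at_t_max_recovers_signs(self):
        n, rate = 450, 150.0
        t = np.arange(n) / rate
        v = np.where(t < 1.5, -4.0, 3.0)
        out = velocity_change(make_event(), vel(v), vel(np.zeros(n)))
        assert out.pre_forward == pytest.approx(-4.0, rel=0.01)
        assert out.post_forward == pytest.approx(3.0, rel=0.01)

    def test_truncated_window_flagged_then_missing(self):
        # t_max 0.15 s into the series: pre window has 75% coverage -> flagged
        e = make_event(onset=0.1, offset=0.5, t_max=0.15)
        out = velocity_change(e, vel(np.full(150, 2.0)), vel(np.zeros(150)))
        assert out.truncated and np.isfinite(out.pre_forward)
        # t_max 0.05 s in: 25% coverage -> missing
        e = make_event(onset=0.01, offset=0.5, t_max=0.05)
        out = velocity_change(e, vel(np.full(150, 2.0)), vel(np.zeros(150)))
        assert np.isnan(out.pre_forward)

    def test_t_max_outside_series_rejected(self):
        with pytest.raises(ValueError):
            velocity_change(make_event(t_max=99.0, offset=100.0),
                            vel(np.zeros(450)), vel(np.zeros(450)))


class TestPrePostTest:
    def test_identical_pairs_t0_p1(self):
        res = pre_post_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == 0.0 and res.t_p == 1.0
        assert res.degenerate and not res.significant

    def test_closed_form_paired_t(self):
        # differences {1,1,1,2}: t = 1.25 / (0.5 / 2) = 5.0
        res = pre_post_test([0, 0, 0, 0], [1, 1, 1, 2])
        assert res.t_stat == pytest.approx(5.0)
        assert res.n == 4

    def test_zero_variance_unequal_is_degenerate_significant(self):
        res = pre_post_test([0.0, 0.0], [1.0, 1.0])
        assert res.degenerate and res.significant
        assert np.isnan(res.t_stat)

    def test_needs_two_pairs(self):
        with pytest.raises(ValueError):
            pre_post_test([1.0], [2.0])

    def test_ks_pvalue_reasonable_under_normality(self):
        rng = np.random.default_rng(0)
        res = pre_post_test(rng.normal(size=200), rng.normal(1.0, 1.0, 200))
        assert 0.0 <= res.ks_p <= 1.0
        assert res.ks_p > 0.01  # normal differences should not be rejected


def burst(channel, onset, offset):
    return EmgBurst(channel=channel, onset=onset, offset=offset, n_spikes=5,
                    mean_spike_amplitude=10.0)


class TestMuscleAssociation:
    def test_burst_in_onset_window(self):
        e = make_event()  # left fin, t_max 1.5
        out = muscle_association(e, [burst("L_abductor", 1.40, 1.45)])
        assert out.onset["ipsi_abductor"]
        assert not out.offset["ipsi_abductor"]
        assert out.onset_any and not out.offset_any

    def test_burst_ending_before_window_excluded(self):
        e = make_event()
        out = muscle_association(e, [burst("L_abductor", 1.0, 1.25)])
        assert not out.onset_any  # ends 0.25 s before t_max, window is 0.2 s

    def test_burst_spanning_t_max_sets_both_windows(self):
        e = make_event()
        out = muscle_association(e, [burst("R_adductor", 1.45, 1.55)])
        assert out.onset["contra_adductor"] and out.offset["contra_adductor"]

    def test_window_monotonicity(self):
        e = make_event()
        bursts = [burst("L_abductor", 1.40, 1.45), burst("R_adductor", 1.0, 1.2),
                  burst("L_adductor", 1.62, 1.9)]
        small = muscle_association(e, bursts, window=0.1)
        large = muscle_association(e, bursts, window=0.4)
        for role in small.onset:
            assert large.onset[role] >= small.onset[role]
            assert large.offset[role] >= small.offset[role]


class TestActivationPattern:
    """The full 6-class truth table over ipsilateral muscle overlap per phase."""

    CASES = {
        # (abductor in abd phase, adductor in abd phase): abduction label
        (False, False): ("passive_abduction", False),
        (True, False): ("active_abduction", False),
        (False, True): ("resistive_abduction", False),
        (True, True): ("active_abduction", True),
    }

    @pytest.mark.parametrize("abd,add", list(CASES))
    def test_abduction_phase_truth_table(self, abd, add):
        e = make_event()  # abduction phase [1.0, 1.5]
        bursts = []
        if abd:
            bursts.append(burst("L_abductor", 1.1, 1.3))
        if add:
            bursts.append(burst("L_adductor", 1.2, 1.4))
        out = classify_activation_pattern(e, bursts)
        label, co = self.CASES[(abd, add)]
        assert out.abduction == label
        assert out.co_contraction_abduction == co
        assert out.adduction == "passive_adduction"

    @pytest.mark.parametrize("abd,add,label,co", [
        (False, False, "passive_adduction", False),
        (False, True, "active_adduction", False),
        (True, False, "resistive_adduction", False),
        (True, True, "active_adduction", True),
    ])
    def test_adduction_phase_truth_table(self, abd, add, label, co):
        e = make_event()  # adduction phase [1.5, 2.0]
        bursts = []
        if abd:
            bursts.append(burst("L_abductor", 1.6, 1.8))
        if add:
            bursts.append(burst("L_adductor", 1.7, 1.9))
        out = classify_activation_pattern(e, bursts)
        assert out.adduction == label
        assert out.co_contraction_adduction == co

    def test_contralateral_bursts_ignored(self):
        e = make_event()
        out = classify_activation_pattern(e, [burst("R_abductor", 1.1, 1.9)])
        assert out.abduction == "passive_abduction"
        assert out.adduction == "passive_adduction"

    def test_braking_co_contraction_sequence(self):
        # both abductor and adductor active while the fin is held out
        e = make_event(onset=1.2, offset=2.2, t_max=1.7)
        bursts = [burst("L_abductor", 1.1, 1.45), burst("L_adductor", 1.55, 2.3)]
        out = classify_activation_pattern(e, bursts)
        assert out.abduction == "active_abduction"
        assert out.co_contraction_abduction
        assert out.adduction == "active_adduction"

    def test_canonical_abductor_then_adductor(self):
        e = make_event()
        bursts = [burst("L_abductor", 1.1, 1.4), burst("L_adductor", 1.6, 1.9)]
        out = classify_activation_pattern(e, bursts)
        assert out.abduction == "active_abduction"
        assert out.adduction == "active_adduction"
        assert not out.co_contraction_abduction
        assert not out.co_contraction_adduction

    def test_extension_with_no_emg_is_passive(self):
        out = classify_activation_pattern(make_event(), [])
        assert out.abduction == "passive_abduction"
        assert out.adduction == "passive_adduction"

    def test_zero_length_phase_unclassified(self):
        e = make_event(onset=1.0, offset=2.0, t_max=1.0)
        out = classify_activation_pattern(e, [])
        assert out.abduction is None
        assert out.adduction == "passive_adduction"


def make_record(behavior, sync, side="left", pre_f=np.nan, post_f=np.nan,
                pre_l=np.nan, post_l=np.nan, durations=()):
    flags = {r: False for r in
             ("ipsi_abductor", "ipsi_adductor", "contra_abductor", "contra_adductor")}
    return CouplingRecord(
        event=make_event(side=side), behavior=behavior, synchronicity=sync,
        velocity=VelocityChange(pre_f, post_f, pre_l, post_l),
        association=MuscleAssociation(onset=dict(flags), offset=dict(flags),
                                      burst_durations=list(durations)),
        activation=PhaseActivation("passive_abduction", "passive_adduction"),
    )


class TestSummarizeCoupling:
    def test_braking_synchronous_fraction_9_of_13(self):
        records = [make_record("braking", "synchronous") for _ in range(9)]
        records += [make_record("braking", "asynchronous") for _ in range(4)]
        out = summarize_coupling(records)
        row = out.synchronicity.iloc[0]
        assert row["n_events"] == 13
        assert row["frac_synchronous"] == pytest.approx(9 / 13)

    def test_kg_asynchronous_fraction_237_of_272(self):
        records = [make_record("karman_gait", "asynchronous") for _ in range(237)]
        records += [make_record("karman_gait", "synchronous") for _ in range(35)]
        out = summarize_coupling(records)
        row = out.synchronicity.iloc[0]
        assert row["frac_asynchronous"] == pytest.approx(237 / 272)

    def test_all_passive_means_zero_activity_fractions(self):
        records = [make_record("karman_gait", "asynchronous") for _ in range(10)]
        out = summarize_coupling(records)
        assert (out.activity["frac_any"] == 0.0).all()
        assert (out.activity["frac_none"] == 1.0).all()

    def test_velocity_tests_built_per_behavior_and_side(self):
        rng = np.random.default_rng(1)
        records = [make_record("braking", "synchronous",
                               pre_f=-4 + rng.normal(), post_f=3 + rng.normal())
                   for _ in range(20)]
        records += [make_record("karman_gait", "asynchronous", side="left",
                                pre_l=1.8 + rng.normal(), post_l=-2.3 + rng.normal())
                    for _ in range(20)]
        out = summarize_coupling(records)
        assert out.velocity_tests["braking_forward"].significant
        assert out.velocity_tests["karman_gait_lateral_left"].significant
        assert "karman_gait_lateral_right" not in out.velocity_tests

    def test_burst_duration_mean_and_sem(self):
        records = [make_record("braking", "synchronous", durations=(0.2, 0.4))]
        out = summarize_coupling(records)
        row = out.durations.iloc[0]
        assert row["mean_duration"] == pytest.approx(0.3)
        assert row["n_bursts"] == 2

    def test_summary_frame_is_tidy(self):
        records = [make_record("braking", "synchronous") for _ in range(3)]
        frame = summarize_coupling(records).to_frame()
        assert list(frame.columns) == ["table", "behavior", "quantity", "value"]
        assert len(frame) > 0
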