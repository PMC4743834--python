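import math
from dataclasses import replace

import numpy as np
import pytest

from pupilhci.decoder import DecoderConfig, measure_block
from pupilhci.pupilsim import (
    ParticipantProfile,
    attended_luminance_series,
    null_trace,
    simulate_session,
    simulate_trace,
)
from pupilhci.schedule import (
    CycleSchedule,
    DisplayConfig,
    ScheduleError,
    make_partition,
)

RATE = 250.0


@pytest.fixture
def clean_profile():
    """No noise, no transient, no blinks: the deterministic light response."""
    return ParticipantProfile(transient_amplitude=1e-9, drift_sd=0.0,
                              sample_noise_sd=0.0, blink_rate=0.0, seed=1)


class TestAttendedLuminance:
    def test_bright_hold_is_one(self, display):
        sched = CycleSchedule(display, make_partition(("a", "b")), n_cycles=2)
        lum = attended_luminance_series(sched, "a", RATE)
        hold = lum[round(0.5 * RATE):round(1.25 * RATE)]
        assert np.allclose(hold, 1.0)  # 'a' transitions into bright first

    def test_alternates_with_cycles(self, display):
        sched = CycleSchedule(display, make_partition(("a", "b")), n_cycles=2)
        lum = attended_luminance_series(sched, "a", RATE)
        hold2 = lum[round(1.75 * RATE):round(2.5 * RATE)]
        assert np.allclose(hold2, 0.0)

    def test_same_group_items_identical(self, display):
        sched = CycleSchedule(display, make_partition(tuple("abcd")), n_cycles=3)
        la = attended_luminance_series(sched, "a", RATE)
        lb = attended_luminance_series(sched, "b", RATE)
        assert np.array_equal(la, lb)

    def test_inactive_item_rejected(self, display):
        sched = CycleSchedule(display, make_partition(("a", "b")), n_cycles=1)
        with pytest.raises(ScheduleError):
            attended_luminance_series(sched, "z", RATE)

    def test_values_normalized(self, display):
        sched = CycleSchedule(display, make_partition(("a", "b")), n_cycles=4)
        lum = attended_luminance_series(sched, "b", RATE)
        assert lum.min() >= 0.0 and lum.max() <= 1.0


class TestSimulateTrace:
    def test_steady_state_under_constant_bright(self, clean_profile):
        lum = np.ones(round(5.0 * RATE))
        trace = simulate_trace(clean_profile, lum, sample_rate=RATE)
        target = clean_profile.baseline_ps - clean_profile.modulation_gain
        assert trace.samples[-1] == pytest.approx(target, abs=0.1)
        # monotone approach after the dead time
        tail = trace.samples[round(0.5 * RATE):]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_fully_degenerate_profile_is_constant(self, clean_profile):
        prof = replace(clean_profile, modulation_gain=0.0)
        trace = simulate_trace(prof, np.full(500, 0.3), sample_rate=RATE)
        assert np.allclose(trace.samples, prof.baseline_ps, atol=1e-6)

    def test_reproducible_given_seed(self):
        prof = ParticipantProfile(seed=7)
        lum = np.linspace(0, 1, 1000)
        t1 = simulate_trace(prof, lum, [0.5], sample_rate=RATE)
        t2 = simulate_trace(prof, lum, [0.5], sample_rate=RATE)
        assert np.array_equal(t1.samples, t2.samples)
        assert np.array_equal(t1.valid, t2.valid)

    def test_transient_trough_timing(self):
        # transient only: trough ~0.2 s after the transition ends
        prof = ParticipantProfile(modulation_gain=0.0, drift_sd=0.0,
                                  sample_noise_sd=0.0, blink_rate=0.0,
                                  transient_amplitude=30.0)
        trace = simulate_trace(prof, np.full(round(1.25 * RATE), 0.5),
                               transition_times=[0.5], sample_rate=RATE)
        trough = np.argmin(trace.samples) / RATE
        assert 0.65 <= trough <= 0.75
        assert trace.samples.min() == pytest.approx(
            prof.baseline_ps - prof.transient_amplitude, abs=0.5)

    def test_blinks_marked_invalid(self):
        prof = ParticipantProfile(blink_rate=60.0, seed=3)
        trace = simulate_trace(prof, np.full(round(20 * RATE), 0.5),
                               sample_rate=RATE)
        assert not trace.valid.all()
        assert trace.valid.any()


class TestMeasurementWindowDirection:
    def test_bright_attended_smaller_than_dark_attended(self, clean_profile,
                                                        display):
        """The decoder's statistic separates the polarities as recorded
        human data does: larger pupil when the attended stimulus is dark."""
        sched = CycleSchedule(display, make_partition(("a", "b")), n_cycles=6)
        rate = RATE
        lum_a = attended_luminance_series(sched, "a", rate)
        lum_b = attended_luminance_series(sched, "b", rate)
        tr_a = simulate_trace(clean_profile, lum_a, sample_rate=rate)
        tr_b = simulate_trace(clean_profile, lum_b, sample_rate=rate)
        # cycle 4 (even): 'a' transitions into bright, 'b' into dark
        w0 = round((5 * 1.25 - 0.25) * rate)
        w1 = round(5 * 1.25 * rate)
        ps_a = np.median(tr_a.samples[w0:w1])
        ps_b = np.median(tr_b.samples[w0:w1])
        assert ps_a < ps_b


class TestNullTrace:
    def test_reproducible(self):
        prof = ParticipantProfile(seed=9)
        t1 = null_trace(prof, 10.0, sample_rate=RATE)
        t2 = null_trace(prof, 10.0, sample_rate=RATE)
        assert np.array_equal(t1.samples, t2.samples)

    def test_zero_noise_zero_transient_is_constant(self):
        prof = ParticipantProfile(transient_amplitude=1e-9, drift_sd=0.0,
                                  sample_noise_sd=0.0, blink_rate=0.0)
        trace = null_trace(prof, 5.0, sample_rate=RATE)
        assert np.allclose(trace.samples, prof.baseline_ps, atol=1e-6)

    def test_mean_log_ppsd_near_zero(self, display):
        """Symmetric noise: consecutive-window log-ratios have zero mean."""
        prof = ParticipantProfile(seed=21, blink_rate=0.0)
        n_cycles = 400
        trace = null_trace(prof, n_cycles * 1.25, sample_rate=100.0)
        ps = []
        for c in range(n_cycles):
            w0 = round((c * 1.25 + 1.0) * 100)
            w1 = round((c + 1) * 1.25 * 100)
            ps.append(np.median(trace.samples[w0:w1]))
        logr = np.diff(np.log(ps))
        sem = logr.std() / math.sqrt(len(logr))
        assert abs(logr.mean()) < 4 * sem


class TestSimulateSession:
    def test_strong_signal_is_perfect(self):
        prof = ParticipantProfile(modulation_gain=200.0, drift_sd=0.5,
                                  sample_noise_sd=0.5, blink_rate=0.0, seed=2,
                                  transient_amplitude=1.0)
        recs = simulate_session(prof, 8, 16, DecoderConfig(), seed=5,
                                sample_rate=100.0)
        assert all(r.correct for r in recs)
        assert all(r.n_items == 8 and r.phase == 3 for r in recs)

    def test_same_seed_identical_records(self):
        prof = ParticipantProfile()
        a = simulate_session(prof, 2, 4, seed=11, sample_rate=100.0)
        b = simulate_session(prof, 2, 4, seed=11, sample_rate=100.0)
        assert a == b

    def test_response_time_matches_cycles(self):
        prof = ParticipantProfile()
        recs = simulate_session(prof, 2, 3, seed=13, sample_rate=100.0)
        for r in recs:
            assert r.response_time == pytest.approx(r.n_cycles * 1.25)

    def test_non_power_of_two_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(ParticipantProfile(), 6, 1)


class TestProfileValidation:
    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ParticipantProfile(baseline_ps=0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ParticipantProfile(sample_noise_sd=-1.0)
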