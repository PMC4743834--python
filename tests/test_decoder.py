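import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pupilhci.decoder import (
    DecoderConfig,
    DecoderError,
    LikelihoodState,
    PupilMeasurement,
    SelectionOutcome,
    decide,
    measure_ps,
    ppsd,
    run_selection,
    update,
)
from pupilhci.schedule import SelectionTreeState, make_partition

from conftest import make_trace


def assignment_to_dark(group: int):
    """Two-item assignment in which ``group`` transitions bright -> dark."""
    a = make_partition(("a", "b"))
    if a.group_polarity[group] == "dark":
        return a
    from pupilhci.schedule import flip_polarity

    return flip_polarity(a)


def measurement(ps, cycle=0):
    return PupilMeasurement(ps=ps, cycle_index=cycle, n_valid_samples=10,
                            valid_fraction=1.0)


class TestMeasurePS:
    def test_median_of_window(self):
        trace = make_trace([4, 5, 6, 100], rate=4.0)
        m = measure_ps(trace, 0.0, 1.0)
        assert m.ps == 5.5 and not m.missing

    def test_constant_series(self):
        trace = make_trace([512.0] * 50, rate=100.0)
        assert measure_ps(trace, 0.0, 0.5).ps == 512.0

    def test_mostly_invalid_window_is_missing(self):
        valid = [False] * 8 + [True] * 2
        trace = make_trace(range(10, 20), valid=valid, rate=10.0)
        m = measure_ps(trace, 0.0, 1.0, min_valid_fraction=0.5)
        assert m.missing and math.isnan(m.ps)
        assert m.valid_fraction == pytest.approx(0.2)

    def test_empty_window_rejected(self):
        trace = make_trace([1.0, 2.0], rate=2.0)
        with pytest.raises(DecoderError):
            measure_ps(trace, 0.5, 0.5)

    def test_window_outside_trace_rejected(self):
        trace = make_trace([1.0, 2.0], rate=2.0)
        with pytest.raises(DecoderError):
            measure_ps(trace, 0.5, 2.0)


class TestPPSD:
    @pytest.mark.parametrize("cur, prev, expected", [
        (500.0, 500.0, 1.0),
        (550.0, 500.0, 1.1),
        (400.0, 500.0, 0.8),
    ])
    def test_ratio(self, cur, prev, expected):
        assert ppsd(cur, prev) == pytest.approx(expected)

    @pytest.mark.parametrize("cur, prev", [(500.0, 0.0), (0.0, 500.0),
                                           (-1.0, 500.0)])
    def test_non_positive_rejected(self, cur, prev):
        with pytest.raises(DecoderError):
            ppsd(cur, prev)


class TestUpdate:
    def test_unit_ppsd_changes_nothing(self):
        s = LikelihoodState.initial((0, 1))
        s2 = update(s, 1.0, assignment_to_dark(0))
        assert s2.log_l == {0: 0.0, 1: 0.0}
        assert s2.cycles_elapsed == 1

    def test_multiply_divide_rule(self):
        # group 0 went bright -> dark with a 20% dilation
        s = update(LikelihoodState.initial((0, 1)), 1.2, assignment_to_dark(0))
        assert math.exp(s.log_l[0]) == pytest.approx(1.2)
        assert math.exp(s.log_l[1]) == pytest.approx(1 / 1.2)

    def test_two_cycle_recursion_grows_log_ratio(self):
        # alternating dilation on A-dark cycles and constriction on
        # A-bright cycles adds 2 log(1.1) to the log-ratio per cycle
        s = LikelihoodState.initial((0, 1))
        s = update(s, 1.1, assignment_to_dark(0))
        s = update(s, 1 / 1.1, assignment_to_dark(1))
        assert s.log_l[0] - s.log_l[1] == pytest.approx(4 * math.log(1.1))
        per_cycle = (s.log_l[0] - s.log_l[1]) / 2
        assert per_cycle == pytest.approx(2 * math.log(1.1))

    def test_invalid_ppsd_rejected(self):
        with pytest.raises(DecoderError):
            update(LikelihoodState.initial((0, 1)), 0.0, assignment_to_dark(0))


class TestDecide:
    def test_no_evidence_no_decision(self):
        assert decide(LikelihoodState.initial((0, 1))) is None

    def test_ratio_above_threshold_wins(self):
        s = LikelihoodState(log_l={0: math.log(1.4), 1: 0.0}, threshold_t=1.375)
        assert decide(s) == 0
        s = LikelihoodState(log_l={0: 0.0, 1: math.log(1.4)}, threshold_t=1.375)
        assert decide(s) == 1

    def test_exactly_at_threshold_continues(self):
        s = LikelihoodState(log_l={0: math.log(1.375), 1: 0.0},
                            threshold_t=1.375)
        assert decide(s) is None


def constant_growth_stream(ratio, n, start=1000.0):
    """PS stream whose PPSDs alternate ratio, 1/ratio (constant evidence)."""
    ps = start
    out = [measurement(ps)]
    for i in range(n):
        ps = ps * ratio if i % 2 == 0 else ps / ratio
        out.append(measurement(ps, i + 1))
    return out


class TestRunSelection:
    def test_two_item_decision_after_two_updates(self):
        # per-cycle ratio growth 1.21: 1.21 then 1.4641 > 1.375
        stream = constant_growth_stream(1.1, 4)
        tree = SelectionTreeState.start(("a", "b"))
        out = run_selection(stream, tree, DecoderConfig(threshold_t=1.375))
        assert out.n_cycles == 3  # baseline + 2 update cycles
        assert out.terminated_by == "threshold"
        assert out.n_eliminations == 1
        assert out.elapsed_time == pytest.approx(3 * 1.25)

    def test_selected_item_follows_evidence_direction(self):
        # cycle 1 has group 0 transitioning into dark (flip of the
        # initial bright assignment); dilation on that cycle favours 'a'
        stream = constant_growth_stream(1.1, 4)
        out = run_selection(stream, SelectionTreeState.start(("a", "b")),
                            DecoderConfig())
        assert out.selected_item == "a"

    def test_eight_items_with_oracle(self, oracle):
        out = oracle(tuple("abcdefgh"), "f")
        assert out.selected_item == "f"
        assert out.n_eliminations == 3
        assert out.terminated_by == "threshold"

    def test_all_missing_terminates_by_cap(self):
        stream = (PupilMeasurement.make_missing(i) for i in range(300))
        out = run_selection(stream, SelectionTreeState.start(("a", "b")),
                            DecoderConfig(max_cycles=10))
        assert out.terminated_by == "max_cycles"
        assert out.n_cycles == 10
        assert out.selected_item in ("a", "b")
        assert all(r is None for r, _ in out.trajectory)

    def test_exhausted_stream_is_an_error(self):
        stream = [measurement(1000.0), measurement(1001.0, 1)]
        with pytest.raises(DecoderError):
            run_selection(stream, SelectionTreeState.start(("a", "b")),
                          DecoderConfig())

    def test_first_cycle_is_baseline_only(self):
        stream = constant_growth_stream(1.1, 4)
        out = run_selection(stream, SelectionTreeState.start(("a", "b")),
                            DecoderConfig())
        assert out.trajectory[0] == (None, 0.0)

    def test_carry_ps_across_stages_updates_immediately(self, oracle):
        # with carry-over, each stage after the first needs one cycle
        out = oracle(tuple("abcdefgh"), "a")
        assert out.n_cycles == 4  # baseline + 1, then 1 + 1


class TestLogDomainEquivalence:
    """Log-domain updating matches the naive product-of-PPSD recursion."""

    @staticmethod
    def naive_run(ppsds, dark_groups, threshold):
        l = {0: 1.0, 1: 1.0}
        for i, (p, dark) in enumerate(zip(ppsds, dark_groups)):
            l[dark] *= p
            l[1 - dark] /= p
            ratio = l[0] / l[1]
            if ratio > threshold:
                return 0, i, l
            if ratio < 1 / threshold:
                return 1, i, l
        return None, len(ppsds) - 1, l

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_naive_products(self, data):
        n = data.draw(st.integers(1, 50))
        ppsds = data.draw(st.lists(
            st.floats(0.5, 2.0, allow_nan=False), min_size=n, max_size=n))
        darks = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        t = data.draw(st.sampled_from([1.1, 1.375, 1.5, 2.0]))

        state = LikelihoodState.initial((0, 1), threshold_t=t)
        log_decision = None
        for i, (p, dark) in enumerate(zip(ppsds, darks)):
            state = update(state, p, assignment_to_dark(dark))
            w = decide(state)
            if w is not None:
                log_decision = (w, i)
                break
        naive_w, naive_i, naive_l = self.naive_run(ppsds, darks, t)
        if naive_w is None:
            assert log_decision is None
        else:
            assert log_decision == (naive_w, naive_i)
        # compare accumulated likelihoods where no decision interrupted
        if naive_w is None and log_decision is None:
            for g in (0, 1):
                assert math.exp(state.log_l[g]) == pytest.approx(
                    naive_l[g], rel=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.6, 1.6), min_size=2, max_size=30),
           st.lists(st.integers(0, 1), min_size=30, max_size=30))
    def test_mirror_symmetry(self, ppsds, darks):
        """Inverting every PPSD (x -> 1/x) yields the mirrored decision:
        dilations become constrictions, so the opposite group wins.
        Equivalently, relabelling the groups mirrors the decision too."""
        darks = darks[:len(ppsds)]
        s1 = LikelihoodState.initial((0, 1))
        s2 = LikelihoodState.initial((0, 1))
        for p, dark in zip(ppsds, darks):
            s1 = update(s1, p, assignment_to_dark(dark))
            s2 = update(s2, 1 / p, assignment_to_dark(dark))
        assert s1.log_l[0] == pytest.approx(s2.log_l[1], abs=1e-9)
        assert s1.log_l[1] == pytest.approx(s2.log_l[0], abs=1e-9)
        d1, d2 = decide(s1), decide(s2)
        assert (d1 is None) == (d2 is None)
        if d1 is not None:
            assert d2 == 1 - d1


class TestClosedFormDecisionCount:
    @pytest.mark.parametrize("g", [0.05, 0.08, 0.13, 0.21, 0.34])
    @pytest.mark.parametrize("t", [1.375, 1.5])
    def test_cycles_to_decision(self, g, t):
        """Constant log-ratio gain g decides after ceil(log T / g) updates."""
        expected = math.ceil(math.log(t) / g)
        if math.isclose(expected * g, math.log(t)):  # strict inequality
            expected += 1
        stream = constant_growth_stream(math.exp(g / 2), expected + 5)
        out = run_selection(stream, SelectionTreeState.start(("a", "b")),
                            DecoderConfig(threshold_t=t))
        assert out.n_cycles - 1 == expected  # first cycle is the baseline
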