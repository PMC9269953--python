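"""Derived metrics on synthetic fixtures and the shared training run."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memconsol import (ParameterSet, classify_consolidation, detect_switch,
                       detect_waves, reduction, return_to_baseline_time,
                       segment_phases)
from memconsol.integrator import Trajectory
from memconsol.kernel import N_STATES, STATE_INDEX
from memconsol.metrics import NOT_RETURNED

HOUR = 3600.0
DAY = 86400.0


def _w_trajectory(times_s, w_values, basal_w=0.3):
    """Synthetic trajectory with only the W column meaningful."""
    states = np.zeros((len(times_s), N_STATES))
    states[:, STATE_INDEX["W"]] = w_values
    basal = np.zeros(N_STATES)
    basal[STATE_INDEX["W"]] = basal_w
    return Trajectory(times=np.asarray(times_s, dtype=float), states=states,
                      step=3.0, record_stride=100, basal=basal)


def _component_trajectory(name, times_s, values, basal_value):
    states = np.zeros((len(times_s), N_STATES))
    states[:, STATE_INDEX[name]] = values
    basal = np.zeros(N_STATES)
    basal[STATE_INDEX[name]] = basal_value
    return Trajectory(times=np.asarray(times_s, dtype=float), states=states,
                      step=3.0, record_stride=100, basal=basal)


class TestReduction:
    def test_intact(self):
        assert reduction(3.0, 3.0) == 0.0

    def test_abolished(self):
        assert reduction(3.0, 0.0) == 100.0

    def test_half(self):
        assert reduction(2.0, 1.0) == 50.0

    def test_invalid_control(self):
        with pytest.raises(ValueError):
            reduction(0.0, 1.0)

    @given(w=st.floats(1e-6, 1e3), delta=st.floats(0, 1e3))
    def test_identity_and_antitone(self, w, delta):
        assert reduction(w, w) == pytest.approx(0.0, abs=1e-9)
        assert reduction(w, w + delta) <= reduction(w, w) + 1e-9


class TestClassifyConsolidation:
    times = np.arange(0, 8 * DAY + 1, 300.0)

    def test_sustained_high(self):
        traj = _w_trajectory(self.times, np.full(len(self.times), 0.75))
        assert classify_consolidation(traj, basal_w=0.3)

    def test_transient_peak_decays(self):
        w = 0.3 + 0.36 * np.exp(-self.times / (6 * HOUR))
        assert w[0] >= 2.0 * 0.3  # passes threshold at the start only
        traj = _w_trajectory(self.times, w)
        assert not classify_consolidation(traj, basal_w=0.3)

    def test_threshold_is_strict(self):
        traj = _w_trajectory(self.times, np.full(len(self.times), 1.99 * 0.3))
        assert not classify_consolidation(traj, basal_w=0.3)

    def test_short_trajectory_rejected(self):
        t = np.arange(0, DAY, 300.0)
        traj = _w_trajectory(t, np.full(len(t), 1.0))
        with pytest.raises(ValueError):
            classify_consolidation(traj, basal_w=0.3)


class TestSegmentPhases:
    def test_monotone_curve_single_segment(self):
        onsets = np.arange(0, 10.0)
        red = np.linspace(100, 10, 10)
        ph = segment_phases(onsets, red)
        assert len(ph.segments) == 1
        assert ph.segments[0].direction == "decreasing"
        assert not ph.second_phase_present

    def test_three_phase_curve(self):
        onsets = np.arange(0, 49.0)
        red = np.concatenate([
            np.linspace(90, 40, 26),         # 0..25 decreasing
            np.linspace(42, 60, 10),         # 25..35 increasing
            np.linspace(58, 20, 13),         # 35..48 decreasing
        ])
        ph = segment_phases(onsets, red, day=7)
        dirs = [s.direction for s in ph.segments]
        assert dirs == ["decreasing", "increasing", "decreasing"]
        assert ph.second_phase_present and ph.reversal_present
        seg = ph.reversal_segment
        assert seg.start_h == 25.0 and seg.end_h == 35.0

    def test_plateau_between_decreasing_counts_for_day2(self):
        onsets = np.arange(0, 20.0)
        red = np.concatenate([np.linspace(80, 40, 8),
                              np.full(5, 40.0),
                              np.linspace(40, 10, 7)])
        ph2 = segment_phases(onsets, red, day=2)
        assert ph2.second_phase_present
        ph7 = segment_phases(onsets, red, day=7)
        assert not ph7.second_phase_present  # day 7 needs an increase
        assert ph7.reversal_present

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            segment_phases(np.arange(3.0), np.arange(3.0))

    @given(st.lists(st.floats(-50, 100), min_size=6, max_size=30, unique=True))
    def test_any_strictly_monotone_curve_is_one_segment(self, values):
        onsets = np.arange(len(values), dtype=float)
        curve = np.sort(np.asarray(values))[::-1]
        if np.min(-np.diff(curve)) < 0.3:  # keep slopes above plateau_eps
            curve = np.linspace(100, 0, len(values))
        ph = segment_phases(onsets, curve)
        assert len(ph.segments) == 1


class TestReturnToBaseline:
    times = np.arange(0, 4 * DAY + 1, 300.0)

    def test_constant_at_basal_returns_zero(self):
        traj = _component_trajectory("pCaMKII", self.times,
                                     np.full(len(self.times), 0.006), 0.006)
        assert return_to_baseline_time(traj, "pCaMKII") == 0.0

    def test_exponential_return(self):
        basal = 0.006
        x = basal * (1 + 2.0 * np.exp(-self.times / (10 * HOUR)))
        traj = _component_trajectory("pCaMKII", self.times, x, basal)
        got = return_to_baseline_time(traj, "pCaMKII", rel_tol=0.05)
        assert got == pytest.approx(10 * np.log(2 / 0.05), rel=0.05)  # hours

    def test_never_returning(self):
        x = np.full(len(self.times), 0.02)
        traj = _component_trajectory("pCaMKII", self.times, x, 0.006)
        assert return_to_baseline_time(traj, "pCaMKII") == NOT_RETURNED


class TestDetectWaves:
    times = np.arange(0, 2 * DAY, 300.0)

    def test_monotone_decay_single_peak_at_start(self):
        x = 0.07 + 0.5 * np.exp(-self.times / (2 * HOUR))
        traj = _component_trajectory("BDNF", self.times, x, 0.07)
        peaks = detect_waves(traj, "BDNF")
        assert len(peaks) == 1 and peaks[0] == 0.0

    def test_two_waves(self):
        t = self.times
        x = (0.07 + 0.5 * np.exp(-t / HOUR)
             + 0.05 * np.exp(-((t - 10 * HOUR) / (3 * HOUR)) ** 2))
        traj = _component_trajectory("BDNF", t, x, 0.07)
        peaks = detect_waves(traj, "BDNF")
        assert len(peaks) == 2
        assert peaks[1] == pytest.approx(10.0, abs=0.5)


class TestDetectSwitch:
    def _state(self, bdnf, pck):
        y = np.zeros(N_STATES)
        y[STATE_INDEX["BDNF"]] = bdnf
        y[STATE_INDEX["pCaMKII"]] = pck
        return y

    def test_basal_state_not_switched(self):
        b = self._state(0.07, 0.006)
        assert not detect_switch(b, b)

    def test_elevated_state_switched(self):
        b = self._state(0.07, 0.006)
        hi = self._state(1.0, 0.07)
        assert detect_switch(hi, b)

    @given(fb=st.floats(1.0, 100.0), fp=st.floats(1.0, 100.0))
    def test_monotone_in_state(self, fb, fp):
        b = self._state(0.07, 0.006)
        hi = self._state(0.75, 0.065)
        more = self._state(0.75 * fb, 0.065 * fp)
        if detect_switch(hi, b):
            assert detect_switch(more, b)
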