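"""Derived quantities: reductions, consolidation, resistance-curve phases,
baseline-return and wave timing, and bistable-switch detection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .integrator import Trajectory
from .kernel import STATE_INDEX

__all__ = [
    "PhaseSegment", "PhaseStructure", "reduction", "classify_consolidation",
    "segment_phases", "return_to_baseline_time", "detect_waves", "detect_switch",
    "NOT_RETURNED",
]

NOT_RETURNED = float("inf")  # sentinel for return_to_baseline_time

DAY_S = 86400.0
HOUR_S = 3600.0


@dataclass(frozen=True)
class PhaseSegment:
    start_h: float
    end_h: float
    direction: str  # "decreasing" | "plateau" | "increasing"


@dataclass(frozen=True)
class PhaseStructure:
    """Monotone segments of a resistance curve, in onset order.

    ``second_phase_present`` flags a resistance reversal: an increasing (or,
    for the day-2 curve, plateau) segment strictly between two decreasing
    segments.
    """

    segments: tuple[PhaseSegment, ...]
    second_phase_present: bool
    reversal_present: bool = False

    @property
    def increasing_segments(self) -> tuple[PhaseSegment, ...]:
        return tuple(s for s in self.segments if s.direction == "increasing")

    @property
    def reversal_segment(self) -> PhaseSegment | None:
        """The non-decreasing segment strictly between two decreasing ones
        (the second resistance phase), if any; increasing preferred over
        plateau when both exist."""
        best = None
        for j in range(1, len(self.segments) - 1):
            s = self.segments[j]
            if s.direction == "decreasing":
                continue
            if (any(t.direction == "decreasing" for t in self.segments[:j])
                    and any(t.direction == "decreasing"
                            for t in self.segments[j + 1:])):
                if best is None or (s.direction == "increasing"
                                    and best.direction != "increasing"):
                    best = s
        return best


def reduction(w_ctrl: float, w_dis: float) -> float:
    """Percent reduction of the disrupted W relative to its paired control.

    100 means W was abolished, 0 means W was untouched; a disrupted run that
    overshoots its control gives a negative value (reported raw).
    """
    if w_ctrl <= 0:
        raise ValueError(f"control W must be > 0, got {w_ctrl}")
    return 100.0 * (1.0 - w_dis / w_ctrl)


def classify_consolidation(traj: Trajectory, basal_w: float,
                           threshold: float = 2.0) -> bool:
    """True if W stays at/above ``threshold x basal`` continuously over a
    window of at least 48 h that includes day 7 post-training."""
    if traj.duration_s < 7 * DAY_S:
        raise ValueError("trajectory must span at least 7 days")
    w = traj.component("W")
    above = w >= threshold * basal_w
    i7 = int(np.argmin(np.abs(traj.times - 7 * DAY_S)))
    if not above[i7]:
        return False
    lo = i7
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = i7
    while hi < len(above) - 1 and above[hi + 1]:
        hi += 1
    return traj.times[hi] - traj.times[lo] >= 48 * HOUR_S


def segment_phases(onsets_h: np.ndarray, reductions: np.ndarray,
                   plateau_eps: float = 0.2, day: int = 7) -> PhaseStructure:
    """Segment a reduction-vs-onset curve into monotone phases.

    Finite-difference slopes below ``plateau_eps`` %/h count as plateau;
    adjacent steps with the same direction are merged.  The second resistance
    phase is an increasing (day-7) or plateau (day-2) segment strictly
    between two decreasing segments.
    """
    onsets_h = np.asarray(onsets_h, dtype=float)
    reductions = np.asarray(reductions, dtype=float)
    if len(onsets_h) < 5:
        raise ValueError("need at least 5 onset points to segment phases")
    if len(onsets_h) != len(reductions):
        raise ValueError("onsets and reductions must have equal length")
    slopes = np.diff(reductions) / np.diff(onsets_h)
    dirs = np.where(np.abs(slopes) < plateau_eps, "plateau",
                    np.where(slopes > 0, "increasing", "decreasing"))
    segments: list[PhaseSegment] = []
    start = onsets_h[0]
    for k in range(1, len(dirs)):
        if dirs[k] != dirs[k - 1]:
            segments.append(PhaseSegment(start, onsets_h[k], str(dirs[k - 1])))
            start = onsets_h[k]
    segments.append(PhaseSegment(start, onsets_h[-1], str(dirs[-1])))

    def _between(middle_dirs) -> bool:
        return any(
            segments[i].direction == "decreasing"
            and segments[j].direction in middle_dirs
            and segments[k].direction == "decreasing"
            for i in range(len(segments))
            for j in range(i + 1, len(segments))
            for k in range(j + 1, len(segments))
        )

    middle = ("increasing",) if day == 7 else ("plateau",)
    return PhaseStructure(tuple(segments), _between(middle),
                          reversal_present=_between(("increasing", "plateau")))


def return_to_baseline_time(traj: Trajectory, component: str,
                            rel_tol: float = 0.05,
                            persistence_h: float = 6.0) -> float:
    """Hours post-stimulus until a component settles back to its basal level.

    Earliest time after the component's post-stimulus global maximum at which
    the trajectory stays within ``rel_tol`` (relative) of basal for at least
    ``persistence_h`` hours; ``NOT_RETURNED`` (inf) if it never does.
    """
    if traj.duration_s < 3 * DAY_S:
        raise ValueError("trajectory must span at least 3 days")
    if traj.basal is None:
        raise ValueError("trajectory carries no basal state")
    x = traj.component(component)
    basal = traj.basal_value(component)
    in_band = np.abs(x - basal) <= rel_tol * abs(basal)
    if in_band.all():
        return 0.0
    imax = int(np.argmax(x))
    n_persist = max(1, int(round(persistence_h * HOUR_S
                                 / (traj.step * traj.record_stride))))
    for i in range(imax, len(x)):
        if not in_band[i]:
            continue
        j = i
        while j < len(x) - 1 and in_band[j + 1]:
            j += 1
        if (traj.times[j] - traj.times[i] >= persistence_h * HOUR_S
                or (j == len(x) - 1 and j - i + 1 >= n_persist)):
            return float(traj.times[i] / HOUR_S)
        # skip past this too-short excursion into the band
    return NOT_RETURNED


def detect_waves(traj: Trajectory, component: str,
                 min_prominence: float = 0.1,
                 window_h: float | None = None) -> list[float]:
    """Times (h) of post-stimulus waves of a component.

    Local maxima exceeding basal by at least ``min_prominence x basal`` and
    separated by a trough of comparable prominence; a maximum at the very
    start of the record counts (a monotone decay has its peak there).
    """
    x = traj.component(component).copy()
    t = traj.times
    if window_h is not None:
        mask = t - t[0] <= window_h * HOUR_S
        x, t = x[mask], t[mask]
    basal = traj.basal_value(component) if traj.basal is not None else x[0]
    height = basal * (1.0 + min_prominence)
    prom = basal * min_prominence
    idx, _ = scipy.signal.find_peaks(x, height=height, prominence=prom)
    peaks = list(idx)
    if len(x) > 1 and x[0] > x[1] and x[0] >= height and 0 not in peaks:
        peaks = [0] + peaks
    return [float(t[i] / HOUR_S) for i in peaks]


def detect_switch(state_48h: np.ndarray, basal: np.ndarray,
                  factor: float = 4.0) -> bool:
    """Classify a post-training state as switched to the elevated attractor.

    True iff both released BDNF and pCaMKII stand at least ``factor`` times
    above their pre-training basal levels.  In the settled elevated state the
    two attractors are separated by ~10-15x in BDNF and ~6-7x in pCaMKII, so
    any factor in roughly [2, 5] gives the same classification; 4 sits in the
    middle of that band.
    """
    ib, ip = STATE_INDEX["BDNF"], STATE_INDEX["pCaMKII"]
    return bool(state_48h[ib] >= factor * basal[ib]
                and state_48h[ip] >= factor * basal[ip])
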