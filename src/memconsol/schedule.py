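"""Piecewise-constant exogenous signals: training pulses and disruptors.

A :class:`Schedule` holds training-pulse onsets and disruptor windows and can
evaluate, at any time, the five signals the model consumes:

* ``stim(t)`` — training drive (mM/s), a square pulse per training onset;
* ``ANI(t)`` — protein-synthesis inhibition fraction in [0, 1];
* activity factors ``a_BDNF``, ``a_CEBP``, ``a_MeCP2`` in (0, 1] implementing
  antisense-ODN style suppression of a species' regulatory activity.

Signals are held constant within an integration step, evaluated at the step's
start; window edges must therefore sit on the step grid (hour-valued onsets
are exact multiples of the 3-s step, so the published protocols never round).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError
from .params import ParameterSet

__all__ = ["Schedule", "DisruptorWindow", "make_schedule", "DISRUPTOR_KINDS"]

DISRUPTOR_KINDS = ("PSI", "antiBDNF", "antiCEBP", "antiMeCP2")


@dataclass(frozen=True)
class DisruptorWindow:
    onset_s: float
    duration_s: float
    kind: str
    efficacy: float

    def __post_init__(self) -> None:
        if self.kind not in DISRUPTOR_KINDS:
            raise ValueError(
                f"unknown disruptor kind {self.kind!r}; expected one of {DISRUPTOR_KINDS}")
        if self.duration_s <= 0:
            raise ValueError(f"disruptor duration must be > 0, got {self.duration_s}")
        if not 0.0 <= self.efficacy <= 1.0:
            raise ValueError(f"efficacy must lie in [0, 1], got {self.efficacy}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Schedule:
    """Training onsets plus disruptor windows, with pulse shape parameters."""

    training_onsets: tuple[float, ...] = ()
    disruptors: tuple[DisruptorWindow, ...] = ()
    stim_amplitude: float = 0.03
    stim_duration: float = 60.0

    def __post_init__(self) -> None:
        if self.stim_amplitude < 0:
            raise ValueError("stim_amplitude must be >= 0")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")

    # -- point evaluation ---------------------------------------------------
    def stim(self, t: float) -> float:
        for on in self.training_onsets:
            if on <= t < on + self.stim_duration:
                return self.stim_amplitude
        return 0.0

    def ani(self, t: float) -> float:
        level = 0.0
        for w in self.disruptors:
            if w.kind == "PSI" and w.onset_s <= t < w.end_s:
                level = max(level, w.efficacy)
        return level

    def activity(self, t: float, kind: str) -> float:
        factor = 1.0
        for w in self.disruptors:
            if w.kind == kind and w.onset_s <= t < w.end_s:
                factor = min(factor, 1.0 - w.efficacy)
        return factor

    def signals_at(self, t: float) -> tuple[float, float, float, float, float]:
        """(stim, ANI, a_BDNF, a_CEBP, a_MeCP2) at time ``t``."""
        return (self.stim(t), self.ani(t),
                self.activity(t, "antiBDNF"),
                self.activity(t, "antiCEBP"),
                self.activity(t, "antiMeCP2"))

    # -- grid evaluation ----------------------------------------------------
    def _edges(self) -> list[float]:
        edges: list[float] = []
        for on in self.training_onsets:
            edges += [on, on + self.stim_duration]
        for w in self.disruptors:
            edges += [w.onset_s, w.end_s]
        return edges

    def check_alignment(self, step: float) -> None:
        """Raise :class:`AlignmentError` if any window edge is off-grid."""
        for e in self._edges():
            r = e / step
            if abs(r - round(r)) > 1e-9:
                raise AlignmentError(
                    f"schedule edge at {e} s is not a multiple of the {step}-s step")

    def per_step_arrays(self, t0: float, n_steps: int, step: float):
        """Signal value per step, evaluated at each step's start time."""
        t = t0 + step * np.arange(n_steps)
        stim = np.zeros(n_steps)
        for on in self.training_onsets:
            stim[(t >= on) & (t < on + self.stim_duration)] = self.stim_amplitude
        ani = np.zeros(n_steps)
        act = {k: np.ones(n_steps) for k in ("antiBDNF", "antiCEBP", "antiMeCP2")}
        for w in self.disruptors:
            mask = (t >= w.onset_s) & (t < w.end_s)
            if w.kind == "PSI":
                ani[mask] = np.maximum(ani[mask], w.efficacy)
            else:
                act[w.kind][mask] = np.minimum(act[w.kind][mask], 1.0 - w.efficacy)
        return stim, ani, act["antiBDNF"], act["antiCEBP"], act["antiMeCP2"]


def make_schedule(train_at: float = 0.0,
                  disruptor: str | None = None,
                  onset_after_training: float = 0.0,
                  params: ParameterSet | None = None) -> Schedule:
    """Standard one-trial protocol: a 1-min training pulse, optionally followed
    by one 6-h disruptor window starting ``onset_after_training`` seconds after
    the pulse.

    ``disruptor`` is one of ``PSI`` (anisomycin-style synthesis inhibition at
    fraction ``params.ani_level``), ``antiBDNF``, ``antiCEBP`` or
    ``antiMeCP2`` (suppression of the species' regulatory activity by the
    same fraction, 0.8 by default), or None for an undisturbed run.
    """
    params = params or ParameterSet()
    if onset_after_training < 0:
        raise ValueError("disruptor onset must be >= 0")
    windows: tuple[DisruptorWindow, ...] = ()
    if disruptor is not None:
        if disruptor not in DISRUPTOR_KINDS:
            raise ValueError(
                f"unknown disruptor kind {disruptor!r}; expected one of {DISRUPTOR_KINDS}")
        efficacy = params.ani_level
        windows = (DisruptorWindow(train_at + onset_after_training,
                                   params.disruptor_duration, disruptor, efficacy),)
    return Schedule(training_onsets=(train_at,), disruptors=windows,
                    stim_amplitude=params.stim_amplitude,
                    stim_duration=params.stim_duration)
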