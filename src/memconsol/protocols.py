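"""The simulated experiments: training, disruption, resistance scans,
infantile-parameter scans, bistability scans, and parameter sensitivity.

Every reduction is computed against a control run with the identical
parameter set and variant (paired-run discipline), and every scan cell
re-equilibrates to its own basal state; percentages always refer to the
cell's own basal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrator import DEFAULT_RECORD_STRIDE, DEFAULT_STEP, Trajectory, \
    equilibrate, integrate
from .kernel import STATE_INDEX
from .metrics import PhaseStructure, detect_switch, reduction, segment_phases
from .model import ModelVariant, STANDARD, frozen_from_basal
from .params import ParameterSet
from .schedule import DISRUPTOR_KINDS, make_schedule

__all__ = [
    "ResistanceCurve", "ScanGrid", "DisruptionResult", "SensitivityResult",
    "run_training", "run_disruption", "resistance_scan", "infantile_scan",
    "bistability_scan", "sensitivity_scan",
    "DEFAULT_ONSETS_H", "INFANTILE_CREB_LEVELS", "INFANTILE_CAMKII_LEVELS",
    "BISTABILITY_CREB_LEVELS", "BISTABILITY_CAMKII_LEVELS",
]

DAY_S = 86400.0
HOUR_S = 3600.0

DEFAULT_ONSETS_H = tuple(range(0, 49))  # 0..48 h, 1-h resolution

# published scan grids: CREB basal phosphorylation 100..300% by 20%,
# CaMKII 100..50% by 10% (weight scan) or 100..10% by 10% (bistability scan)
INFANTILE_CREB_LEVELS = tuple(round(1.0 + 0.2 * k, 2) for k in range(11))
INFANTILE_CAMKII_LEVELS = tuple(round(1.0 - 0.1 * k, 2) for k in range(6))
BISTABILITY_CREB_LEVELS = INFANTILE_CREB_LEVELS
BISTABILITY_CAMKII_LEVELS = tuple(round(0.1 + 0.1 * k, 2) for k in range(10))


@dataclass(frozen=True)
class ResistanceCurve:
    """Reduction of W versus disruptor onset, at day 2 and day 7."""

    kind: str
    onsets_h: np.ndarray
    reduction_day2_pct: np.ndarray
    reduction_day7_pct: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.onsets_h) > 0):
            raise ValueError("onsets must be strictly increasing")
        for r in (self.reduction_day2_pct, self.reduction_day7_pct):
            if np.any(np.asarray(r) > 100.0 + 1e-9):
                raise ValueError("a reduction cannot exceed 100%")

    def phases(self, day: int = 7, plateau_eps: float = 0.2) -> PhaseStructure:
        r = self.reduction_day7_pct if day == 7 else self.reduction_day2_pct
        return segment_phases(self.onsets_h, r, plateau_eps=plateau_eps, day=day)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "onset_h": self.onsets_h,
            "reduction_day2_pct": self.reduction_day2_pct,
            "reduction_day7_pct": self.reduction_day7_pct,
        })


@dataclass(frozen=True)
class ScanGrid:
    """Long-form 2-D parameter scan result."""

    axis1_name: str
    axis1_levels: tuple[float, ...]
    axis2_name: str
    axis2_levels: tuple[float, ...]
    values: np.ndarray  # shape (len(axis1), len(axis2))
    value_name: str
    protocol: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.axis1_levels), len(self.axis2_levels)):
            raise ValueError("grid shape does not match level lists")

    def to_frame(self):
        import pandas as pd

        rows = [
            (a1, a2, self.values[i, j])
            for i, a1 in enumerate(self.axis1_levels)
            for j, a2 in enumerate(self.axis2_levels)
        ]
        return pd.DataFrame(rows, columns=[self.axis1_name, self.axis2_name,
                                           self.value_name])


@dataclass(frozen=True)
class DisruptionResult:
    trajectory: Trajectory           # the disrupted run
    control: Trajectory              # paired control (same params/variant)
    onset_h: float
    kind: str
    reductions_pct: dict[int, float]  # eval day -> % reduction of W


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    factors: tuple[float, ...]
    curves: dict[float, ResistanceCurve]
    phases_day7: dict[float, PhaseStructure]

    def second_phase_present(self, factor: float) -> bool:
        return self.phases_day7[factor].second_phase_present


def _prepare(params: ParameterSet, variant: ModelVariant):
    """Basal state, gate-recalibrated parameters, and frozen variant values.

    The synaptic-weight gate (the basal tag*capture product below which the
    weight is not driven) cannot sit below the parameter set's *own*
    equilibrated resting product: a scan cell with, say, elevated basal pCREB
    has a higher resting capture-protein level that must not drive W by
    itself, so there the gate is raised to the cell's rest product.  Cells
    resting below the calibrated threshold keep it unchanged.  The gate is
    suppressed during equilibration (the weight module is inert at rest
    either way) and re-referenced afterwards.
    """
    ungated = params.replace(Tag_basal=1e9)
    frozen = None
    if variant.any_loop_block:
        basal_std = equilibrate(ungated, STANDARD)
        frozen = frozen_from_basal(basal_std, params)
    basal = equilibrate(ungated, variant, frozen=frozen)
    rest_product = float(basal[STATE_INDEX["Tag"]]
                         * basal[STATE_INDEX["GPROD"]])
    gated = params
    if rest_product > params.Tag_basal * params.GPROD_basal:
        gated = params.replace(Tag_basal=float(basal[STATE_INDEX["Tag"]]),
                               GPROD_basal=float(basal[STATE_INDEX["GPROD"]]))
    return basal, gated, frozen


def run_training(params: ParameterSet | None = None,
                 variant: ModelVariant = STANDARD,
                 horizon_days: float = 9.0,
                 record_stride: int = DEFAULT_RECORD_STRIDE,
                 step: float = DEFAULT_STEP) -> Trajectory:
    """Equilibrate, apply the 1-min training pulse at t = 0, and integrate.

    The returned trajectory carries the basal state, so metrics can express W
    as percent of its pre-training level.
    """
    params = params or ParameterSet()
    basal, gated, frozen = _prepare(params, variant)
    sched = make_schedule(0.0, None, 0.0, gated)
    return integrate(basal, 0.0, horizon_days * DAY_S, gated, schedule=sched,
                     variant=variant, step=step, record_stride=record_stride,
                     frozen=frozen, basal=basal)


def run_disruption(params: ParameterSet | None = None,
                   variant: ModelVariant = STANDARD,
                   kind: str = "PSI",
                   onset_h: float = 0.0,
                   eval_days: tuple[int, ...] = (2, 7),
                   record_stride: int = DEFAULT_RECORD_STRIDE,
                   step: float = DEFAULT_STEP,
                   _prepared=None) -> DisruptionResult:
    """Paired training runs with and without a 6-h disruptor at ``onset_h``
    hours post-training; reports the reduction of W at each evaluation day."""
    params = params or ParameterSet()
    if kind not in DISRUPTOR_KINDS:
        raise ValueError(f"unknown disruptor kind {kind!r}")
    if not 0.0 <= onset_h <= 48.0:
        raise ValueError(f"onset must lie in [0, 48] h, got {onset_h}")
    horizon = max(eval_days) * DAY_S
    if _prepared is None:
        basal, gated, frozen = _prepare(params, variant)
        sched0 = make_schedule(0.0, None, 0.0, gated)
        ctrl = integrate(basal, 0.0, horizon, gated, schedule=sched0,
                         variant=variant, step=step,
                         record_stride=record_stride, frozen=frozen, basal=basal)
    else:
        basal, gated, frozen, ctrl = _prepared
    sched = make_schedule(0.0, kind, onset_h * HOUR_S, gated)
    dis = integrate(basal, 0.0, horizon, gated, schedule=sched,
                    variant=variant, step=step, record_stride=record_stride,
                    frozen=frozen, basal=basal)
    reductions = {
        d: reduction(ctrl.value_at(d * DAY_S, "W"), dis.value_at(d * DAY_S, "W"))
        for d in eval_days
    }
    return DisruptionResult(trajectory=dis, control=ctrl, onset_h=onset_h,
                            kind=kind, reductions_pct=reductions)


def resistance_scan(params: ParameterSet | None = None,
                    variant: ModelVariant = STANDARD,
                    kind: str = "PSI",
                    onsets_h=DEFAULT_ONSETS_H,
                    record_stride: int = DEFAULT_RECORD_STRIDE,
                    step: float = DEFAULT_STEP) -> ResistanceCurve:
    """Day-2/day-7 reduction of W for a disruptor initiated at each onset.

    The control run (and the equilibration) is shared across onsets; each
    onset adds a single disrupted run.
    """
    params = params or ParameterSet()
    onsets = np.asarray(sorted(onsets_h), dtype=float)
    if onsets[0] < 0 or onsets[-1] > 48:
        raise ValueError("onsets must lie within [0, 48] h")
    basal, gated, frozen = _prepare(params, variant)
    sched0 = make_schedule(0.0, None, 0.0, gated)
    ctrl = integrate(basal, 0.0, 7 * DAY_S, gated, schedule=sched0,
                     variant=variant, step=step, record_stride=record_stride,
                     frozen=frozen, basal=basal)
    prepared = (basal, gated, frozen, ctrl)
    r2, r7 = [], []
    for onset in onsets:
        res = run_disruption(params, variant, kind, float(onset),
                             eval_days=(2, 7), record_stride=record_stride,
                             step=step, _prepared=prepared)
        r2.append(res.reductions_pct[2])
        r7.append(res.reductions_pct[7])
    return ResistanceCurve(kind=kind, onsets_h=onsets,
                           reduction_day2_pct=np.array(r2),
                           reduction_day7_pct=np.array(r7))


def infantile_scan(params: ParameterSet | None = None,
                   creb_levels=INFANTILE_CREB_LEVELS,
                   camkii_levels=INFANTILE_CAMKII_LEVELS,
                   record_stride: int = DEFAULT_RECORD_STRIDE,
                   step: float = DEFAULT_STEP) -> ScanGrid:
    """Day-7 W (percent of each cell's own basal W) over a grid of scaled
    basal CREB and CaMKII phosphorylation rates, emulating the infant
    hippocampus (higher basal pCREB, lower basal pCaMKII).

    Each cell re-equilibrates, so elevated basal repressor-complex binding
    emerges at reduced CaMKII levels before the stimulus is applied.
    """
    params = params or ParameterSet()
    values = np.empty((len(creb_levels), len(camkii_levels)))
    for i, fc in enumerate(creb_levels):
        for j, fk in enumerate(camkii_levels):
            cell = params.scaled(k_basalp_creb=fc, k_basalp_CaMKII=fk)
            traj = run_training(cell, STANDARD, horizon_days=7.0,
                                record_stride=record_stride, step=step)
            w7 = traj.value_at(7 * DAY_S, "W")
            values[i, j] = 100.0 * w7 / traj.basal_value("W")
    return ScanGrid(axis1_name="creb_level", axis1_levels=tuple(creb_levels),
                    axis2_name="camkii_level", axis2_levels=tuple(camkii_levels),
                    values=values, value_name="w_day7_pct_of_basal",
                    protocol="infantile_scan")


def bistability_scan(params: ParameterSet | None = None,
                     creb_levels=BISTABILITY_CREB_LEVELS,
                     camkii_levels=BISTABILITY_CAMKII_LEVELS,
                     record_stride: int = DEFAULT_RECORD_STRIDE,
                     step: float = DEFAULT_STEP,
                     switch_factor: float = 4.0,
                     horizon_days: float = 10.0) -> ScanGrid:
    """Switch/blocked classification after training in the variant with both
    MeCP2 effects removed (the bistability-capable model).

    The default ten-day horizon classifies the settled attractor: the
    transit to the elevated state takes three to four simulated days in this
    model, so a 48-h snapshot would still be mid-flight.  In the settled
    state the attractors are separated by ~10-15x in BDNF and ~6-7x in
    pCaMKII, so the call is insensitive to the factor within roughly [2, 5].
    """
    params = params or ParameterSet()
    variant = ModelVariant(no_mecp2_effects=True)
    values = np.empty((len(creb_levels), len(camkii_levels)))
    for i, fc in enumerate(creb_levels):
        for j, fk in enumerate(camkii_levels):
            cell = params.scaled(k_basalp_creb=fc, k_basalp_CaMKII=fk)
            basal, gated, _ = _prepare(cell, variant)
            sched = make_schedule(0.0, None, 0.0, gated)
            traj = integrate(basal, 0.0, horizon_days * DAY_S, gated,
                             schedule=sched, variant=variant, step=step,
                             record_stride=record_stride, basal=basal)
            values[i, j] = float(detect_switch(traj.states[-1], basal,
                                               factor=switch_factor))
    return ScanGrid(axis1_name="creb_level", axis1_levels=tuple(creb_levels),
                    axis2_name="camkii_level", axis2_levels=tuple(camkii_levels),
                    values=values, value_name="switched",
                    protocol="bistability_scan")


def sensitivity_scan(params: ParameterSet | None = None,
                     target_param: str = "tau_comp",
                     factors=(0.3, 1.0, 3.0),
                     kind: str = "PSI",
                     onsets_h=DEFAULT_ONSETS_H,
                     variant: ModelVariant = STANDARD,
                     record_stride: int = DEFAULT_RECORD_STRIDE,
                     step: float = DEFAULT_STEP,
                     plateau_eps: float = 0.2) -> SensitivityResult:
    """Resistance scans with one parameter rescaled, plus day-7 phase
    structure per factor — probes which kinetics shape the multi-phase
    resistance profile."""
    params = params or ParameterSet()
    if target_param not in ParameterSet.names():
        raise KeyError(f"unknown parameter {target_param!r}")
    curves: dict[float, ResistanceCurve] = {}
    phases: dict[float, PhaseStructure] = {}
    for f in factors:
        scaled = params.scaled(**{target_param: f})
        curve = resistance_scan(scaled, variant, kind, onsets_h,
                                record_stride=record_stride, step=step)
        curves[float(f)] = curve
        phases[float(f)] = curve.phases(day=7, plateau_eps=plateau_eps)
    return SensitivityResult(parameter=target_param,
                             factors=tuple(float(f) for f in factors),
                             curves=curves, phases_day7=phases)
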