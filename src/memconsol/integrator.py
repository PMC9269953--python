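"""Fixed-step fourth-order Runge–Kutta integration and basal equilibration.

The model is integrated with classic RK4 at a 3-s step (halving the step
changes the day-7 synaptic weight by well under 0.1%).  Exogenous signals are
piecewise constant, held fixed within a step and shared by the four stages.

``equilibrate`` relaxes the model from a documented cold start to its basal
fixed point: it integrates with all signals at rest for at least two simulated
days and until the motion is negligible, then polishes the state with a Newton
solve of the right-hand side so the residual reaches the requested tolerance
(far below what pure relaxation could achieve in reasonable simulated time,
given the 8.7-day time constant of the slowest variable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from . import kernel
from .errors import EquilibrationError, NumericError
from .kernel import N_STATES, STATE_INDEX, STATE_NAMES
from .model import ModelVariant, STANDARD, frozen_from_basal
from .params import ParameterSet
from .schedule import Schedule, make_schedule  # re-exported; part of this layer's API

__all__ = ["Trajectory", "integrate", "equilibrate", "rk4_step", "make_schedule",
            "DEFAULT_STEP", "COLD_START"]

DEFAULT_STEP = 3.0          # s
DEFAULT_RECORD_STRIDE = 100  # record every 100th step = 5-min resolution

# Cold start for equilibration: the tabulated basal calibration (promoter
# occupancies at 1 mM, Tag at 0.1, GPROD at 0.12) completed with coarse
# analytic estimates of the remaining rest concentrations.  The start must
# sit in the basin of the physiological rest state: three sub-systems (the
# promoter occupancies, the W/P/PP weight module, and the BDNF loop itself in
# the variant without MeCP2 effects) are multistable even at rest, so a
# near-zero start would relax onto a non-physiological branch.  The weight
# module's (W, P, PP) = (0.3, 0.7, 0.08) is the exact positive rest point of
# its production/precursor balance.
COLD_START = {
    "BDNF": 0.07, "bdnf_m": 3.4e-3, "pCREB": 6.9e-3, "CEBP": 0.078,
    "E_MeCP2": 0.09, "E_comp": 0.0, "pCaMKII": 6.4e-3,
    "B_Sin3a": 1.0, "B_HDAC2": 1.0, "B_MeCP2": 1.0,
    "Tag": 0.1, "TF1": 0.026, "TF2": 0.031, "GPROD": 0.12,
    "W": 0.3, "P": 0.7, "PP": 0.08,
}

_EMPTY_SCHEDULE = Schedule()
_NO_FROZEN = np.zeros(3)

# characteristic relaxation times (s) per state, used only to equalise the
# scales of the fixed-point residual for the Newton polish
_RES_SCALE_TAU = {
    "BDNF": 1e3, "bdnf_m": 1e4, "pCREB": 1e4, "CEBP": 2e5, "E_MeCP2": 1.44e4,
    "E_comp": 5.4e6, "pCaMKII": 9e3, "B_Sin3a": 5e4, "B_HDAC2": 1.25e5,
    "B_MeCP2": 1e4, "Tag": 2e2, "TF1": 3e4, "TF2": 1.6e4, "GPROD": 4e4,
    "W": 3e5, "P": 3e5, "PP": 7.5e5,
}
_RES_SCALE = np.array([_RES_SCALE_TAU[n] for n in STATE_NAMES])


@dataclass(frozen=True)
class Trajectory:
    """Recorded states on a uniform time grid (plus the final step).

    ``states`` has one row per recorded time, columns in ``STATE_NAMES``
    order.  ``basal`` optionally carries the pre-stimulus fixed point the run
    started from, used by metrics that normalise to rest.
    """

    times: np.ndarray
    states: np.ndarray
    step: float
    record_stride: int
    variant: ModelVariant = STANDARD
    basal: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def component(self, name: str) -> np.ndarray:
        return self.states[:, STATE_INDEX[name]]

    def at_time(self, t_s: float) -> np.ndarray:
        """State at the recorded time nearest to ``t_s`` (must be on-grid)."""
        i = int(np.argmin(np.abs(self.times - t_s)))
        if abs(self.times[i] - t_s) > self.step * self.record_stride:
            raise ValueError(f"time {t_s} s is outside the recorded range")
        return self.states[i]

    def value_at(self, t_s: float, name: str) -> float:
        return float(self.at_time(t_s)[STATE_INDEX[name]])

    def basal_value(self, name: str) -> float:
        if self.basal is None:
            raise ValueError("trajectory carries no basal state")
        return float(self.basal[STATE_INDEX[name]])

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.states, columns=list(STATE_NAMES),
                            index=pd.Index(self.times, name="time_s"))


def rk4_step(f, t: float, y, h: float):
    """One classic RK4 step for an arbitrary ODE ``dy/dt = f(t, y)``.

    Generic scalar/vector test hook, independent of the compiled model loop;
    used to verify the integration scheme itself (quartic local accuracy).
    """
    k1 = f(t, y)
    k2 = f(t + h / 2.0, y + h / 2.0 * k1)
    k3 = f(t + h / 2.0, y + h / 2.0 * k2)
    k4 = f(t + h, y + h * k3)
    return y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(state0: np.ndarray, t0: float, t1: float,
              params: ParameterSet, schedule: Schedule | None = None,
              variant: ModelVariant = STANDARD,
              step: float = DEFAULT_STEP,
              record_stride: int = DEFAULT_RECORD_STRIDE,
              frozen: np.ndarray | None = None,
              basal: np.ndarray | None = None) -> Trajectory:
    """Integrate the model from ``t0`` to ``t1`` (inclusive of the final step).

    The number of steps is ``round((t1 - t0)/step)``; the schedule's window
    edges must sit on the step grid.  Raises :class:`NumericError` with the
    failing time and component on a non-finite or substantially negative
    state.
    """
    if t1 <= t0:
        raise ValueError(f"t1 ({t1}) must exceed t0 ({t0})")
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if record_stride < 1:
        raise ValueError("record_stride must be >= 1")
    schedule = schedule or _EMPTY_SCHEDULE
    schedule.check_alignment(step)
    if variant.any_loop_block and frozen is None:
        raise ValueError("a loop-blocking variant requires frozen basal values")
    frozen = _NO_FROZEN if frozen is None else np.asarray(frozen, dtype=float)

    y0 = np.ascontiguousarray(state0, dtype=float)
    if y0.shape != (N_STATES,):
        raise ValueError(f"state0 must have shape ({N_STATES},), got {y0.shape}")
    n_steps = int(round((t1 - t0) / step))
    sig = schedule.per_step_arrays(t0, n_steps, step)
    times, states, status, fail_step, fail_comp = kernel.rk4_loop(
        y0, float(t0), float(step), n_steps, params.as_array(),
        *variant.flags(), frozen, *sig, int(record_stride))
    if status != kernel.OK:
        t_fail = t0 + fail_step * step
        comp = STATE_NAMES[fail_comp]
        kind = "non-finite" if status == kernel.NONFINITE else "negative"
        raise NumericError(
            f"{kind} value in state component {comp!r} at t={t_fail:.1f} s",
            time_s=t_fail, component=comp)
    return Trajectory(times=times, states=states, step=step,
                      record_stride=record_stride, variant=variant, basal=basal)


def _residual(y: np.ndarray, p_arr: np.ndarray, variant: ModelVariant,
              frozen: np.ndarray) -> np.ndarray:
    """RHS with clamped components replaced by pinning equations.

    Clamped variables have identically-zero derivatives, which would make a
    Newton system singular; pin them to their clamp values instead.
    """
    y = np.asarray(y, dtype=float)
    # evaluate at the nonnegative clip (the model is only defined there) and
    # pull excursions back linearly so the solver stays in the feasible set
    yc = np.maximum(y, 0.0)
    dy = np.empty(N_STATES)
    kernel.rhs(yc, 0.0, 0.0, 1.0, 1.0, 1.0, p_arr,
               *variant.flags(), frozen, dy)
    dy += y - yc
    if variant.no_mecp2_effects:
        dy[STATE_INDEX["E_MeCP2"]] = y[STATE_INDEX["E_MeCP2"]]
        dy[STATE_INDEX["E_comp"]] = y[STATE_INDEX["E_comp"]]
    if variant.block_w_loop:
        dy[STATE_INDEX["PP"]] = y[STATE_INDEX["PP"]] - frozen[2]
    return dy


def equilibrate(params: ParameterSet, variant: ModelVariant = STANDARD,
                max_days: float = 240.0, tol: float = 1e-12,
                y0: np.ndarray | None = None,
                frozen: np.ndarray | None = None,
                step: float = DEFAULT_STEP) -> np.ndarray:
    """Basal (pre-stimulus) fixed point of the model.

    Relaxes from the documented cold start (see ``_COLD_SEEDS``) with all
    signals at rest, for at least two simulated days, attempting after every
    two-day chunk a Newton polish of the fixed point, and verifies
    ``sup |dy/dt| < tol``.  Deterministic and
    idempotent: re-equilibrating from the result returns the same state to
    well below 1e-9 mM.

    For a variant that blocks a feedback loop, the standard model is
    equilibrated first to supply the frozen basal quantities (unless
    ``frozen`` is given); the basal state is unchanged by construction.
    """
    if variant.any_loop_block and frozen is None:
        basal_std = equilibrate(params, STANDARD, max_days=max_days, tol=tol,
                                step=step)
        frozen = frozen_from_basal(basal_std, params)
    frozen = _NO_FROZEN if frozen is None else np.asarray(frozen, dtype=float)

    if y0 is None:
        y = np.array([COLD_START[n] for n in STATE_NAMES])
    else:
        y = np.asarray(y0, dtype=float).copy()
    if variant.no_mecp2_effects:
        y[STATE_INDEX["E_MeCP2"]] = 0.0
        y[STATE_INDEX["E_comp"]] = 0.0
    p_arr = params.as_array()

    def scaled_res(x):
        return _residual(x, p_arr, variant, frozen) * _RES_SCALE

    def is_attracting(x):
        # finite-difference Jacobian of the rest dynamics; the weight module
        # sits at a rest point with one near-neutral direction (growth time
        # of weeks), so a tiny positive bound is used rather than zero
        J = np.empty((N_STATES, N_STATES))
        f0 = _residual(x, p_arr, variant, frozen)
        for j in range(N_STATES):
            d = np.zeros(N_STATES)
            h = 1e-8 * (1.0 + abs(x[j]))
            d[j] = h
            if x[j] < h:  # one-sided into the feasible region at the clip
                J[:, j] = (_residual(x + d, p_arr, variant, frozen) - f0) / h
            else:
                J[:, j] = (_residual(x + d, p_arr, variant, frozen)
                           - _residual(x - d, p_arr, variant, frozen)) / (2 * h)
        if not np.all(np.isfinite(J)):
            return False
        # clamped components are pinned algebraically, not dynamical d.o.f.
        keep = np.ones(N_STATES, dtype=bool)
        if variant.no_mecp2_effects:
            keep[STATE_INDEX["E_MeCP2"]] = keep[STATE_INDEX["E_comp"]] = False
        if variant.block_w_loop:
            keep[STATE_INDEX["PP"]] = False
        J = J[np.ix_(keep, keep)]
        return float(np.max(np.linalg.eigvals(J).real)) < 1e-6

    elapsed = 0.0
    res = np.inf
    while elapsed < max_days:
        chunk_days = 2.0 if elapsed < 10.0 else 10.0
        traj = integrate(y, 0.0, chunk_days * 86400.0, params,
                         schedule=None, variant=variant, step=step,
                         record_stride=10 ** 9, frozen=frozen)
        y = traj.states[-1].copy()
        elapsed += chunk_days
        res = float(np.max(np.abs(_residual(y, p_arr, variant, frozen))))
        if res < tol:
            return y
        # Newton polish on the time-scaled residual; accepted only if the
        # polished state is nonnegative (after snapping roundoff-level
        # negatives to zero), meets the unscaled tolerance, did not leap to a
        # far-away root, and is confirmed by integration (two further days of
        # relaxation from it do not move it — i.e. it is the state the
        # relaxation is actually approaching)
        sol = scipy.optimize.root(scaled_res, y, method="lm",
                                  options=dict(xtol=1e-15, ftol=1e-15,
                                               maxiter=20000))
        y_fix = np.where((sol.x < 0) & (sol.x > -kernel.NEG_CLAMP), 0.0, sol.x)
        if np.all(y_fix >= 0.0):
            res_fix = float(np.max(np.abs(_residual(y_fix, p_arr, variant, frozen))))
            jump = float(np.max(np.abs(y_fix - y)))
            scale = 1.0 + float(np.max(np.abs(y)))
            if res_fix < tol and jump < 1e-8 * scale:
                # the relaxation has already reached this root to machine
                # precision; it is the de-facto rest state
                return y_fix
            if res_fix < tol and jump < 2.0 * scale and is_attracting(y_fix):
                check = integrate(y_fix, 0.0, 2 * 86400.0, params,
                                  schedule=None, variant=variant, step=step,
                                  record_stride=10 ** 9, frozen=frozen)
                if float(np.max(np.abs(check.states[-1] - y_fix))) < 1e-7 * scale:
                    return y_fix

    worst = int(np.argmax(np.abs(_residual(y, p_arr, variant, frozen))))
    raise EquilibrationError(
        f"equilibration stalled: residual {res:.3e} mM/s in component "
        f"{STATE_NAMES[worst]!r} exceeds tol {tol:.1e}",
        residual=res, component=STATE_NAMES[worst])
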