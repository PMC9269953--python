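"""Model surface: state layout, elementary regulatory functions, variants,
and a convenient wrapper around the compiled right-hand side.

The dynamical system couples two BDNF-dependent positive feedback loops
(BDNF -> pCaMKII -> BDNF release, and BDNF -> pCREB -> C/EBP -> *bdnf* ->
BDNF), dual regulation of *bdnf* transcription by MeCP2 (activation by free
MeCP2, repression by the MeCP2/Sin3a/HDAC2 complex), occupancy dynamics of
the three repressor-complex components on the *bdnf* promoter, and a synaptic
tagging-and-capture cascade ending in the synaptic weight W — the model's
memory readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kernel
from .kernel import N_STATES, STATE_INDEX, STATE_NAMES
from .params import ParameterSet

__all__ = [
    "STATE_NAMES", "STATE_INDEX", "N_STATES",
    "ModelVariant", "hill2", "upstream_drive", "derivatives",
    "frozen_from_basal", "state_dict",
]


@dataclass(frozen=True)
class ModelVariant:
    """Structural knockout flags; all off reproduces the standard model.

    ``block_camkii_loop``
        Sever the BDNF–CaMKII feedback by freezing the pCaMKII saturation
        factor of the BDNF release term at its basal value (basal flux kept).
    ``block_cebp_loop``
        Sever the BDNF–C/EBP feedback by freezing C/EBP at its basal value
        inside the *bdnf* transcription term.
    ``block_w_loop``
        Disable the downstream W positive feedback by clamping PP to basal.
    ``no_mecp2_effects``
        Clamp both MeCP2 effect variables (free-MeCP2 activation and complex
        repression) to zero; this is the bistability-capable variant.
    """

    block_camkii_loop: bool = False
    block_cebp_loop: bool = False
    block_w_loop: bool = False
    no_mecp2_effects: bool = False

    @property
    def any_loop_block(self) -> bool:
        """True if any flag needs frozen basal-state values."""
        return self.block_camkii_loop or self.block_cebp_loop or self.block_w_loop

    def flags(self) -> tuple[bool, bool, bool, bool]:
        return (self.block_camkii_loop, self.block_cebp_loop,
                self.block_w_loop, self.no_mecp2_effects)


STANDARD = ModelVariant()


def hill2(x: float, K: float) -> float:
    """Hill saturation with coefficient 2: ``x^2 / (x^2 + K^2)``.

    Transcription-factor action is modelled as dimeric, hence the square.
    """
    x = np.asarray(x, dtype=float)
    K = float(K)
    if K <= 0:
        raise ValueError(f"Hill constant K must be > 0, got {K}")
    if np.any(x < 0):
        raise ValueError("hill2 input must be nonnegative")
    out = x * x / (x * x + K * K)
    return float(out) if out.ndim == 0 else out


def upstream_drive(tag: float, gprod: float,
                   tag_basal: float, gprod_basal: float) -> float:
    """Heaviside-gated excess of Tag*GPROD over its basal product.

    Returns ``max(0, tag*gprod - tag_basal*gprod_basal)``; the gate makes the
    synaptic weight respond only to above-basal tagging-and-capture drive, so
    W is never pushed below its rest level (the model has no depression).
    """
    for name, v in (("tag", tag), ("gprod", gprod),
                    ("tag_basal", tag_basal), ("gprod_basal", gprod_basal)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    return max(0.0, tag * gprod - tag_basal * gprod_basal)


def frozen_from_basal(basal: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Basal-state quantities a loop-blocking variant holds fixed.

    Computed from the *standard-model* equilibrium so that severing a loop
    preserves the basal flux through it (the rest state stays a fixed point).
    """
    basal = np.asarray(basal, dtype=float)
    pck = basal[STATE_INDEX["pCaMKII"]]
    sat_ck = pck / (pck + params.K_CaMKII_BDNF_syn)
    return np.array([sat_ck, basal[STATE_INDEX["CEBP"]],
                     basal[STATE_INDEX["PP"]]], dtype=float)


_NO_FROZEN = np.zeros(3)


def _check_state(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},), got {y.shape}")
    return y


def derivatives(state: np.ndarray, t: float, params: ParameterSet,
                schedule=None, variant: ModelVariant | None = None,
                frozen: np.ndarray | None = None) -> np.ndarray:
    """Full right-hand side at one time point (convenience wrapper).

    ``schedule`` may be None (all signals at rest).  ``frozen`` must be
    supplied (via :func:`frozen_from_basal`) when ``variant`` blocks a
    feedback loop.  The compiled kernel is the single source of the algebra;
    this wrapper only evaluates the exogenous signals and validates input.
    """
    y = _check_state(state)
    variant = variant or STANDARD
    if variant.any_loop_block and frozen is None:
        raise ValueError("a loop-blocking variant requires frozen basal values; "
                         "compute them with frozen_from_basal()")
    if frozen is None:
        frozen = _NO_FROZEN
    if schedule is None:
        stim, ani, ab, ac, am = 0.0, 0.0, 1.0, 1.0, 1.0
    else:
        stim, ani, ab, ac, am = schedule.signals_at(float(t))
    dy = np.empty(N_STATES)
    kernel.rhs(y, stim, ani, ab, ac, am, params.as_array(),
               *variant.flags(), np.asarray(frozen, dtype=float), dy)
    if not np.all(np.isfinite(dy)):
        bad = int(np.flatnonzero(~np.isfinite(dy))[0])
        from .errors import NumericError
        raise NumericError(
            f"non-finite derivative for state component {STATE_NAMES[bad]!r} "
            f"at t={t} s", time_s=float(t), component=STATE_NAMES[bad])
    return dy


def state_dict(y: np.ndarray) -> dict[str, float]:
    """Map a 17-vector to ``{state name: value}``."""
    y = _check_state(y)
    return {n: float(v) for n, v in zip(STATE_NAMES, y)}
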