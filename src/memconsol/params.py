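"""Model calibration: the standard parameter set.

Every rate constant, binding capacity and time constant of the consolidation
model lives here, one named field per published table entry, plus the handful
of protocol-level constants (stimulus amplitude/duration, disruptor level and
duration, consolidation threshold).  Units follow the source calibration:
concentrations in mM, first-order rates in s^-1, fluxes in mM/s, time
constants in s.  A few printed units are dimensionally odd (``r_sin3a`` in
mM^-1, ``k_f_w`` in mM); they are carried numerically as calibrated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import field

__all__ = ["ParameterSet", "PARAM_TABLE", "PARAM_ORDER"]

# name -> (default value, unit, printed symbol)
PARAM_TABLE: dict[str, tuple[float, str, str]] = {
    # BDNF release (Eq for d[BDNF]/dt)
    "r_BDNF": (0.3, "s^-1", "r_BDNF"),
    "k_fB": (1.5e-3, "mM/s", "k_fB"),
    "K_CaMKII_BDNF_syn": (7.3e-3, "mM", "K_CaMKII,BDNF"),
    "K_trans": (3e-2, "mM", "K_trans"),
    "K_dB": (0.6, "mM", "K_dB"),
    "k_dBDNF": (6.6e-4, "mM/s", "k_dBDNF"),
    # CREB phosphorylation
    "k_basalp_creb": (3.2e-6, "s^-1", "k_basalp_creb"),
    "k_dphos_creb": (9.6e-5, "s^-1", "k_dphos_creb"),
    "k_phos_creb": (4e-3, "s^-1", "k_phos_creb"),
    "K_CREB_BDNF": (2.0, "mM", "K_CREB_BDNF"),
    "CREB_total": (0.085, "mM", "CREB_total"),
    # C/EBPbeta expression
    "k_basal_cebp": (1.6e-2, "s^-1", "k_basal_cebp"),
    "k_f_cebp": (2.2, "s^-1", "k_f_cebp"),
    "k_d_cebp": (5.7e-3, "mM/s", "k_d_cebp"),
    "K_CREB_CEBP": (0.19, "mM", "K_CREB_CEBP"),
    "CEBP_max": (0.23, "mM", "CEBP_max"),
    "K_cebp": (7.6e-2, "mM", "K_cebp"),
    "tau_cebp": (3e3, "s", "tau_cebp"),
    # bdnf transcription and its dual MeCP2 regulation
    "k_b_MeCP2": (1.6e-7, "mM/s", "k_b_MeCP2"),
    "k_f_bdnf": (1.6e-4, "mM/s", "k_f_bdnf"),
    "K_a_bdnf": (3.2, "mM", "K_a_bdnf"),
    "k_degb": (4.5e-5, "mM/s", "k_degb"),
    "K_db": (0.6, "mM", "K_db"),
    "k_f_EMeCP2": (0.34, "mM", "k_f_EMeCP2"),
    "E_MeCP2_max": (5.0, "mM", "[E_MeCP2]_max"),
    "tau_E_MeCP2": (1.44e4, "s", "tau_E_MeCP2"),
    "k_f_comp": (4.5, "mM", "k_f_comp"),
    "k_d_comp": (6.7e-3, "mM", "k_d_comp"),
    "B_Sin3a_basal": (1.0, "mM", "[B_Sin3a]_basal"),
    "B_HDAC2_basal": (1.0, "mM", "[B_HDAC2]_basal"),
    "E_comp_max": (5.0, "mM", "[I_Comp]_max"),
    "tau_comp": (3.6e4, "s", "tau_Comp"),
    # CaMKIIalpha phosphorylation and BDNF feedback
    "r_CaMKII": (0.15, "s^-1", "r_CaMKII"),
    "k_basalp_CaMKII": (3.6e-6, "mM/s", "k_basalp_CaMKII"),
    "k_dphos_CaMKII": (1.1e-4, "s^-1", "k_dphos_CaMKII"),
    "pCaMKII_total": (0.085, "mM", "pCaMKII_total"),
    "k_CaMKII_B": (5.3e-5, "mM/s", "k_CaMKII_B"),
    "K_CaMKII_BDNF": (0.28, "mM", "K_CaMKII_BDNF"),
    "k_CaMKII_F": (4.1e-5, "mM/s", "k_CaMKII_F"),
    "K_CaMKII_feed": (0.03, "mM", "K_CaMKII_feed"),
    # promoter occupancy by Sin3a / HDAC2 / MeCP2
    "r_sin3a": (3e4, "mM^-1", "r_sin3a"),
    "k_f_Sin3a": (0.25, "mM^-2", "k_f_Sin3a"),
    "tau_sin3a": (5e4, "s", "tau_sina"),
    "B_Sin3a_max": (5.0, "mM", "[B_Sin3a]_max"),
    "k_f_HDAC2": (0.25, "mM^-2", "k_f_HDAC2"),
    "B_HDAC2_max": (5.0, "mM", "[B_HDAC2]_max"),
    "tau_HDAC2": (1.25e5, "s", "tau_HDAC2"),
    "k_f_MeCP2": (0.25, "mM^-2", "k_f_MeCP2"),
    "B_MeCP2_max": (5.0, "mM", "[B_MeCP2]_max"),
    "k_d_MeCP2": (4.0, "mM", "k_d_MeCP2"),
    "K_pCaMKII_MeCP2": (0.011, "mM", "K_pCaMKII_MeCP2"),
    "tau_MeCP2": (1e4, "s", "tau_MeCP2"),
    # synaptic tagging and capture
    "k_f_tag": (0.5, "mM^-1 s^-1", "k_f_tag"),
    "k_d_tag": (0.03, "s^-1", "k_d_tag"),
    "tau_Tag": (5.0, "s", "tau_Tag"),
    "k_f_tif1": (1.1e-4, "mM^-1 s^-1", "k_f_tif1"),
    "k_d_tif1": (3e-5, "s^-1", "k_d_tif1"),
    "k_f_tif2": (2.4e-5, "mM^-1 s^-1", "k_f_tif2"),
    "k_d_tif2": (6e-5, "s^-1", "k_d_tif2"),
    "k_basal_GPROD": (4e-4, "mM/s", "k_basal_GROP"),
    "k_f_GPROD": (7.5, "mM/s", "k_f_GROD"),
    "k_d_GPROD": (0.05, "s^-1", "k_d_GROD"),
    "K_tif1": (1.0, "mM", "K_tif1"),
    "tau_GPROD": (2e3, "s", "tau_GPROD"),
    "K_tif2": (1.0, "mM", "K_tif2"),
    # synaptic weight W, precursor P, and the W->PP->P feedback
    "k_basal_p": (0.48, "mM", "k_basal_p"),
    "k_f_w": (1680.0, "mM", "k_f_w"),
    "K_p": (13.3, "mM", "K_p"),
    "k_d_w": (0.08, "s^-1", "k_d_w"),
    "Tag_basal": (0.1, "mM", "[tag]_basal"),
    "GPROD_basal": (0.12, "mM", "[GPROD]_basal"),
    "K_w_pp": (0.9, "mM", "K_w_pp"),
    "tau_p": (2.5e4, "s", "tau_p"),
    "tau_pp": (7.5e5, "s", "tau_pp"),
    "k_f_pp": (0.8, "mM", "k_f_pp"),
    # Reference occupancy for the MeCP2-excess terms (not in the published
    # calibration table).  Set just below the resting bound-MeCP2 level so the
    # free-MeCP2 effect is mildly engaged at rest (MeCP2 constitutively
    # activates bdnf) and acts as a two-sided stabiliser of the basal
    # promoter-occupancy state; at 0.98 the equilibrated occupancies and the
    # basal tag/capture levels land on their tabulated values.
    "B_MeCP2_basal": (0.98, "mM", "[B_MeCP2]_basal"),
    # protocol-level constants
    "stim_amplitude": (0.03, "mM/s", "stim"),
    "stim_duration": (60.0, "s", "stim duration"),
    "ani_level": (0.8, "1", "ANI"),
    "disruptor_duration": (21600.0, "s", "disruptor duration"),
    "consolidation_threshold": (2.0, "1", "W threshold"),
}

PARAM_ORDER: tuple[str, ...] = tuple(PARAM_TABLE)

# parameters allowed to be zero (protocol amplitudes / efficacies)
_MAY_BE_ZERO = {"stim_amplitude", "ani_level"}


class _ParameterSetMixin:
    """Behaviour shared into the generated ``ParameterSet`` dataclass."""

    def __post_init__(self) -> None:
        for name in PARAM_ORDER:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or v != v:
                raise ValueError(f"parameter {name!r} must be a finite number, got {v!r}")
            if name in _MAY_BE_ZERO:
                if v < 0:
                    raise ValueError(f"parameter {name!r} must be >= 0, got {v}")
            elif v <= 0:
                raise ValueError(f"parameter {name!r} must be > 0, got {v}")
        if not 0.0 <= self.ani_level <= 1.0:
            raise ValueError(f"ani_level must lie in [0, 1], got {self.ani_level}")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced."""
        unknown = set(overrides) - set(PARAM_ORDER)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def scaled(self, **factors: float) -> "ParameterSet":
        """Return a copy with the named parameters multiplied by factors.

        Mirrors how protocols are phrased ("at 50% of the standard value"):
        ``params.scaled(k_basalp_CaMKII=0.5)``.
        """
        unknown = set(factors) - set(PARAM_ORDER)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        for name, f in factors.items():
            if f <= 0:
                raise ValueError(f"scale factor for {name!r} must be > 0, got {f}")
        return dataclasses.replace(
            self, **{n: getattr(self, n) * f for n, f in factors.items()}
        )

    def as_array(self):
        """Parameter values as a float64 vector in :data:`PARAM_ORDER` order."""
        import numpy as np

        return np.array([float(getattr(self, n)) for n in PARAM_ORDER], dtype=np.float64)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_ORDER}

    @classmethod
    def names(cls) -> tuple[str, ...]:
        return PARAM_ORDER


def reference_table_markdown() -> str:
    """Markdown reference table: config name, published symbol, value, unit."""
    lines = [
        "# Parameter reference",
        "",
        "Config/CLI names map to the published calibration symbols as below.",
        "",
        "| name | symbol | value | unit |",
        "|---|---|---|---|",
    ]
    for name, (value, unit, symbol) in PARAM_TABLE.items():
        lines.append(f"| `{name}` | {symbol} | {value:g} | {unit} |")
    return "\n".join(lines) + "\n"


# The fields are generated from PARAM_TABLE so defaults cannot drift from it.
ParameterSet = dataclasses.make_dataclass(
    "ParameterSet",
    [(n, float, field(default=v)) for n, (v, _u, _s) in PARAM_TABLE.items()],
    bases=(_ParameterSetMixin,),
    frozen=True,
)
ParameterSet.__doc__ = (
    "Immutable bag of the model constants plus protocol constants.\n\n"
    "Construct with no arguments for the standard calibration; override by\n"
    "keyword, or derive scaled copies with :meth:`scaled`."
)
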