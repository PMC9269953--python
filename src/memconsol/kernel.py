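"""Compiled inner loop: model right-hand side and fixed-step RK4.

The 17 coupled rate equations are written out once, in scalar form, against a
flat parameter vector (ordering from :data:`memconsol.params.PARAM_ORDER`) and
per-step exogenous signal arrays.  When numba is importable the right-hand
side and the integration loop are JIT-compiled; otherwise the same functions
run as plain Python (slow but exact, used as an automatic fallback).

Exogenous signals are piecewise constant and held fixed within each step, so
they are passed as one value per step (evaluated at the step's start time) and
shared by the four RK4 stages.
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


from .params import PARAM_ORDER

# ---------------------------------------------------------------------------
# state layout (mM throughout; Tag/TF1/TF2 dimensionless occupancies)
STATE_NAMES: tuple[str, ...] = (
    "BDNF", "bdnf_m", "pCREB", "CEBP", "E_MeCP2", "E_comp", "pCaMKII",
    "B_Sin3a", "B_HDAC2", "B_MeCP2", "Tag", "TF1", "TF2", "GPROD",
    "W", "P", "PP",
)
N_STATES = len(STATE_NAMES)
STATE_INDEX: dict[str, int] = {n: i for i, n in enumerate(STATE_NAMES)}

_PI = {n: i for i, n in enumerate(PARAM_ORDER)}

# parameter indices, resolved at import so the kernel reads like the equations
P_R_BDNF = _PI["r_BDNF"]; P_K_FB = _PI["k_fB"]
P_K_CK_B_SYN = _PI["K_CaMKII_BDNF_syn"]; P_K_TRANS = _PI["K_trans"]
P_K_DB_BDNF = _PI["K_dB"]; P_K_DBDNF = _PI["k_dBDNF"]
P_K_BP_CREB = _PI["k_basalp_creb"]; P_K_DP_CREB = _PI["k_dphos_creb"]
P_K_P_CREB = _PI["k_phos_creb"]; P_K_CREB_BDNF = _PI["K_CREB_BDNF"]
P_CREB_TOT = _PI["CREB_total"]
P_K_B_CEBP = _PI["k_basal_cebp"]; P_K_F_CEBP = _PI["k_f_cebp"]
P_K_D_CEBP = _PI["k_d_cebp"]; P_K_CREB_CEBP = _PI["K_CREB_CEBP"]
P_CEBP_MAX = _PI["CEBP_max"]; P_K_CEBP = _PI["K_cebp"]; P_TAU_CEBP = _PI["tau_cebp"]
P_K_B_MECP2 = _PI["k_b_MeCP2"]; P_K_F_BDNF = _PI["k_f_bdnf"]
P_K_A_BDNF = _PI["K_a_bdnf"]; P_K_DEGB = _PI["k_degb"]; P_K_DB_M = _PI["K_db"]
P_K_F_EM = _PI["k_f_EMeCP2"]; P_EM_MAX = _PI["E_MeCP2_max"]; P_TAU_EM = _PI["tau_E_MeCP2"]
P_K_F_COMP = _PI["k_f_comp"]; P_K_D_COMP = _PI["k_d_comp"]
P_BS_BASAL = _PI["B_Sin3a_basal"]; P_BH_BASAL = _PI["B_HDAC2_basal"]
P_EC_MAX = _PI["E_comp_max"]; P_TAU_COMP = _PI["tau_comp"]
P_R_CK = _PI["r_CaMKII"]; P_K_BP_CK = _PI["k_basalp_CaMKII"]
P_K_DP_CK = _PI["k_dphos_CaMKII"]; P_CK_TOT = _PI["pCaMKII_total"]
P_K_CK_B = _PI["k_CaMKII_B"]; P_K_CK_BDNF = _PI["K_CaMKII_BDNF"]
P_K_CK_F = _PI["k_CaMKII_F"]; P_K_CK_FEED = _PI["K_CaMKII_feed"]
P_R_SIN3A = _PI["r_sin3a"]; P_K_F_BS = _PI["k_f_Sin3a"]; P_TAU_BS = _PI["tau_sin3a"]
P_BS_MAX = _PI["B_Sin3a_max"]; P_K_F_BH = _PI["k_f_HDAC2"]; P_BH_MAX = _PI["B_HDAC2_max"]
P_TAU_BH = _PI["tau_HDAC2"]; P_K_F_BM = _PI["k_f_MeCP2"]; P_BM_MAX = _PI["B_MeCP2_max"]
P_K_D_BM = _PI["k_d_MeCP2"]; P_K_CK_MECP2 = _PI["K_pCaMKII_MeCP2"]
P_TAU_BM = _PI["tau_MeCP2"]
P_K_F_TAG = _PI["k_f_tag"]; P_K_D_TAG = _PI["k_d_tag"]; P_TAU_TAG = _PI["tau_Tag"]
P_K_F_TIF1 = _PI["k_f_tif1"]; P_K_D_TIF1 = _PI["k_d_tif1"]
P_K_F_TIF2 = _PI["k_f_tif2"]; P_K_D_TIF2 = _PI["k_d_tif2"]
P_K_B_G = _PI["k_basal_GPROD"]; P_K_F_G = _PI["k_f_GPROD"]; P_K_D_G = _PI["k_d_GPROD"]
P_K_TIF1 = _PI["K_tif1"]; P_TAU_G = _PI["tau_GPROD"]; P_K_TIF2 = _PI["K_tif2"]
P_K_B_P = _PI["k_basal_p"]; P_K_F_W = _PI["k_f_w"]; P_K_P = _PI["K_p"]
P_K_D_W = _PI["k_d_w"]; P_TAG_BASAL = _PI["Tag_basal"]; P_G_BASAL = _PI["GPROD_basal"]
P_K_W_PP = _PI["K_w_pp"]; P_TAU_P = _PI["tau_p"]; P_TAU_PP = _PI["tau_pp"]
P_K_F_PP = _PI["k_f_pp"]; P_BM_BASAL = _PI["B_MeCP2_basal"]

# kernel status codes
OK = 0
NONFINITE = 1
NEGATIVE = 2

NEG_CLAMP = 1e-12  # components in (-NEG_CLAMP, 0) are snapped to 0 each step


@njit(cache=True, error_model="numpy")
def rhs(y, stim, ani, a_bdnf, a_cebp, a_mecp2, p,
        f_camkii, f_cebp, f_w, f_nomecp2, frz, dy):
    """Time derivatives of the 17 state variables (in-place into ``dy``).

    ``a_*`` are activity factors in (0, 1] implementing ODN-style knockdown:
    they multiply the species wherever it acts as a regulatory input, never
    the state itself.  ``frz`` carries basal-state values used when a
    feedback-loop flag severs a loop while preserving the basal flux:
    ``frz[0]`` the basal pCaMKII saturation factor of the BDNF release term,
    ``frz[1]`` basal C/EBP, ``frz[2]`` basal PP.
    """
    BDNF = y[0]; BDNFM = y[1]; PCREB = y[2]; CEBP = y[3]
    EM = y[4]; EC = y[5]; PCK = y[6]
    BS = y[7]; BH = y[8]; BM = y[9]
    TAG = y[10]; TF1 = y[11]; TF2 = y[12]; G = y[13]
    W = y[14]; P = y[15]; PP = y[16]

    if f_nomecp2:
        EM = 0.0
        EC = 0.0

    syn = 1.0 - ani          # translation not blocked by the inhibitor
    BDNF_a = BDNF * a_bdnf   # BDNF as regulatory input (anti-BDNF ODN)
    CEBP_a = CEBP * a_cebp   # C/EBP as regulatory input (anti-C/EBP ODN)
    EM_a = EM * a_mecp2      # free-MeCP2 effect (MeCP2 suppression)
    BM_a = BM * a_mecp2      # bound MeCP2 as regulatory input

    # --- BDNF release: stimulus + pCaMKII- and mRNA-gated synthesis
    if f_camkii:
        sat_ck = frz[0]
    else:
        sat_ck = PCK / (PCK + p[P_K_CK_B_SYN])
    dy[0] = (p[P_R_BDNF] * stim
             + p[P_K_FB] * sat_ck * (BDNFM / (BDNFM + p[P_K_TRANS])) * syn
             - p[P_K_DBDNF] * BDNF / (BDNF + p[P_K_DB_BDNF]))

    # --- CREB phosphorylation (Hill(2) in BDNF)
    b2 = BDNF_a * BDNF_a
    kb2 = p[P_K_CREB_BDNF] * p[P_K_CREB_BDNF]
    dy[2] = ((p[P_K_BP_CREB] + p[P_K_P_CREB] * b2 / (b2 + kb2))
             * (p[P_CREB_TOT] - PCREB)
             - p[P_K_DP_CREB] * PCREB)

    # --- C/EBP expression (Hill(2) in pCREB, saturable degradation)
    c2 = PCREB * PCREB
    kc2 = p[P_K_CREB_CEBP] * p[P_K_CREB_CEBP]
    dy[3] = ((p[P_K_B_CEBP] + p[P_K_F_CEBP] * c2 / (c2 + kc2))
             * (p[P_CEBP_MAX] - CEBP) * syn
             - p[P_K_D_CEBP] * CEBP / (CEBP + p[P_K_CEBP])) / p[P_TAU_CEBP]

    # --- bdnf transcription: free-MeCP2 activation, C/EBP activation,
    #     repression by the complex effect entering the Hill denominator
    ce = frz[1] * a_cebp if f_cebp else CEBP_a
    ce2 = ce * ce
    ka2 = p[P_K_A_BDNF] * p[P_K_A_BDNF]
    dy[1] = (p[P_K_B_MECP2] * (1.0 + EM_a)
             + p[P_K_F_BDNF] * ce2 / (ka2 + ce2 + EC * EC)
             - p[P_K_DEGB] * BDNFM / (BDNFM + p[P_K_DB_M]))

    # --- effect of free MeCP2: grows with excess MeCP2 binding, suppressed
    #     by Sin3a/HDAC2 binding (ratio form)
    exM = BM_a - p[P_BM_BASAL]
    if exM < 0.0:
        exM = 0.0
    if f_nomecp2:
        dy[4] = 0.0
    else:
        den = BS * BH
        if den < 1e-12:  # collapsed occupancies; avoids 0/0 at exM = 0
            den = 1e-12
        dy[4] = (p[P_K_F_EM] * (exM / den) * (p[P_EM_MAX] - EM)
                 - EM) / p[P_TAU_EM]

    # --- effect of the MeCP2/Sin3a/HDAC2 complex (all three above basal)
    exS = BS - p[P_BS_BASAL]
    if exS < 0.0:
        exS = 0.0
    exH = BH - p[P_BH_BASAL]
    if exH < 0.0:
        exH = 0.0
    if f_nomecp2:
        dy[5] = 0.0
    else:
        dy[5] = (p[P_K_F_COMP] * exM * exS * exH * (p[P_EC_MAX] - EC)
                 - p[P_K_D_COMP] * EC) / p[P_TAU_COMP]

    # --- CaMKII phosphorylation: stimulus + basal + BDNF/self feedback
    bb2 = BDNF_a * BDNF_a
    kk2 = p[P_K_CK_BDNF] * p[P_K_CK_BDNF]
    pk2 = PCK * PCK
    kf2 = p[P_K_CK_FEED] * p[P_K_CK_FEED]
    efb = (p[P_K_CK_B] * bb2 / (bb2 + kk2)
           + p[P_K_CK_F] * pk2 / (pk2 + kf2))
    dy[6] = ((p[P_R_CK] * stim + p[P_K_BP_CK] + efb) * (p[P_CK_TOT] - PCK)
             - p[P_K_DP_CK] * PCK)

    # --- promoter occupancies: mutual cooperativity of the three factors
    dy[7] = ((p[P_R_SIN3A] * stim + p[P_K_F_BS] * BM_a * BH)
             * (p[P_BS_MAX] - BS) - BS) / p[P_TAU_BS]
    dy[8] = (p[P_K_F_BH] * BM_a * BS * (p[P_BH_MAX] - BH) - BH) / p[P_TAU_BH]
    hk2 = p[P_K_CK_MECP2] * p[P_K_CK_MECP2]
    dy[9] = (p[P_K_F_BM] * BH * BS * (p[P_BM_MAX] - BM)
             - p[P_K_D_BM] * (pk2 / (pk2 + hk2)) * BM) / p[P_TAU_BM]

    # --- tagging and capture
    dy[10] = (p[P_K_F_TAG] * PCK * (1.0 - TAG) - p[P_K_D_TAG] * TAG) / p[P_TAU_TAG]
    dy[11] = p[P_K_F_TIF1] * PCREB * (1.0 - TF1) * syn - p[P_K_D_TIF1] * TF1
    dy[12] = p[P_K_F_TIF2] * CEBP_a * (1.0 - TF2) * syn - p[P_K_D_TIF2] * TF2
    dy[13] = ((p[P_K_B_G] + p[P_K_F_G]
               * (TF1 / (TF1 + p[P_K_TIF1])) * (TF2 / (TF2 + p[P_K_TIF2]))) * syn
              - p[P_K_D_G] * G) / p[P_TAU_G]

    # --- synaptic weight: tag*capture-gated production limited by precursor P,
    #     which is replenished from PP (the W positive-feedback intermediate)
    eup = TAG * G - p[P_TAG_BASAL] * p[P_G_BASAL]
    if eup < 0.0:
        eup = 0.0
    phi = (p[P_K_B_P] + p[P_K_F_W] * eup) * (P / (P + p[P_K_P])) * syn
    dy[14] = (phi - p[P_K_D_W] * W) / p[P_TAU_P]
    ppv = frz[2] if f_w else PP
    dy[15] = (ppv - phi - p[P_K_D_W] * P) / p[P_TAU_P]
    if f_w:
        dy[16] = 0.0
    else:
        w2 = W * W
        kw2 = p[P_K_W_PP] * p[P_K_W_PP]
        dy[16] = (p[P_K_F_PP] * w2 / (w2 + kw2) - PP) / p[P_TAU_PP]


@njit(cache=True, error_model="numpy")
def rk4_loop(y0, t0, h, n_steps, p, f_camkii, f_cebp, f_w, f_nomecp2, frz,
             stim, ani, a_bdnf, a_cebp, a_mecp2, record_stride):
    """Classic RK4 over ``n_steps`` fixed steps with per-step signals.

    Returns ``(times, states, status, fail_step, fail_comp)``.  ``states``
    holds every ``record_stride``-th step plus the final one; on a numeric
    failure the arrays are truncated at the last healthy record.
    """
    n = y0.shape[0]
    n_rec = n_steps // record_stride + 1
    if n_steps % record_stride != 0:
        n_rec += 1
    times = np.empty(n_rec)
    states = np.empty((n_rec, n))

    y = y0.copy()
    yt = np.empty(n)
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)

    times[0] = t0
    states[0, :] = y
    irec = 1
    status = OK
    fail_step = -1
    fail_comp = -1

    for i in range(n_steps):
        s = stim[i]; a = ani[i]
        ab = a_bdnf[i]; ac = a_cebp[i]; am = a_mecp2[i]
        rhs(y, s, a, ab, ac, am, p, f_camkii, f_cebp, f_w, f_nomecp2, frz, k1)
        for j in range(n):
            yt[j] = y[j] + 0.5 * h * k1[j]
        rhs(yt, s, a, ab, ac, am, p, f_camkii, f_cebp, f_w, f_nomecp2, frz, k2)
        for j in range(n):
            yt[j] = y[j] + 0.5 * h * k2[j]
        rhs(yt, s, a, ab, ac, am, p, f_camkii, f_cebp, f_w, f_nomecp2, frz, k3)
        for j in range(n):
            yt[j] = y[j] + h * k3[j]
        rhs(yt, s, a, ab, ac, am, p, f_camkii, f_cebp, f_w, f_nomecp2, frz, k4)
        for j in range(n):
            y[j] = y[j] + (h / 6.0) * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])

        for j in range(n):
            v = y[j]
            if not np.isfinite(v):
                status = NONFINITE
                fail_step = i + 1
                fail_comp = j
                break
            if v < 0.0:
                if v > -NEG_CLAMP:
                    y[j] = 0.0
                else:
                    status = NEGATIVE
                    fail_step = i + 1
                    fail_comp = j
                    break
        if status != OK:
            break

        if (i + 1) % record_stride == 0:
            times[irec] = t0 + (i + 1) * h
            states[irec, :] = y
            irec += 1

    if status == OK and n_steps % record_stride != 0:
        times[irec] = t0 + n_steps * h
        states[irec, :] = y
        irec += 1

    return times[:irec], states[:irec], status, fail_step, fail_comp
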