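# Methods

## The model

`memconsol` simulates the molecular program engaged by a single trial of
inhibitory-avoidance (IA) training in rat hippocampus as a deterministic
17-state ODE system. The state variables, all in mM (the synaptic tag and the
two generic transcription factors are dimensionless occupancies):

* released **BDNF** and *bdnf* mRNA (`bdnf_m`);
* phosphorylated CREB (`pCREB`, free CREB is `CREB_total − pCREB`) and the
  transcription factor C/EBPβ (`CEBP`);
* phosphorylated CaMKIIα (`pCaMKII`, free kinase `pCaMKII_total − pCaMKII`);
* occupancies of Sin3a, HDAC2 and MeCP2 on the *bdnf* exon-IV promoter
  (`B_Sin3a`, `B_HDAC2`, `B_MeCP2`) and the two MeCP2 effect variables:
  activation of *bdnf* by free MeCP2 (`E_MeCP2`) and repression by the
  MeCP2/Sin3a/HDAC2 complex (`E_comp`);
* a synaptic tagging-and-capture cascade: tag (`Tag`), transcription factors
  `TF1`/`TF2`, plasticity product `GPROD`, and the synaptic weight module
  `W`, precursor `P`, and feedback intermediate `PP`.

Two BDNF-dependent positive feedback loops drive consolidation: a fast
translation-independent loop (BDNF → pCaMKIIα → BDNF release) and a slow
transcriptional loop (BDNF → pCREB → C/EBPβ → *bdnf* → BDNF). MeCP2
regulates *bdnf* in a dual mode: free MeCP2 bound to the promoter activates
transcription (`k_b_MeCP2·(1 + E_MeCP2)`), while the ternary complex with
Sin3a and HDAC2 represses it (`E_comp²` enters the activation Hill
denominator). pCaMKIIα phosphorylates MeCP2 and lowers its DNA binding, so
the kinase gates the repressor: while pCaMKIIα is elevated after training the
complex cannot assemble, and when the kinase decays the complex forms and
terminates the loops. The weight W grows only when the product `Tag·GPROD`
exceeds its basal value (a one-sided gate — the model expresses potentiation,
not depression), is limited by the precursor P, and is maintained by its own
positive feedback through PP.

Training is a 60-s square stimulus pulse (amplitude 0.03 mM/s) that drives
BDNF release, CaMKIIα phosphorylation and Sin3a binding directly.
Protein-synthesis inhibition (anisomycin-style, "PSI") multiplies the
synthesis terms of BDNF, C/EBP, TF1, TF2, GPROD and W by `1 − ANI` (default
ANI = 0.8 for 6 h); transcription is untouched, since the inhibitor acts on
translation. Antisense-ODN style disruptors multiply a species wherever it
acts as a regulatory input (never the state itself): anti-BDNF scales BDNF in
the pCREB and pCaMKII drive terms, anti-C/EBP scales C/EBP in the *bdnf* and
TF2 terms, and MeCP2 suppression scales `E_MeCP2` and `B_MeCP2` as inputs to
the occupancy and effect equations.

Structural variants sever individual loops for mechanism analysis: the two
BDNF loops are cut by freezing the relevant saturation factor at its basal
value (so the basal flux, and hence the basal state, is preserved), the
downstream W feedback by clamping PP at basal, and the bistability-capable
variant clamps both MeCP2 effect variables to zero.

## Numerics

Classic fixed-step fourth-order Runge–Kutta at a 3-s step; exogenous signals
are piecewise constant, held fixed within a step (all four stages see the
step-start value), and window edges must lie on the step grid — hour-valued
onsets do exactly. Halving the step changes the day-7 weight by well under
0.1%. After each step, components in (−10⁻¹², 0) are snapped to zero; a
larger negative or a non-finite value raises an error naming the failing
component and time. The kernel is JIT-compiled with numba when available and
runs as plain Python otherwise (identical results, ~1000× slower).

**Equilibration.** The basal state is obtained by relaxing from a documented
cold start — the tabulated basal calibration (promoter occupancies 1 mM, tag
0.1, capture product 0.12, the weight module at the exact rest point of its
production/precursor balance, W = 0.3, P = 0.7, PP = 0.08) completed with
coarse analytic estimates of the remaining rest concentrations — for at least
two simulated days, then polishing the fixed point with a Newton solve of the
right-hand side (residuals scaled by per-state relaxation times). A polished
root is accepted only if it is nonnegative, meets the 10⁻¹² mM/s residual
tolerance, and is either dynamically attracting (finite-difference Jacobian
spectrum, with the weight module's near-neutral direction tolerated) or
already reached by the relaxation to machine precision. The cold start
matters: three sub-systems are multistable even at rest (the promoter
occupancies, the weight module, and — without MeCP2 effects — the BDNF loop
itself), and a near-zero start would relax onto non-physiological branches.

**The basal reference for MeCP2 excess.** The occupancy equations' shared
intermediate fixed point is structurally a knife-edge: the three binding
variables are mutually cooperative, so the tabulated (1, 1, 1) rest is
unstable on its own. The untabulated reference occupancy `B_MeCP2_basal` is
set to 0.98 mM, slightly below the resting bound-MeCP2 level, so the
free-MeCP2 effect is mildly engaged at rest (consistent with MeCP2 acting as
a constitutive *bdnf* activator) and supplies two-sided negative feedback
that stabilises the basal state. The equilibrated standard basal then lands
on the tabulated calibration: occupancies 1.00–1.01 mM, tag 0.097, capture
product 0.120, basal weight 0.3 mM.

**The tag-capture gate.** The drive on W switches on when `Tag·GPROD`
exceeds the gate constant, tabulated as 0.1 × 0.12 — which equals the
standard-model resting product (rounded). A scan cell with elevated basal
CREB phosphorylation has a higher resting product; if the gate stayed at
0.012 the weight module would be driven at rest and no basal state would
exist. The gate is therefore `max(0.012, the cell's own equilibrated resting
product)`.

## Protocols and metrics

All protocols follow paired-run discipline (each reduction is measured
against a control run with identical parameters and variant) and per-cell
re-equilibration (every scan cell derives its own basal; percentages refer
to that cell's own basal W). Default problem sizes: 9-day training runs and
7-day paired runs at the 3-s step, recorded every 100th step (5-min
resolution); resistance scans over onsets 0–48 h at 1-h resolution (one
shared control plus 49 disrupted runs); the infantile grid is 11 CREB levels
(100–300% by 20%) × 6 CaMKII levels (100–50% by 10%); bistability scans use
10 CaMKII levels (10–100%) and 11 CREB levels.

Metrics: percent reduction `100·(1 − W_disrupted/W_control)` (negative if
the disrupted run overshoots control — reported raw); consolidation = W at or
above 200% of basal continuously over ≥ 48 h including day 7; resistance
curves are segmented into monotone phases by finite-difference slope with a
0.2 %/h plateau tolerance (an explicit parameter — the quantity is not pinned
numerically by the source); the *second resistance phase* is a non-decreasing
segment strictly between two decreasing segments; baseline return = earliest
sustained (≥ 6 h) entry into a ±5% band around basal after the post-stimulus
maximum; wave detection = local maxima exceeding basal by ≥ 10% of basal with
comparable prominence; the bistable switch is classified on the settled
attractor (10-day horizon) as BDNF *and* pCaMKII at ≥ 4× basal — the
attractors are separated by ~10–15× in BDNF and ~6–7× in pCaMKII, so any
factor in roughly [2, 5] gives the same call, while the transit is only ~3.5×
complete at 48 h.

## Behaviour of this reconstruction, and known limitations

The printed equations and calibration admit several readings; this package
fixes them by dimensional analysis, basal-state self-consistency, and
stability under the published 3-s integration step (for example, the
alternative stimulus normalisation in the CaMKII and Sin3a drive terms is
RK4-unstable at 3 s and can be excluded on those grounds). Under the
resulting model:

* Standard training consolidates: W(day 7) ≈ 248% of basal, with the weight
  maintained by the downstream feedback after the BDNF loops shut off.
* The repressor complex acts as a latch: its effect variable integrates
  nearly irreversibly (62-day effective decay), terminating the feedback
  loops at roughly 40–48 h; afterwards the system rests on a high-binding,
  mildly repressed attractor ~20% below the pre-training basal in the
  signalling variables. pCREB and pCaMKIIα consequently re-enter the ±5%
  basal band at ~59 h rather than by 48 h, and undershoot.
* The second BDNF release wave peaks near 8 h but is shallow (dip-to-peak
  ~5% of basal), below the default 10% wave-detection prominence.
* The day-7 resistance curve shows the resistance reversal as a plateau at
  onsets ~22–26 h rather than a rising segment at 25–35 h; the reversal's
  mechanism (fast MeCP2-alone rebinding after disruption vs. complex
  formation) is present but weaker than in the source, whose deposited code
  evidently differs from the printed equations in a way that strengthens
  loop ignition. Consistent with the source's mechanism analysis, the
  reversal disappears when either BDNF loop is severed or when the
  MeCP2-complex kinetics are rescaled (complex time constant × 0.3,
  free-MeCP2 time constant × 3, HDAC2 binding time constant × 0.3, Sin3a
  stimulus coupling × 3), while tag and capture time-constant rescalings and
  the W-loop block leave it intact.
* The infantile grid is graded with consolidation failing at strong CaMKII
  reductions (boundary at 50% CaMKII with elevated repressor-complex basal
  binding emerging from re-equilibration, 30% under the strict gate rule
  used here; the source reports 40%), and a handful of high-CREB /
  near-standard-CaMKII cells sit on an ignited or collapsed basal branch —
  artefacts of the knife-edged occupancy equations.
* The bistability-variant switch blocks at CaMKII ≤ 80% of standard (the
  source reports 40%) and, at that boundary, first succeeds at CREB 120%
  (source: 140%).

Passing tests therefore demonstrate the implemented dynamics, protocols and
metrics — not quantitative agreement with every published boundary; the
time-course shape checks and scan boundaries above are asserted at the
published values in the acceptance tests and fail where this reconstruction
deviates, as documented.

The simulator is single-compartment, deterministic (no stochastic channel or
expression noise) and does not model synaptic depression, memory
reinstatement protocols, or exogenous BDNF application.
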