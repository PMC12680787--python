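# Methods

## The model

`transmural` simulates single human ventricular myocytes with the
O'Hara–Rudy (ORd) formulation: 41 state variables covering the fast and
late Na⁺ currents, the transient-outward, L-type Ca²⁺, rapid and slow
delayed-rectifier and inward-rectifier currents, the Na/K pump, the Na/Ca
exchanger, background/pump remainders, CaMKII trapping, and a
four-compartment Ca²⁺ subsystem with SR release/uptake.  The three
transmural variants (ENDO / EPI / MID) share the equation structure and
initial conditions and differ only in the published parameter scalings
(e.g. MID has 2.5× L-type Ca²⁺ permeability and 0.8× I_Kr conductance;
EPI has 1.3× I_Kr, 1.4× I_Ks and a delayed-recovery factor on I_to
inactivation).  Units are mV, ms, pA/pF and mM throughout; outward
current is positive.

Pharmacology is idealised as multiplicative scaling of seven maximum
conductances (I_NaL, I_CaL, I_Ks, I_Kr, I_K1, I_NaK, I_NaCa) with hard
ranges [0,2], [0.5,1.5], [0,50], [0,2], [0.2,2], [0.5,1.5], [0.5,1.5];
a blockers-only mode caps each multiplier at 1.  Binding/unbinding
kinetics and rate-dependent block are out of scope, as are tissue
coupling and conduction: transmural dispersion here is a single-cell
proxy, the maximum pairwise APD90 difference among the three variants.

## Numerics

The integrator is a deterministic fixed-grid scheme: Rush–Larsen
exponential updates for all gates with (x_inf, tau) form (including SR
release), forward Euler for V_m, concentrations, the Ca-channel mode
switch and CaMKII.  Steps land exactly on the 0.1 ms output grid; within
each output interval the step is `dt` (default 0.005 ms) while the
stimulus is on or |dV/dt| > 0.25 mV/ms, and `dt_coarse` (default 0.05 ms)
during plateau and diastole where all rates are slow.  Setting
`dt_coarse = dt` recovers plain fixed-step integration; the two-level
scheme changes the steady-beat APD by < 0.2 ms relative to pure 0.005 ms
stepping and halving both steps changes it by < 0.2 ms (the test suite
asserts < 1 ms).  The scheme was chosen over adaptive ODE solvers for
bit-level reproducibility.

Stimulation follows the 1.5× threshold rule: a 0.5 ms rectangular inward
pulse whose amplitude is 1.5× the diastolic threshold, found by bisection
(0.01 pA/pF tolerance) after 50 pre-pacing beats, re-measured per (cell
type, scaling, BCL).  The pulse duration is a convention, not a reported
value.  The stimulus charge is carried by K⁺, as in the source model, and
so is the reserve test current.

Steady state: `mode="full"` paces for 30 simulated minutes from the
published resting initial conditions.  `mode="converged"` (the desk-scale
default) stops when |ΔAPD| between consecutive beats stays below 0.05 ms
for 10 beats, capped at 1800 beats.  At BCL ≤ 1000 ms the two agree to a
few ms in APD and ~2 ms in dispersion; at BCL = 3000 ms slow [Na]_i
drift makes the converged mode stop early (dispersion 148.5 vs 139.4 ms),
so slow-pacing results and the phase breakdown of the control epicardial
beat are always computed with the full protocol.  Ionic concentrations are reset
to the published initial conditions for every run; nothing is carried
across BCLs.

## AP phase analytics

Phase boundaries follow current-based rules on the final beat:

* end of depolarization = the phase-0 spike, the first local maximum of
  V_m after the upstroke (in MID cells the dome can exceed the spike, so
  the global maximum is not used here);
* phase-1 end = start of sustained repolarization: the upward
  zero-crossing of total ionic current I_tot after which I_tot stays
  positive for ≥ 15 ms (the literal first positive sample would land
  inside the notch, because V falls there too; the sustain window skips
  the notch-dome transient, which is ≲ 10 ms of positivity in all ORd
  variants);
* phase-2 end = first crossing of I_K1 through 10 % of its within-beat
  peak (peak taken outside the stimulus window);
* phase-3 end = 90 % repolarization of the AP amplitude from the maximum
  depolarization potential (global V_m maximum).

APD is measured from the spike to the APD90 crossing, so
APD = ph1 + ph2 + ph3 exactly.  All crossings are refined by linear
interpolation on the 0.1 ms grid.  Phase-averaged currents are time
averages over [phase-1 end, APD90]; the depolarizing group
{I_Na, I_NaL, I_CaL, I_CaNa, I_NaCa, I_Nab, I_Cab} and repolarizing group
{I_to, I_Kr, I_Ks, I_K1, I_NaK, I_Kb, I_CaK, I_pCa} partition the full
current set, so I_dep + I_rep = I_tot identically.  Grouping I_NaK (and
the small outward remainders) as repolarizing is a convention exposed as
a parameter.  The duration–current law I = K/d is fitted by closed-form
least squares (linear in K).

Repolarization abnormalities: an EAD is a local V_m minimum between the
phase-1 end and APD90 followed by a rise of > 2 mV (threshold
configurable; 2 mV rejects solver ripple while catching genuine
afterdepolarizations); repolarization failure is APD90 not reached within
the BCL; capture failure is V_m never exceeding 0 mV.

## Repolarization reserve

The reserve deficit is the APD prolongation under a constant depolarizing
current of −0.1 pA/pF applied during the action potential, an idealised
I_NaL-like (ATX-II) challenge.  "During the action potential" is
operationalised self-consistently: the injection runs from stimulus onset
to the injected beat's own APD90 crossing, found by fixed-point iteration
(start with the full BCL, shrink to the measured crossing, repeat until
it moves < 0.2 ms; 2–3 iterations suffice).  The challenge is acute — one
beat on top of the drug-condition steady state, no re-equilibration.

## Optimization and attribution

The PSO uses the stated settings (20 particles, ring topology of
neighborhood size 10 — five on each side, linearly decreasing inertia
0.9 → 0.4, 50 iterations) with the canonical acceleration coefficients
c1 = c2 = 1.49618, which the source settings do not fix.  Positions are
clamped to the bounds with the offending velocity component zeroed;
evaluations are memoized on 4-decimal-rounded vectors; one master seed
drives initialization, and the whole search is reproducible bit-for-bit.
Candidates whose beats show an EAD, repolarization failure or loss of
capture receive a large finite penalty (10⁴ ms), the in-swarm equivalent
of "discarded".  The objective is |APD_EPI − APD_MID| plus, in target
modes, the distance of the named cell's APD from a user target; ENDO is
reported in dispersion results but not optimized over.

Backward elimination re-optimizes every leave-one-out subset at each
step (left-out current pinned at control), keeps the subset with the
lowest achieved dispersion, and eliminates its left-out current until two
remain.  Subset searches may warm-start from the parent optimum (one
seeded particle) — both behaviours are exposed, since the source protocol
does not say.  Ties are broken by eliminating the current whose
parent-optimal multiplier was closest to 1 (least informative first).

Because one full-model PSO run costs thousands of paced simulations,
optimizer and elimination *studies* accept an injectable evaluation
backend.  `ORdBackend` is the real thing; `SurrogateBackend` is a cheap
analytic stand-in (monotone APD responses with transmural asymmetries,
saturating I_Ks response, a crude EAD region; control APDs 231/334/265
ms).  The surrogate exists so optimizer/elimination properties are
testable at desk scale; printed optima are verified by forward evaluation
on the full model, never rediscovered by PSO in tests.

## Synthetic-waveform generator

`synthetic_ap` emits beats from a piecewise family (linear upstroke,
linear notch capped at 8 ms, parabolic dome whose maximum sits exactly at
the phase-1/2 boundary, linear plateau decay, linear phase-3 fall through
the APD90 level exactly at the phase-2 end + ph3, exponential tail) with
I_tot = −dV/dt analytically and a Gaussian I_K1 bump whose rising
10 %-of-peak crossing is placed exactly at the phase-2/3 boundary.  Every
boundary the segmentation rules look for is therefore known in closed
form, which is what makes the feature extractor exactly testable.  These
traces deliberately do not reproduce biophysical current morphologies,
restitution or Ca²⁺ handling: a green synthetic test establishes that the
*rules* are implemented correctly, not that the model is right — the
model-level checks against steady-state simulations do that.

Gaussian noise (seeded, V_m only) emulates measurement noise; at
0.5 mV the measured APD stays within ~1 ms of truth in the median (a
rare peak-sample outlier can reach ~2 ms).

## Known limitations

* Single cells only; no electrotonic loading, so dispersion here is an
  upper-bound style proxy for tissue dispersion.
* Conductance scaling ignores drug kinetics and state dependence.
* The converged pacing mode under-relaxes slow [Na]_i drift at long BCLs;
  the full protocol is the reference there.
* The ToR-ORd variant is not implemented; the cell-model interface
  (integer cell code + scaling vector + state array) is what a second
  model would plug into.
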