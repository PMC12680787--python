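"""Synthetic AP-shaped traces with analytically known phase boundaries.

The waveform family is piecewise smooth and purpose-built so that the
current-based segmentation rules are exactly invertible:

* linear phase-0 upstroke from V_rest to V_peak over ``upstroke_ms``;
* a notch-and-dome phase 1: linear fall to the notch potential, then a
  parabolic rise whose maximum sits exactly at the intended phase-1/2
  boundary, so the total current -dV/dt crosses zero there;
* a linear phase-2 plateau decay to ``v_ph2_end``;
* a linear phase-3 fall that passes through the APD90 level exactly
  ``ph3_ms`` after the phase-2 end, then an exponential tail back to rest;
* a Gaussian I_K1 bump peaking in phase 3 whose rising 10 %-of-peak
  crossing is placed exactly at the phase-2/3 boundary.

I_tot is the analytic -dV/dt of the noise-free waveform; the remainder
I_tot - I_K1 is booked under I_Kr so the per-current series still sum to
I_tot.  These traces are test plumbing for the feature-extraction and
dispersion stages, not biophysics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trace import BeatTrace, CURRENT_NAMES
from .ap_features import PhaseDurations, APFeatures

_SQRT_2LN10 = math.sqrt(2.0 * math.log(10.0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic beat; durations in ms, potentials in mV."""

    v_rest: float = -88.0
    v_peak: float = 32.0
    upstroke_ms: float = 2.0
    ph1_ms: float = 30.0
    ph2_ms: float = 160.0
    ph3_ms: float = 36.0
    notch_depth: float = 12.0     # spike-to-notch drop
    dome_drop: float = 4.0        # V_peak - dome potential (>= 0)
    v_ph2_end: float = -39.0      # potential at the phase-2/3 boundary
    ik1_peak: float = 2.5         # pA/pF
    tail_tau: float = 8.0         # ms, exponential return to rest
    bcl: float = 1000.0
    dt: float = 0.1
    noise_sd: float = 0.0         # mV, Gaussian noise on V_m only
    seed: int = 0

    def __post_init__(self):
        if min(self.upstroke_ms, self.ph1_ms, self.ph2_ms, self.ph3_ms) <= 0:
            raise ValueError("all phase durations must be positive")
        if self.v_peak <= self.v_rest:
            raise ValueError("v_peak must exceed v_rest")
        dome = self.v_peak - self.dome_drop
        notch = self.v_peak - self.notch_depth
        if not (notch < dome <= self.v_peak):
            raise ValueError("need notch below dome and dome at or below peak")
        apa = self.v_peak - self.v_rest
        v90 = self.v_peak - 0.9 * apa
        if not (v90 < self.v_ph2_end < dome):
            raise ValueError("v_ph2_end must lie between the APD90 level and the dome")
        if self.upstroke_ms + self.ph1_ms + self.ph2_ms + self.ph3_ms >= self.bcl:
            raise ValueError("phases exceed one BCL")

    # ---- exact boundary times -------------------------------------------
    @property
    def t_peak(self) -> float:
        return self.upstroke_ms

    @property
    def t_ph1_end(self) -> float:
        return self.upstroke_ms + self.ph1_ms

    @property
    def t_ph2_end(self) -> float:
        return self.t_ph1_end + self.ph2_ms

    @property
    def t_apd90(self) -> float:
        return self.t_ph2_end + self.ph3_ms

    @property
    def apa(self) -> float:
        return self.v_peak - self.v_rest

    @property
    def apd(self) -> float:
        return self.ph1_ms + self.ph2_ms + self.ph3_ms

    def ground_truth(self) -> tuple[PhaseDurations, APFeatures]:
        ph = PhaseDurations(
            ph1_ms=self.ph1_ms, ph2_ms=self.ph2_ms, ph3_ms=self.ph3_ms,
            t_ph1_end=self.t_ph1_end, t_ph2_end=self.t_ph2_end,
            t_apd90=self.t_apd90, t_peak=self.t_peak)
        ap = APFeatures(apd=self.apd, apa=self.apa, v_peak=self.v_peak,
                        v_rest=self.v_rest, v_ph2_end=self.v_ph2_end)
        return ph, ap


def _waveform(spec: SyntheticSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free V(t) and its analytic derivative dV/dt on the grid."""
    v = np.full_like(t, spec.v_rest)
    dv = np.zeros_like(t)
    tp, t1, t2, t3 = spec.t_peak, spec.t_ph1_end, spec.t_ph2_end, spec.t_apd90
    dome = spec.v_peak - spec.dome_drop
    notch = spec.v_peak - spec.notch_depth
    # notch minimum: the notch is a fast transient-outward episode, a few ms
    # long regardless of how long the dome rise (phase 1) lasts
    tn = tp + min(0.4 * spec.ph1_ms, 8.0)

    # phase 0: linear upstroke
    m0 = (t >= 0) & (t < tp)
    s0 = (spec.v_peak - spec.v_rest) / tp
    v[m0] = spec.v_rest + s0 * t[m0]
    dv[m0] = s0
    # notch fall (linear)
    mN = (t >= tp) & (t < tn)
    sN = (notch - spec.v_peak) / (tn - tp)
    v[mN] = spec.v_peak + sN * (t[mN] - tp)
    dv[mN] = sN
    # dome rise: parabola with maximum exactly at t1, so -dV/dt crosses 0 there
    mD = (t >= tn) & (t < t1)
    b = (dome - notch) / (t1 - tn) ** 2
    v[mD] = dome - b * (t1 - t[mD]) ** 2
    dv[mD] = 2.0 * b * (t1 - t[mD])
    # phase 2: linear plateau decay
    m2 = (t >= t1) & (t < t2)
    s2 = (spec.v_ph2_end - dome) / (t2 - t1)
    v[m2] = dome + s2 * (t[m2] - t1)
    dv[m2] = s2
    # phase 3: linear fall through the APD90 level exactly at t3
    v90 = spec.v_peak - 0.9 * spec.apa
    s3 = (v90 - spec.v_ph2_end) / (t3 - t2)
    v_tail_start = spec.v_rest + 0.02 * spec.apa   # hand over to the tail here
    t_tail = t3 + (v_tail_start - v90) / s3
    m3 = (t >= t2) & (t < t_tail)
    v[m3] = spec.v_ph2_end + s3 * (t[m3] - t2)
    dv[m3] = s3
    # exponential relaxation to rest (continuous in value)
    mT = t >= t_tail
    v[mT] = spec.v_rest + (v_tail_start - spec.v_rest) * np.exp(
        -(t[mT] - t_tail) / spec.tail_tau)
    dv[mT] = -(v[mT] - spec.v_rest) / spec.tail_tau
    return v, dv


def make_trace(spec: SyntheticSpec) -> tuple[BeatTrace, PhaseDurations, APFeatures]:
    """Build one synthetic beat plus its exact ground truth.

    With ``noise_sd == 0`` the trace is deterministic; otherwise Gaussian
    noise (seeded) is added to V_m only, so the ground truth is unchanged.
    """
    n = int(round(spec.bcl / spec.dt))
    t = np.arange(n) * spec.dt
    v, dv = _waveform(spec, t)
    itot = -dv

    # I_K1 bump: Gaussian peaking in phase 3 whose rising 10%-of-peak
    # crossing sits exactly at the phase-2 end
    t_pk3 = spec.t_ph2_end + 0.6 * spec.ph3_ms
    sigma = (t_pk3 - spec.t_ph2_end) / _SQRT_2LN10
    ik1 = spec.ik1_peak * np.exp(-0.5 * ((t - t_pk3) / sigma) ** 2)

    currents = np.zeros((n, len(CURRENT_NAMES)))
    currents[:, CURRENT_NAMES.index("IK1")] = ik1
    currents[:, CURRENT_NAMES.index("IKr")] = itot - ik1   # keep the sum exact

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=n)

    trace = BeatTrace(
        t=t, v=v, currents=currents, itot=itot,
        i_stim=np.zeros(n), i_inject=np.zeros(n),
        cai=np.full(n, 1e-4), nai=np.full(n, 7.0), bcl=spec.bcl,
        meta={"synthetic": True, "spec": {k: getattr(spec, k)
                                          for k in spec.__dataclass_fields__}})
    ph, ap = spec.ground_truth()
    return trace, ph, ap


def make_cell_family(spec_epi: SyntheticSpec, spec_mid: SyntheticSpec,
                     spec_endo: SyntheticSpec):
    """Three synthetic beats plus the exact transmural dispersion.

    Returns ``(traces, truths, dispersion)`` where dispersion is the
    maximum pairwise ground-truth APD difference.
    """
    out = {name: make_trace(s) for name, s in
           [("EPI", spec_epi), ("MID", spec_mid), ("ENDO", spec_endo)]}
    traces = {k: v[0] for k, v in out.items()}
    truths = {k: (v[1], v[2]) for k, v in out.items()}
    apds = [v[2].apd for v in out.values()]
    dispersion = float(max(apds) - min(apds))
    return traces, truths, dispersion


#: ready-made control-like presets (APDs mirror the control transmural
#: ordering; these are synthetic stand-ins, not model output)
PRESETS = {
    "epi-control": SyntheticSpec(ph1_ms=35.0, ph2_ms=160.0, ph3_ms=36.0),
    "mid-control": SyntheticSpec(ph1_ms=33.0, ph2_ms=254.0, ph3_ms=47.0,
                                 v_peak=36.0, dome_drop=2.0),
    "endo-control": SyntheticSpec(ph1_ms=34.0, ph2_ms=200.0, ph3_ms=42.0),
}
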