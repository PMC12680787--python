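"""Action-potential phase segmentation and feature extraction.

Phases are delimited by current-based rules on a single-beat trace:

* phase 1 runs from the end of depolarization (the instant of V_m,peak) to
  the start of sustained repolarization, detected as the upward
  zero-crossing of the total ionic current I_tot after which I_tot stays
  positive (the spike-notch-dome transient produces earlier, short-lived
  positive episodes that do not count);
* phase 2 ends when I_K1 rises to 10% of its within-beat peak (the peak is
  taken outside the stimulus window);
* phase 3 ends at 90% repolarization of the action-potential amplitude
  (APA = V_m,peak - V_m,rest) from V_m,peak.

APD is the phase-1 start to the APD90 crossing, so APD = ph1 + ph2 + ph3
exactly.  All boundary times are refined by linear interpolation between
samples of the 0.1 ms output grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace import BeatTrace, CURRENT_NAMES, cross_down, cross_up

#: current grouping for phase-averaged currents (inward negative). The two
#: groups partition the full current set so I_dep + I_rep = I_tot exactly.
DEPOLARIZING = ("INa", "INaL", "ICaL", "ICaNa", "INaCa", "INab", "ICab")
REPOLARIZING = ("Ito", "IKr", "IKs", "IK1", "INaK", "IKb", "ICaK", "IpCa")


class FeatureError(ValueError):
    """A trace cannot be segmented (no AP, or repolarization incomplete)."""


@dataclass(frozen=True)
class PhaseDurations:
    ph1_ms: float
    ph2_ms: float
    ph3_ms: float
    t_ph1_end: float
    t_ph2_end: float
    t_apd90: float
    t_peak: float

    def __post_init__(self):
        if not (self.t_peak < self.t_ph1_end < self.t_ph2_end < self.t_apd90):
            raise FeatureError("phase boundaries must be strictly increasing")


@dataclass(frozen=True)
class APFeatures:
    apd: float          # ms, V_m,peak time -> APD90 crossing
    apa: float          # mV
    v_peak: float       # mV
    v_rest: float       # mV
    v_ph2_end: float    # mV, potential at the phase-2/3 boundary


@dataclass(frozen=True)
class PhaseCurrents:
    """Time-averaged currents over the phase-2+3 repolarization window."""

    i_tot: float
    i_dep: float
    i_rep: float
    per_current: dict = field(default_factory=dict)
    window: tuple = (float("nan"), float("nan"))


@dataclass(frozen=True)
class HyperbolaFit:
    """Least-squares fit of I = K / duration (K in mV)."""

    K: float
    r2: float
    residuals: np.ndarray


def _phase0_end(v: np.ndarray) -> int:
    """Index of the end of depolarization: the first local maximum of V_m at
    or after the upstroke (the phase-0 spike).

    In mid-myocardial cells the plateau dome can exceed the spike, so the
    global maximum is not a reliable phase-0 marker.
    """
    i_up = int(np.argmax(np.diff(v)))
    k = i_up
    n = v.size - 1
    while k < n and v[k + 1] > v[k]:
        k += 1
    return k


def _ik1_peak(trace: BeatTrace) -> float:
    ik1 = trace.current("IK1")
    mask = trace.i_stim == 0.0
    return float(ik1[mask].max()) if mask.any() else float(ik1.max())


def segment_phases(trace: BeatTrace, ik1_fraction: float = 0.10,
                   sustain_ms: float = 15.0) -> PhaseDurations:
    """Segment one captured beat into phases 1/2/3.

    ``sustain_ms`` is the minimum run of positive I_tot required for an
    upward zero-crossing to count as the start of sustained repolarization
    (phase-1 end); shorter positive episodes belong to the notch.

    Raises :class:`FeatureError` if no AP was elicited, if repolarization
    never starts, or if the APD90 level is not reached within the trace
    ("repolarization incomplete").
    """
    t, v, itot = trace.t, trace.v, trace.itot
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    if v_peak <= 0.0:
        raise FeatureError("no action potential (V_m never exceeds 0 mV)")
    i_spike = _phase0_end(v)
    v_rest = float(v[0])
    v90 = v_peak - 0.9 * (v_peak - v_rest)
    t_apd90 = cross_down(t, v, v90, start=i_peak)
    if not np.isfinite(t_apd90):
        raise FeatureError("repolarization incomplete (APD90 never reached)")

    # phase-2 end: first I_K1 crossing of the 10%-of-peak level after V peak
    ik1 = trace.current("IK1")
    ik1_pk = _ik1_peak(trace)
    if ik1_pk <= 0:
        raise FeatureError("I_K1 has no positive peak")
    t_ph2_end = cross_up(t, ik1, ik1_fraction * ik1_pk, start=i_spike)
    if not np.isfinite(t_ph2_end) or t_ph2_end > t_apd90:
        raise FeatureError("I_K1 never reaches the phase-2 end level in the beat")

    # phase-1 end: upward zero-crossing of I_tot followed by >= sustain_ms
    # of positivity, searched between the spike and the phase-2 end
    dt = trace.dt
    nsus = max(1, int(round(sustain_ms / dt)))
    k2 = int(t_ph2_end / dt)
    pos = itot > 0.0
    t_ph1_end = float("nan")
    k = i_spike + 1
    while k < k2:
        if pos[k] and not pos[k - 1]:
            run_end = min(k + nsus, len(pos))
            if pos[k:run_end].all():
                # interpolate the zero crossing between k-1 and k
                y0, y1 = itot[k - 1], itot[k]
                t_ph1_end = float(t[k - 1] + (0.0 - y0) / (y1 - y0) * dt)
                break
        k += 1
    if not np.isfinite(t_ph1_end):
        # fall back to the last upward crossing before the phase-2 end;
        # if I_tot is positive throughout (repolarization starts at the
        # spike itself) the boundary is the spike
        ks = np.flatnonzero(pos[i_spike + 1:k2] & ~pos[i_spike:k2 - 1]) + i_spike + 1
        if ks.size > 0:
            k = int(ks[-1])
            y0, y1 = itot[k - 1], itot[k]
            t_ph1_end = float(t[k - 1] + (0.0 - y0) / (y1 - y0) * dt)
        elif pos[i_spike + 1:k2].all():
            t_ph1_end = float(t[i_spike]) + 0.5 * dt
        else:
            raise FeatureError(
                "total current never becomes positive (repolarization failure)")

    t_pk = float(t[i_spike])
    return PhaseDurations(
        ph1_ms=t_ph1_end - t_pk, ph2_ms=t_ph2_end - t_ph1_end,
        ph3_ms=t_apd90 - t_ph2_end, t_ph1_end=t_ph1_end,
        t_ph2_end=t_ph2_end, t_apd90=t_apd90, t_peak=t_pk)


def ap_metrics(trace: BeatTrace) -> APFeatures:
    """Whole-beat AP features.

    APD runs from the end of depolarization (the phase-0 spike, which is
    also the phase-1 start) to the APD90 crossing, so it equals
    ph1 + ph2 + ph3 exactly.  APA uses the maximum depolarization
    potential, i.e. the global V_m maximum (spike or dome).
    """
    t, v = trace.t, trace.v
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    if v_peak <= 0.0:
        raise FeatureError("no action potential (V_m never exceeds 0 mV)")
    i_spike = _phase0_end(v)
    v_rest = float(v[0])
    apa = v_peak - v_rest
    v90 = v_peak - 0.9 * apa
    t_apd90 = cross_down(t, v, v90, start=i_peak)
    if not np.isfinite(t_apd90):
        raise FeatureError("repolarization incomplete (APD90 never reached)")
    try:
        ph = segment_phases(trace)
        v_ph2 = float(np.interp(ph.t_ph2_end, t, v))
    except FeatureError:
        v_ph2 = float("nan")
    return APFeatures(apd=t_apd90 - float(t[i_spike]), apa=apa, v_peak=v_peak,
                      v_rest=v_rest, v_ph2_end=v_ph2)


def phase_mean_currents(trace: BeatTrace, phases: PhaseDurations,
                        depolarizing: tuple = DEPOLARIZING,
                        repolarizing: tuple = REPOLARIZING) -> PhaseCurrents:
    """Time-averaged currents over the phase-2+3 window [t_ph1_end, t_apd90]."""
    t = trace.t
    sel = (t >= phases.t_ph1_end) & (t <= phases.t_apd90)
    if not sel.any():
        raise FeatureError("empty phase-2+3 averaging window")
    per = {name: float(trace.current(name)[sel].mean()) for name in CURRENT_NAMES}
    i_dep = sum(per[n] for n in depolarizing)
    i_rep = sum(per[n] for n in repolarizing)
    return PhaseCurrents(i_tot=float(trace.itot[sel].mean()), i_dep=i_dep,
                         i_rep=i_rep, per_current=per,
                         window=(phases.t_ph1_end, phases.t_apd90))


def fit_hyperbola(points) -> HyperbolaFit:
    """Fit I = K/d by least squares to (duration, mean-current) pairs.

    The model is linear in K, so the optimum is closed-form:
    K = sum(I_i/d_i) / sum(1/d_i^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (duration, current) points")
    d, i = pts[:, 0], pts[:, 1]
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    K = float(np.sum(i / d) / np.sum(1.0 / d ** 2))
    pred = K / d
    res = i - pred
    ss_tot = float(np.sum((i - i.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return HyperbolaFit(K=K, r2=r2, residuals=res)


def ca_transient_amplitude(trace: BeatTrace) -> float:
    """Peak-to-trough amplitude of the intracellular Ca2+ transient (mM)."""
    return float(trace.cai.max() - trace.cai.min())
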