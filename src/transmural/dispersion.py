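"""Transmural dispersion, repolarization reserve, and abnormality detection.

Transmural dispersion of repolarization is the single-cell proxy used
throughout: the maximum pairwise APD difference among the epicardial,
mid-myocardial and endocardial variants paced to steady state under the
same conductance scaling and BCL (cell-to-cell coupling and conduction are
out of scope by construction).

Repolarization reserve is probed by re-simulating the steady beat with a
constant depolarizing current (default -0.1 pA/pF) active from stimulus
onset until the injected beat's own APD90 crossing (found by fixed-point
iteration); the APD prolongation is the reserve deficit - larger
prolongation means less reserve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ord as _ord
from .ord import CellType, Scaling, PacingConfig, SimulationError
from .ap_features import ap_metrics, segment_phases, FeatureError
from .trace import BeatTrace, cross_down


@dataclass(frozen=True)
class Abnormality:
    abnormal: bool
    kind: str | None = None     # "ead" | "repolarization_failure" | "no_capture"


@dataclass(frozen=True)
class DispersionResult:
    apds: dict                  # cell label -> APD90 (ms)
    dispersion: float           # ms, max pairwise difference
    bcl: float
    scaling: dict
    valid: bool = True
    flags: dict = field(default_factory=dict)

    @property
    def apd_epi(self):
        return self.apds.get("EPI")

    @property
    def apd_mid(self):
        return self.apds.get("MID")

    @property
    def apd_endo(self):
        return self.apds.get("ENDO")


@dataclass(frozen=True)
class ReserveResult:
    apd_baseline: float
    apd_injected: float
    delta_apd: float            # ms; the reserve deficit
    i_inject: float
    failed: bool = False        # injection caused repolarization failure


def dispersion_from_apds(apds) -> float:
    """Max pairwise |APD difference|; permutation-invariant and >= 0."""
    vals = np.asarray(list(apds.values()) if isinstance(apds, dict) else apds,
                      dtype=float)
    return float(vals.max() - vals.min())


def detect_abnormality(trace: BeatTrace, ead_rise_mv: float = 2.0) -> Abnormality:
    """Flag EADs, repolarization failure, or capture failure on one beat.

    An EAD is a local minimum of V_m between the phase-1 end and the APD90
    crossing followed by a rise of more than ``ead_rise_mv``; the rise
    threshold guards against solver ripple.
    """
    v = trace.v
    if v.max() <= 0.0:
        return Abnormality(True, "no_capture")
    i_peak = int(np.argmax(v))
    v90 = v.max() - 0.9 * (v.max() - v[0])
    t90 = cross_down(trace.t, v, v90, start=i_peak)
    if not np.isfinite(t90):
        return Abnormality(True, "repolarization_failure")
    try:
        ph = segment_phases(trace)
        t_start = ph.t_ph1_end
    except FeatureError:
        t_start = float(trace.t[i_peak])
    sel = (trace.t >= t_start) & (trace.t <= t90)
    w = v[sel]
    if w.size > 2:
        run_min = np.minimum.accumulate(w)
        if np.max(w - run_min) > ead_rise_mv:
            return Abnormality(True, "ead")
    return Abnormality(False, None)


def transmural_dispersion(scaling: Scaling | None = None, bcl: float = 1000.0,
                          cells=("EPI", "MID", "ENDO"),
                          pacing: PacingConfig | None = None) -> DispersionResult:
    """Pace each cell type to steady state and measure the APD spread.

    Any abnormal beat marks the result invalid (``valid=False``); APDs are
    still reported where measurable.
    """
    scaling = scaling or _ord.CONTROL
    pc = pacing or PacingConfig(bcl=bcl)
    apds, flags = {}, {}
    for cell in cells:
        label = CellType.parse(cell).name
        try:
            trace, diag, _ = _ord.steady_beat(label, scaling, bcl, pacing=pc)
        except SimulationError as e:
            flags[label] = str(e)
            apds[label] = float("nan")
            continue
        ab = detect_abnormality(trace)
        if ab.abnormal:
            flags[label] = ab.kind
        try:
            apds[label] = ap_metrics(trace).apd
        except FeatureError as e:
            flags[label] = flags.get(label) or str(e)
            apds[label] = float("nan")
    finite = {k: v for k, v in apds.items() if np.isfinite(v)}
    disp = dispersion_from_apds(finite) if len(finite) >= 2 else float("nan")
    return DispersionResult(apds=apds, dispersion=disp, bcl=float(pc.bcl),
                            scaling=scaling.as_dict(), valid=not flags,
                            flags=flags)


def repolarization_reserve(cell, scaling: Scaling | None = None,
                           bcl: float = 1000.0, i_inject: float = -0.1,
                           pacing: PacingConfig | None = None,
                           max_iter: int = 6, tol_ms: float = 0.2) -> ReserveResult:
    """Reserve deficit: APD prolongation under a constant depolarizing current.

    The injection window [stimulus onset, APD90 of the injected beat] is
    self-consistent: starting from the full BCL it is shrunk to the measured
    APD90 crossing until the crossing moves by less than ``tol_ms``.  The
    challenge is acute - one beat on top of the drug-condition steady state,
    with no re-equilibration.
    """
    scaling = scaling or _ord.CONTROL
    pc = pacing or PacingConfig(bcl=bcl)
    base_trace, diag, y_ss = _ord.steady_beat(cell, scaling, bcl, pacing=pc)
    base = ap_metrics(base_trace)
    if detect_abnormality(base_trace).abnormal:
        raise SimulationError("baseline beat is abnormal; reserve undefined")
    amp = diag["stim_amplitude"]
    if i_inject == 0.0:
        return ReserveResult(base.apd, base.apd, 0.0, 0.0)

    inj_end = float(pc.bcl)
    apd_inj = float("nan")
    for _ in range(max_iter):
        tr, _ = _ord.simulate_beat(y_ss, cell, scaling, pc, amp,
                                   i_inject=i_inject, inj_end=inj_end)
        try:
            m = ap_metrics(tr)
        except FeatureError:
            return ReserveResult(base.apd, float("inf"), float("inf"),
                                 i_inject, failed=True)
        i_peak = int(np.argmax(tr.v))
        t90 = cross_down(tr.t, tr.v, m.v_peak - 0.9 * m.apa, start=i_peak)
        apd_inj = m.apd
        if abs(t90 - inj_end) < tol_ms:
            break
        inj_end = t90
    return ReserveResult(base.apd, apd_inj, apd_inj - base.apd, i_inject)
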