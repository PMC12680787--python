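"""Particle swarm optimization over the conductance-scaling space.

A ring-topology PSO (20 particles, neighborhood 10, linearly decreasing
inertia, 50 iterations) searches the 7-dimensional multiplier space for
combinations that minimize transmural APD dispersion, optionally holding
one cell type's APD near a target.  Candidate combinations that produce
early afterdepolarizations or other repolarization abnormalities receive a
large finite penalty, which is how "discarded" solutions are kept out of
the swarm's memory.

The evaluation backend is injectable: :class:`ORdBackend` paces the full
biophysical model (expensive; results are memoized), while
:class:`SurrogateBackend` is a cheap analytic stand-in with the same
qualitative structure, used for desk-scale optimizer and elimination
studies and for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import ord as _ord
from .ord import Scaling, SCALED_CURRENTS, SCALING_BOUNDS, PacingConfig, SimulationError
from .ap_features import ap_metrics, FeatureError
from .dispersion import detect_abnormality

#: finite penalty standing in for "discarded" abnormal/failed candidates
PENALTY = 1.0e4


# --------------------------------------------------------------------------
# evaluation backends: scaling -> per-cell APDs (+ abnormality flags)
# --------------------------------------------------------------------------


class ORdBackend:
    """Evaluate candidate scalings on the full ORd model.

    Returns per-cell APD90s of the steady-state beat; a cell is reported
    abnormal if its beat shows an EAD, repolarization failure, or loss of
    capture.  Steady states are memoized per (cell, scaling, BCL).
    """

    def __init__(self, bcl: float = 1000.0, cells=("EPI", "MID"),
                 pacing: PacingConfig | None = None):
        self.bcl = float(bcl)
        self.cells = tuple(cells)
        self.pacing = pacing or PacingConfig(bcl=bcl)

    def __call__(self, scaling: Scaling) -> dict:
        apds, abnormal = {}, False
        for cell in self.cells:
            try:
                trace, _, _ = _ord.steady_beat(cell, scaling, self.bcl,
                                               pacing=self.pacing)
                if detect_abnormality(trace).abnormal:
                    abnormal = True
                apds[cell] = ap_metrics(trace).apd
            except (SimulationError, FeatureError):
                abnormal = True
                apds[cell] = float("nan")
        return {"apds": apds, "abnormal": abnormal}


class SurrogateBackend:
    """Synthetic stand-in for the simulator (not biophysical).

    APDs respond monotonically to each multiplier with cell-type-specific
    sensitivities whose signs and rough magnitudes mirror the transmural
    physiology (blocking repolarizing currents prolongs APD, more so in
    MID for I_Kr; blocking depolarizing currents shortens APD, more so in
    MID).  Control reproduces APDs of 231/334/265 ms so surrogate studies
    live on a familiar scale.
    """

    #: d(APD)/d(x) around control, ms per unit multiplier
    _SENS = {
        #            EPI     MID    ENDO
        "INaL":   (  12.0,   35.0,  20.0),
        "ICaL":   (  30.0,   60.0,  40.0),
        "IKs":    (  -1.2,   -2.8,  -1.6),
        "IKr":    ( -90.0, -130.0, -105.0),
        "IK1":    ( -10.0,  -14.0,  -12.0),
        "INaK":   (  -8.0,  -16.0,  -11.0),
        "INaCa":  (  14.0,   30.0,  20.0),
    }
    _CONTROL_APD = {"EPI": 231.0, "MID": 334.0, "ENDO": 265.0}

    def __init__(self, bcl: float = 1000.0, cells=("EPI", "MID")):
        self.bcl = float(bcl)
        self.cells = tuple(cells)

    def __call__(self, scaling: Scaling) -> dict:
        x = scaling.as_dict()
        apds = {}
        for ci, cell in enumerate(("EPI", "MID", "ENDO")):
            if cell not in self.cells:
                continue
            apd = self._CONTROL_APD[cell]
            for name, sens in self._SENS.items():
                dx = x[name] - 1.0
                # saturating response keeps strong activators bounded
                apd += sens[ci] * math.tanh(dx) if name == "IKs" else sens[ci] * dx
            apds[cell] = apd
        # crude EAD proxy: strong IKr block with enhanced ICaL
        abnormal = x["IKr"] < 0.05 and x["ICaL"] > 1.3 and x["IKs"] < 2.0
        return {"apds": apds, "abnormal": abnormal}


# --------------------------------------------------------------------------
# objective
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Objective:
    """Optimization goal over the (EPI, MID) APD pair.

    ``min_dispersion`` minimizes |APD_EPI - APD_MID|; the target modes add
    |APD_cell - apd_target| for the named cell; ``combined`` targets both
    cells.  Abnormal or failed evaluations receive :data:`PENALTY`.
    """

    mode: str = "min_dispersion"   # min_dispersion | epi_target | mid_target | combined
    apd_target: float | None = None
    bcl: float = 1000.0
    penalty: float = PENALTY

    def __post_init__(self):
        if self.mode not in ("min_dispersion", "epi_target", "mid_target", "combined"):
            raise ValueError(f"unknown objective mode {self.mode!r}")
        if self.mode != "min_dispersion" and self.apd_target is None:
            raise ValueError(f"mode {self.mode!r} needs apd_target")


def evaluate_objective(scaling: Scaling, objective: Objective, backend) -> float:
    """Scalar objective for one candidate scaling (lower is better)."""
    out = backend(scaling)
    apds = out["apds"]
    if out.get("abnormal") or any(not np.isfinite(v) for v in apds.values()):
        return objective.penalty
    val = abs(apds["EPI"] - apds["MID"])
    if objective.mode == "epi_target":
        val += abs(apds["EPI"] - objective.apd_target)
    elif objective.mode == "mid_target":
        val += abs(apds["MID"] - objective.apd_target)
    elif objective.mode == "combined":
        val += (abs(apds["EPI"] - objective.apd_target)
                + abs(apds["MID"] - objective.apd_target))
    return float(val)


# --------------------------------------------------------------------------
# particle swarm
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PSOConfig:
    n_particles: int = 20
    neighborhood_size: int = 10     # ring: size//2 neighbors on each side
    n_iterations: int = 50
    c_cognitive: float = 1.49618
    c_social: float = 1.49618
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    seed: int = 0
    blockers_only: bool = False
    #: optional (n_dim, 2) bounds; default = Methods ranges for the 7 currents
    bounds: tuple | None = None
    memo_decimals: int = 4

    def resolve_bounds(self, dims=SCALED_CURRENTS) -> np.ndarray:
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
        else:
            b = np.array([SCALING_BOUNDS[d] for d in dims], dtype=float)
            if self.blockers_only:
                b[:, 1] = np.minimum(b[:, 1], 1.0)
        if np.any(b[:, 0] > b[:, 1]):
            raise ValueError("lower bound exceeds upper bound")
        return b

    def __post_init__(self):
        if self.neighborhood_size > self.n_particles:
            raise ValueError("neighborhood_size must be <= n_particles")


@dataclass
class PSOResult:
    x: np.ndarray            # best position found
    value: float             # best objective value
    history: list            # per-iteration swarm-best value
    n_evaluations: int
    config: PSOConfig


def pso_minimize(f, config: PSOConfig, dims=SCALED_CURRENTS,
                 x0: np.ndarray | None = None) -> PSOResult:
    """Minimize ``f(x)`` over a box with a ring-topology particle swarm.

    Deterministic for a given ``config.seed``.  ``x0`` optionally seeds one
    particle (e.g. a warm start from a parent optimization).  Positions are
    clamped to the box with the offending velocity component zeroed, so the
    swarm can never evaluate outside the bounds.
    """
    bounds = config.resolve_bounds(dims)
    nd = bounds.shape[0]
    npart = config.n_particles
    rng = np.random.default_rng(config.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo

    x = lo + rng.random((npart, nd)) * span
    if x0 is not None:
        x[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    vmax = 0.5 * span
    v = (rng.random((npart, nd)) - 0.5) * span * 0.2

    memo: dict = {}
    n_eval = 0

    def feval(xi):
        nonlocal n_eval
        key = tuple(np.round(xi, config.memo_decimals))
        if key not in memo:
            memo[key] = float(f(xi))
            n_eval += 1
        return memo[key]

    pbest_x = x.copy()
    pbest_v = np.array([feval(xi) for xi in x])
    half = max(1, config.neighborhood_size // 2)
    neigh = [np.arange(i - half, i + half + 1) % npart for i in range(npart)]

    history = []
    best_so_far = float(pbest_v.min())
    for it in range(config.n_iterations):
        w = (config.inertia_start
             + (config.inertia_end - config.inertia_start)
             * (it / max(1, config.n_iterations - 1)))
        # neighborhood best (ring)
        lbest_x = np.empty_like(x)
        for i in range(npart):
            j = neigh[i][np.argmin(pbest_v[neigh[i]])]
            lbest_x[i] = pbest_x[j]
        r1 = rng.random((npart, nd))
        r2 = rng.random((npart, nd))
        v = (w * v + config.c_cognitive * r1 * (pbest_x - x)
             + config.c_social * r2 * (lbest_x - x))
        np.clip(v, -vmax, vmax, out=v)
        x = x + v
        # clamp to the box, zeroing the offending velocity component
        under, over = x < lo, x > hi
        v[under | over] = 0.0
        np.clip(x, lo, hi, out=x)
        for i in range(npart):
            fi = feval(x[i])
            if fi < pbest_v[i]:
                pbest_v[i] = fi
                pbest_x[i] = x[i]
        best_so_far = min(best_so_far, float(pbest_v.min()))
        history.append(best_so_far)

    i_best = int(np.argmin(pbest_v))
    return PSOResult(x=pbest_x[i_best].copy(), value=float(pbest_v[i_best]),
                     history=history, n_evaluations=n_eval, config=config)


def optimize_scaling(objective: Objective, config: PSOConfig, backend=None,
                     active: tuple = SCALED_CURRENTS,
                     x0: Scaling | None = None):
    """PSO over the scaling multipliers of the ``active`` currents.

    Inactive currents are pinned at control (1.0).  Returns
    ``(Scaling, PSOResult)``.
    """
    backend = backend or ORdBackend(bcl=objective.bcl)
    active = tuple(active)
    idx = [SCALED_CURRENTS.index(a) for a in active]

    def to_scaling(xa: np.ndarray) -> Scaling:
        full = np.ones(len(SCALED_CURRENTS))
        for k, i in enumerate(idx):
            full[i] = xa[k]
        return Scaling(*full)

    def f(xa):
        return evaluate_objective(to_scaling(xa), objective, backend)

    sub_bounds = config.resolve_bounds(SCALED_CURRENTS)[idx] \
        if config.bounds is None else config.resolve_bounds(active)
    cfg = replace(config, bounds=tuple(map(tuple, sub_bounds)))
    x0a = None
    if x0 is not None:
        x0a = x0.as_array()[idx]
    res = pso_minimize(f, cfg, dims=active, x0=x0a)
    return to_scaling(res.x), res
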