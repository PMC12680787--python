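"""Population-of-models dispersion maps over two conductance dimensions.

Samples candidate models by uniformly varying two chosen conductance
multipliers (all others fixed), evaluates per-cell APDs and transmural
dispersion at each point, and flags the rows whose epicardial APD falls
inside a target window with no repolarization abnormality - the
population-of-models construction behind dispersion maps conditioned on a
fixed APD prolongation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .ord import Scaling, SCALED_CURRENTS, SCALING_BOUNDS
from .optimize import ORdBackend
from .dispersion import dispersion_from_apds


@dataclass(frozen=True)
class DimSpec:
    """One sampled dimension: a current name and its multiplier range."""

    current: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.current not in SCALED_CURRENTS:
            raise ValueError(f"unknown current {self.current!r}")
        blo, bhi = SCALING_BOUNDS[self.current]
        if not (blo <= self.lo <= self.hi <= bhi):
            raise ValueError(
                f"range [{self.lo},{self.hi}] outside bounds [{blo},{bhi}] "
                f"for {self.current}")


def _set(scaling: Scaling, current: str, value: float) -> Scaling:
    field = ("inal", "ical", "iks", "ikr", "ik1", "inak", "inaca")[
        SCALED_CURRENTS.index(current)]
    return replace(scaling, **{field: float(value)})


def sample_map(dim1: DimSpec, dim2: DimSpec, fixed: Scaling | None = None,
               apd_window: tuple = (270.0, 5.0), n_samples: int = 500,
               seed: int = 0, bcl: float = 1000.0, backend=None,
               grid: bool = False) -> pd.DataFrame:
    """Sample the (dim1, dim2) plane and tabulate APDs and dispersion.

    ``apd_window`` is (center, half-width) in ms on the epicardial APD;
    ``accepted`` marks rows inside the window with no abnormality.  With
    ``grid=True`` the points sit on a regular sqrt(n) x sqrt(n) lattice
    instead of being drawn uniformly (seed then only recorded).  Returns a
    DataFrame with columns x1, x2, apd_epi, apd_mid, apd_endo, dispersion,
    abnormal, accepted.
    """
    backend = backend or ORdBackend(bcl=bcl, cells=("EPI", "MID", "ENDO"))
    fixed = fixed or Scaling()
    center, tol = float(apd_window[0]), float(apd_window[1])
    if grid:
        k = max(2, int(round(np.sqrt(n_samples))))
        g1, g2 = np.meshgrid(np.linspace(dim1.lo, dim1.hi, k),
                             np.linspace(dim2.lo, dim2.hi, k))
        x1, x2 = g1.ravel(), g2.ravel()
    else:
        rng = np.random.default_rng(seed)
        x1 = rng.uniform(dim1.lo, dim1.hi, n_samples)
        x2 = rng.uniform(dim2.lo, dim2.hi, n_samples)

    rows = []
    for a, b in zip(x1, x2):
        sc = _set(_set(fixed, dim1.current, a), dim2.current, b)
        out = backend(sc)
        apds = out["apds"]
        finite = {k: v for k, v in apds.items() if np.isfinite(v)}
        disp = dispersion_from_apds(finite) if len(finite) >= 2 else np.nan
        abnormal = bool(out.get("abnormal"))
        apd_epi = apds.get("EPI", np.nan)
        accepted = (not abnormal and np.isfinite(apd_epi)
                    and abs(apd_epi - center) <= tol)
        rows.append({"x1": a, "x2": b, "apd_epi": apd_epi,
                     "apd_mid": apds.get("MID", np.nan),
                     "apd_endo": apds.get("ENDO", np.nan),
                     "dispersion": disp, "abnormal": abnormal,
                     "accepted": accepted})
    df = pd.DataFrame(rows)
    df.attrs.update({"dim1": dim1.current, "dim2": dim2.current, "bcl": bcl,
                     "apd_window": (center, tol), "seed": seed,
                     "sampling": "grid" if grid else "uniform"})
    if not df["accepted"].any():
        import warnings
        warnings.warn("no samples accepted by the APD window", stacklevel=2)
    return df
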