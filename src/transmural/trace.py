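"""Single-beat trace container and low-level waveform measurements.

A :class:`BeatTrace` holds one paced beat on a uniform output grid: membrane
potential, every membrane ionic current (outward positive, in pA/pF), the
total ionic current, the stimulus/injected currents, and the intracellular
Ca2+ and Na+ concentrations.  Both the biophysical simulator and the
synthetic-waveform generator emit this container, so all downstream
analytics (phase segmentation, APD, dispersion) are model-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Order of the per-current columns produced by the ORd right-hand side.
CURRENT_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK",
    "IKr", "IKs", "IK1", "INaCa", "INaK", "IKb", "INab", "ICab", "IpCa",
)


@dataclass
class BeatTrace:
    """One beat of a paced cell on a uniform time grid spanning one BCL."""

    t: np.ndarray                 # ms, t[0] = stimulus onset
    v: np.ndarray                 # mV
    currents: np.ndarray          # (n, len(CURRENT_NAMES)), pA/pF, outward > 0
    itot: np.ndarray              # pA/pF, sum of ionic currents (no stim/inject)
    i_stim: np.ndarray            # pA/pF (inward negative)
    i_inject: np.ndarray          # pA/pF
    cai: np.ndarray               # mM
    nai: np.ndarray               # mM
    bcl: float = float("nan")     # ms
    meta: dict = field(default_factory=dict)

    def current(self, name: str) -> np.ndarray:
        """Return one named ionic current series (e.g. ``"IKr"``)."""
        return self.currents[:, CURRENT_NAMES.index(name)]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular view using the CSV column contract."""
        data = {"t_ms": self.t, "Vm_mV": self.v}
        for j, name in enumerate(CURRENT_NAMES):
            data[f"{name}_pApF"] = self.currents[:, j]
        data["Itot_pApF"] = self.itot
        data["Istim_pApF"] = self.i_stim
        data["Iinject_pApF"] = self.i_inject
        data["Cai_mM"] = self.cai
        data["Nai_mM"] = self.nai
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bcl: float = float("nan"),
                   meta: dict | None = None) -> "BeatTrace":
        cur = np.column_stack([df[f"{n}_pApF"].to_numpy() for n in CURRENT_NAMES])
        return cls(
            t=df["t_ms"].to_numpy(float),
            v=df["Vm_mV"].to_numpy(float),
            currents=cur,
            itot=df["Itot_pApF"].to_numpy(float),
            i_stim=df["Istim_pApF"].to_numpy(float),
            i_inject=df["Iinject_pApF"].to_numpy(float),
            cai=df["Cai_mM"].to_numpy(float),
            nai=df["Nai_mM"].to_numpy(float),
            bcl=bcl,
            meta=dict(meta or {}),
        )


def cross_down(t: np.ndarray, y: np.ndarray, level: float, start: int = 0) -> float:
    """First downward crossing of ``level`` at/after index ``start``.

    Linear interpolation between the bracketing samples; NaN if no crossing.
    """
    yy = y[start:]
    below = yy <= level
    if not below.any():
        return float("nan")
    k = int(np.argmax(below))
    if k == 0:
        return float(t[start])
    i = start + k - 1
    y0, y1 = y[i], y[i + 1]
    frac = (y0 - level) / (y0 - y1)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def cross_up(t: np.ndarray, y: np.ndarray, level: float, start: int = 0) -> float:
    """First upward crossing of ``level`` at/after index ``start`` (interpolated)."""
    yy = y[start:]
    above = yy >= level
    if not above.any():
        return float("nan")
    k = int(np.argmax(above))
    if k == 0:
        return float(t[start])
    i = start + k - 1
    y0, y1 = y[i], y[i + 1]
    frac = (level - y0) / (y1 - y0)
    return float(t[i] + frac * (t[i + 1] - t[i]))


def apd90_measure(t: np.ndarray, v: np.ndarray, frac: float = 0.9) -> dict:
    """Core APD measurement on a single-beat voltage series.

    Depolarization time is the instant of maximum dV/dt (the upstroke),
    V_rest is the pre-stimulus potential (first sample), and APD is the
    interval from depolarization to the first downward crossing of
    ``V_peak - frac * APA`` after the peak.
    """
    dvdt = np.diff(v) / np.diff(t)
    i_dep = int(np.argmax(dvdt))
    t_dep = float(t[i_dep])
    i_peak = int(np.argmax(v))
    v_peak = float(v[i_peak])
    v_rest = float(v[0])
    apa = v_peak - v_rest
    v90 = v_peak - frac * apa
    t90 = cross_down(t, v, v90, start=i_peak)
    apd = t90 - t_dep if np.isfinite(t90) else float("nan")
    return {
        "t_dep": t_dep, "t_peak": float(t[i_peak]), "v_peak": v_peak,
        "v_rest": v_rest, "apa": apa, "v90": v90, "t_apd90": t90, "apd": apd,
        "captured": bool(v_peak > 0.0),
    }
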