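"""Backward feature elimination over the modulated currents.

Ranks the contribution of each current to dispersion reduction: starting
from the optimized full set, each step re-optimizes every leave-one-out
subset (the left-out current pinned at control), keeps the subset that
achieves the lowest objective, and eliminates its left-out current.  The
procedure repeats until ``stop_at`` currents remain, recording the
achieved dispersion at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ord import Scaling, SCALED_CURRENTS
from .optimize import Objective, PSOConfig, optimize_scaling


@dataclass(frozen=True)
class EliminationStep:
    active: tuple                # currents still modulated at this step
    scaling: Scaling             # optimized multipliers (inactive pinned at 1)
    value: float                 # achieved objective (dispersion, ms)
    eliminated: str | None       # current dropped after this step


@dataclass
class EliminationTrace:
    steps: list = field(default_factory=list)

    @property
    def final_pair(self) -> tuple:
        return self.steps[-1].active

    @property
    def order(self) -> list:
        return [s.eliminated for s in self.steps if s.eliminated]

    def values(self) -> list:
        return [s.value for s in self.steps]


def backward_eliminate(objective: Objective, pso_config: PSOConfig,
                       backend=None, initial=SCALED_CURRENTS,
                       stop_at: int = 2, warm_start: bool = True,
                       verbose: bool = False) -> EliminationTrace:
    """Run the elimination procedure; returns the full step-by-step trace.

    ``warm_start`` seeds one particle of every subset re-optimization with
    the parent optimum (projected onto the subset).  Ties between subsets
    are broken by eliminating the current whose parent-optimal multiplier
    was closest to control (least informative first).
    """
    initial = tuple(initial)
    if not set(initial) <= set(SCALED_CURRENTS):
        raise ValueError("initial currents must be among the 7 modulated currents")
    if stop_at < 1 or stop_at > len(initial):
        raise ValueError("stop_at out of range")

    trace = EliminationTrace()
    active = initial
    best_scaling, res = optimize_scaling(objective, pso_config, backend,
                                         active=active)
    parent_value = res.value
    if verbose:
        print(f"full set {active}: {parent_value:.2f}")

    while True:
        eliminated = None
        if len(active) > stop_at:
            candidates = []
            for drop in active:
                subset = tuple(c for c in active if c != drop)
                x0 = best_scaling if warm_start else None
                # deterministic per-subset seed (str hash is salted per process)
                sub_seed = pso_config.seed + sum(
                    2 ** SCALED_CURRENTS.index(c) for c in subset)
                sub_cfg = replace(pso_config, seed=sub_seed)
                s, r = optimize_scaling(objective, sub_cfg, backend,
                                        active=subset, x0=x0)
                # tie-break key: |parent multiplier - 1| (least informative)
                informative = abs(best_scaling.as_dict()[drop] - 1.0)
                candidates.append((r.value, informative, drop, s))
                if verbose:
                    print(f"  drop {drop}: {r.value:.2f}")
            candidates.sort(key=lambda c: (round(c[0], 6), c[1]))
            value, _, eliminated, next_scaling = candidates[0]
        trace.steps.append(EliminationStep(active=active, scaling=best_scaling,
                                           value=parent_value,
                                           eliminated=eliminated))
        if eliminated is None:
            break
        active = tuple(c for c in active if c != eliminated)
        best_scaling, parent_value = next_scaling, value
    return trace
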