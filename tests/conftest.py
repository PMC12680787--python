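"""Shared fixtures: steady beats are memoized inside transmural.ord, so any
test that asks for the same (cell, scaling, BCL, protocol) reuses the run."""

import numpy as np
import pytest

from transmural.ord import Scaling, PacingConfig, steady_beat
from transmural.synthetic_ap import SyntheticSpec, make_trace

#: printed intervention vectors used across tests
BLOCKER_OPT = Scaling(inal=0.0, ical=0.5, ikr=0.56, inak=0.95, inaca=0.5)
BLOCKER_ACTIVATOR_OPT = Scaling(inal=0.26, ical=0.5, iks=32.56, ikr=0.0,
                                ik1=0.64, inak=1.5, inaca=0.56)
PAIR_OPT = Scaling(iks=26.83, ikr=0.0)
POPMAP_POINT = Scaling(ikr=0.43, iks=5.0)
IKR_BLOCK_25 = Scaling(ikr=0.75)


def full_pacing(bcl: float) -> PacingConfig:
    return PacingConfig(bcl=bcl, mode="full")


def steady(cell, scaling=None, bcl=1000.0, mode="converged"):
    """Convenience wrapper; converged mode by default (desk scale)."""
    pc = PacingConfig(bcl=bcl, mode=mode)
    return steady_beat(cell, scaling or Scaling(), bcl, pacing=pc)


@pytest.fixture(scope="session")
def synthetic_control():
    """A noise-free synthetic beat with exact ground truth."""
    spec = SyntheticSpec()
    trace, ph, ap = make_trace(spec)
    return spec, trace, ph, ap


@pytest.fixture(scope="session")
def random_specs():
    """200 randomized-but-valid synthetic specs (fixed seed)."""
    rng = np.random.default_rng(42)
    specs = []
    for _ in range(200):
        specs.append(SyntheticSpec(
            v_rest=float(rng.uniform(-92, -84)),
            v_peak=float(rng.uniform(25, 45)),
            upstroke_ms=float(rng.uniform(1, 3)),
            ph1_ms=float(rng.uniform(15, 50)),
            ph2_ms=float(rng.uniform(80, 260)),
            ph3_ms=float(rng.uniform(20, 80)),
            notch_depth=float(rng.uniform(6, 18)),
            dome_drop=float(rng.uniform(1, 5)),
            v_ph2_end=float(rng.uniform(-45, -30)),
            ik1_peak=float(rng.uniform(1, 4))))
    return specs
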