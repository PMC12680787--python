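"""Unit and property tests for the conductance-scalable ORd cell model."""

import numpy as np
import pytest

from transmural import ord as m
from transmural.ord import (CellType, Scaling, PacingConfig, SimulationError,
                            init_state, derivatives, find_stim_threshold,
                            pace_to_steady_state)
from conftest import steady


class TestInitState:
    def test_invariants(self):
        for cell in ("EPI", "MID", "ENDO"):
            y = init_state(cell)
            m.check_state(y)
            assert y[5] > 0  # [Ca]_i

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown cell type"):
            init_state("SUBEPI")

    def test_same_equations_different_parameters(self):
        # cell types share initial conditions and state layout; only the
        # transmural parameter scalings differ
        assert np.array_equal(init_state("EPI"), init_state("MID"))

    def test_quiescent_cell_is_stable(self):
        # 100 unstimulated beats; resting potential drifts < 0.5 mV over
        # the final 10 s
        pc = PacingConfig(bcl=1000.0, mode="fixed", n_beats=100,
                          stim_amplitude=0.0)
        trace, diag, y = pace_to_steady_state("MID", pacing=pc,
                                              return_state=True)
        m.check_state(y)
        assert trace.v.max() < 0  # never fires
        # 10 further quiescent seconds: resting V stays within 0.5 mV
        pc2 = PacingConfig(bcl=10000.0, stim_amplitude=0.0)
        tail, _ = m.simulate_beat(y, "MID", pacing=pc2, stim_amplitude=0.0)
        assert tail.v.max() - tail.v.min() < 0.5


@pytest.fixture(scope="module")
def plateau_state():
    # a mid-plateau state exercises every current
    pc = PacingConfig(bcl=1000.0, mode="fixed", n_beats=3,
                      stim_amplitude=80.0)
    _, _, y = pace_to_steady_state("EPI", pacing=pc, return_state=True)
    tr, y2 = m.simulate_beat(y, "EPI", pacing=pc, stim_amplitude=80.0)
    # integrate 100 ms into the next beat to land on the plateau
    pc3 = PacingConfig(bcl=100.0, mode="fixed", n_beats=1,
                       stim_amplitude=80.0)
    _, y3 = m.simulate_beat(y2, "EPI", pacing=pc3, stim_amplitude=80.0)
    return y3


class TestDerivatives:
    def test_identity_scaling_matches_control(self, plateau_state):
        d0, c0 = derivatives(plateau_state, "EPI", Scaling())
        d1, c1 = derivatives(plateau_state, "EPI", None)
        assert np.array_equal(d0, d1)
        assert c0 == c1

    def test_zero_multiplier_kills_current(self, plateau_state):
        _, c = derivatives(plateau_state, "EPI", Scaling(ikr=0.0))
        assert c["IKr"] == 0.0

    @pytest.mark.parametrize("field,name", [
        ("iks", "IKs"), ("ikr", "IKr"), ("inal", "INaL"), ("ik1", "IK1"),
    ])
    def test_multiplier_scales_current_exactly(self, plateau_state, field, name):
        # single-point evaluation oracle: x=2 doubles the current exactly
        _, c1 = derivatives(plateau_state, "EPI", Scaling())
        _, c2 = derivatives(plateau_state, "EPI", Scaling(**{field: 2.0}))
        assert c2[name] == pytest.approx(2.0 * c1[name], rel=1e-12)
        # all other currents untouched
        for other in set(c1) - {name, "Itot"}:
            assert c2[other] == c1[other]

    def test_dvdt_consistent_with_currents(self, plateau_state):
        d, c = derivatives(plateau_state, "EPI")
        assert d[0] == pytest.approx(-c["Itot"], abs=1e-6)

    def test_nonfinite_state_rejected(self):
        y = init_state("EPI")
        y[0] = np.nan
        with pytest.raises(SimulationError):
            derivatives(y, "EPI")


class TestScalingValidation:
    def test_ranges_enforced(self):
        with pytest.raises(ValueError, match=r"x_IKr=2.5"):
            Scaling(ikr=2.5).validate()

    def test_blockers_only_caps_at_control(self):
        Scaling(iks=40.0).validate()  # fine in full mode
        with pytest.raises(ValueError, match="blockers-only"):
            Scaling(iks=1.2).validate(blockers_only=True)

    def test_override_skips_check(self):
        Scaling(ikr=2.5).validate(override=True)


class TestThreshold:
    def test_definition_and_protocol(self):
        # bisection guarantee: T captures, 0.95 T does not (same prepaced
        # diastolic state as the search itself)
        bcl, pc = 1000.0, PacingConfig(bcl=1000.0)
        thr = find_stim_threshold("EPI", bcl=bcl)
        y = init_state("EPI")
        bufs = None
        for _ in range(50):
            bufs = m._one_beat(y, 1, Scaling().as_array(), bcl, pc, 80.0,
                               bufs=bufs)
        short = PacingConfig(bcl=25.0)

        def fires(amp):
            tr, _ = m.simulate_beat(y, "EPI", pacing=short, stim_amplitude=amp)
            return tr.v[:200].max() > 0.0

        assert fires(thr)
        assert not fires(0.95 * thr)
        assert fires(1.5 * thr)

    @pytest.mark.parametrize("bcl", [400.0, 1000.0, 3000.0])
    def test_protocol_stimulus_captures(self, bcl):
        # the 1.5x threshold protocol elicits an AP at every protocol BCL
        pc = PacingConfig(bcl=bcl, mode="fixed", n_beats=2)
        trace, diag = pace_to_steady_state("EPI", pacing=pc)
        assert trace.v.max() > 0
        assert diag["threshold"] is not None

    def test_strength_duration_monotone(self):
        t_short = find_stim_threshold("EPI", bcl=1000.0, pulse_ms=0.5)
        t_long = find_stim_threshold(
            "EPI", bcl=1000.0, pulse_ms=1.0,
            pacing=PacingConfig(bcl=1000.0, stim_duration=1.0))
        assert t_long <= t_short


class TestPacing:
    def test_determinism(self):
        pc = PacingConfig(bcl=1000.0, mode="fixed", n_beats=3,
                          stim_amplitude=80.0)
        t1, _ = pace_to_steady_state("EPI", pacing=pc)
        t2, _ = pace_to_steady_state("EPI", pacing=pc)
        assert np.array_equal(t1.v, t2.v)
        assert np.array_equal(t1.currents, t2.currents)

    def test_trace_contract(self):
        pc = PacingConfig(bcl=1000.0, mode="fixed", n_beats=2,
                          stim_amplitude=80.0)
        tr, _ = pace_to_steady_state("EPI", pacing=pc)
        assert tr.n == 10000 and tr.dt == pytest.approx(0.1)
        # I_tot equals the sum of the per-current series
        assert np.allclose(tr.itot, tr.currents.sum(axis=1), atol=1e-9)

    def test_itot_matches_minus_dvdt(self):
        trace, diag, _ = steady("EPI")
        dvdt = np.gradient(trace.v, trace.t)
        resid = np.abs(trace.itot + dvdt)[trace.t > 5.0]
        assert np.percentile(resid, 95) < 0.05

    def test_solver_convergence_halving_dt(self):
        pc1 = PacingConfig(bcl=1000.0, mode="fixed", n_beats=20,
                           stim_amplitude=80.0)
        pc2 = PacingConfig(bcl=1000.0, mode="fixed", n_beats=20,
                           stim_amplitude=80.0, dt=0.0025, dt_coarse=0.025)
        _, d1 = pace_to_steady_state("EPI", pacing=pc1)
        _, d2 = pace_to_steady_state("EPI", pacing=pc2)
        assert abs(d1["apd"] - d2["apd"]) < 1.0

    def test_capture_failure_raises(self):
        pc = PacingConfig(bcl=1000.0, mode="fixed", n_beats=1,
                          stim_amplitude=5.0)  # far below threshold
        with pytest.raises(SimulationError, match="capture"):
            pace_to_steady_state("EPI", pacing=pc)


class TestControlPhysiology:
    """Identity scaling reproduces the published transmural phenotype."""

    def test_transmural_ordering_and_currents(self):
        epi, _, _ = steady("EPI")
        mid, _, _ = steady("MID")
        from transmural.ap_features import ap_metrics, ca_transient_amplitude
        assert ap_metrics(epi).apd < ap_metrics(mid).apd
        assert epi.current("IKr").max() > mid.current("IKr").max()
        assert ca_transient_amplitude(mid) > ca_transient_amplitude(epi)

    def test_apd_rate_dependence(self):
        from transmural.ap_features import ap_metrics
        apds = [ap_metrics(steady("EPI", bcl=b)[0]).apd
                for b in (3000.0, 1000.0, 500.0, 400.0)]
        assert apds == sorted(apds, reverse=True)

    def test_ca_amplitude_rate_dependence(self):
        from transmural.ap_features import ca_transient_amplitude
        fast = ca_transient_amplitude(steady("EPI", bcl=500.0)[0])
        slow = ca_transient_amplitude(steady("EPI", bcl=3000.0)[0])
        assert fast > slow

    @pytest.mark.parametrize("cell", ["EPI", "MID"])
    def test_duration_current_hyperbola(self, cell):
        # mean phase-2+3 current x duration is approximately the constant K
        # (the potential drop over repolarization) across pacing rates
        from transmural.ap_features import segment_phases, phase_mean_currents
        products = []
        for bcl in (400.0, 500.0, 1000.0, 3000.0):
            trace, _, _ = steady(cell, bcl=bcl)
            ph = segment_phases(trace)
            pm = phase_mean_currents(trace, ph)
            products.append(pm.i_tot * (ph.ph2_ms + ph.ph3_ms))
        products = np.asarray(products)
        assert products.std() / products.mean() < 0.15
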