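"""Feature extraction: segmentation oracle, phase invariants, fits."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transmural.ap_features import (segment_phases, ap_metrics,
                                    phase_mean_currents, fit_hyperbola,
                                    ca_transient_amplitude, FeatureError,
                                    DEPOLARIZING, REPOLARIZING)
from transmural.synthetic_ap import SyntheticSpec, make_trace
from transmural.trace import BeatTrace, CURRENT_NAMES


class TestSegmentationOracle:
    def test_boundaries_match_ground_truth(self, random_specs):
        """Noise-free synthetic beats: each boundary recovered within one
        output sample (0.1 ms); durations may combine two boundary errors."""
        for spec in random_specs:
            trace, ph_true, ap_true = make_trace(spec)
            ph = segment_phases(trace)
            assert ph.t_ph1_end == pytest.approx(ph_true.t_ph1_end, abs=0.1)
            assert ph.t_ph2_end == pytest.approx(ph_true.t_ph2_end, abs=0.1)
            assert ph.t_apd90 == pytest.approx(ph_true.t_apd90, abs=0.1)
            assert ph.ph2_ms == pytest.approx(ph_true.ph2_ms, abs=0.2)
            assert ph.ph3_ms == pytest.approx(ph_true.ph3_ms, abs=0.2)

    def test_phase_additivity(self, random_specs):
        for spec in random_specs[:50]:
            trace, _, _ = make_trace(spec)
            ph = segment_phases(trace)
            ap = ap_metrics(trace)
            assert ph.ph1_ms + ph.ph2_ms + ph.ph3_ms == pytest.approx(
                ap.apd, abs=0.1)

    def test_clipped_trace_errors(self, synthetic_control):
        _, trace, ph, _ = synthetic_control
        cut = int(ph.t_ph2_end / trace.dt)  # clip before the APD90 crossing
        clipped = BeatTrace(
            t=trace.t[:cut], v=trace.v[:cut], currents=trace.currents[:cut],
            itot=trace.itot[:cut], i_stim=trace.i_stim[:cut],
            i_inject=trace.i_inject[:cut], cai=trace.cai[:cut],
            nai=trace.nai[:cut], bcl=trace.bcl)
        with pytest.raises(FeatureError, match="repolarization incomplete"):
            segment_phases(clipped)

    def test_no_ap_errors(self, synthetic_control):
        _, trace, _, _ = synthetic_control
        flat = dataclasses.replace(trace, v=np.full_like(trace.v, -88.0))
        with pytest.raises(FeatureError, match="no action potential"):
            ap_metrics(flat)


class TestPhaseCurrents:
    def test_groups_partition_itot(self, synthetic_control):
        assert sorted(DEPOLARIZING + REPOLARIZING) == sorted(CURRENT_NAMES)
        _, trace, _, _ = synthetic_control
        ph = segment_phases(trace)
        pm = phase_mean_currents(trace, ph)
        assert pm.i_dep + pm.i_rep == pytest.approx(pm.i_tot, abs=1e-9)

    def test_constant_currents_average_to_constant(self, synthetic_control):
        _, trace, _, _ = synthetic_control
        cur = np.zeros_like(trace.currents)
        cur[:, CURRENT_NAMES.index("IKr")] = 0.7
        cur[:, CURRENT_NAMES.index("INaCa")] = -0.2
        const = dataclasses.replace(trace, currents=cur,
                                    itot=cur.sum(axis=1))
        ph = segment_phases(trace)  # boundaries from the original beat
        pm = phase_mean_currents(const, ph)
        assert pm.per_current["IKr"] == pytest.approx(0.7)
        assert pm.per_current["INaCa"] == pytest.approx(-0.2)
        assert pm.i_tot == pytest.approx(0.5)


class TestHyperbola:
    def test_exact_recovery(self):
        d = np.array([50.0, 100.0, 200.0, 400.0])
        fit = fit_hyperbola(np.column_stack([d, 110.0 / d]))
        assert fit.K == pytest.approx(110.0)
        assert fit.r2 == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(K=st.floats(10.0, 500.0),
           d=st.lists(st.floats(20.0, 600.0), min_size=2, max_size=8))
    def test_exact_recovery_property(self, K, d):
        d = np.asarray(d)
        fit = fit_hyperbola(np.column_stack([d, K / d]))
        assert fit.K == pytest.approx(K, rel=1e-9)

    def test_equal_current_change_moves_long_durations_more(self):
        # operational form of the duration asymmetry: on I = K/d, the same
        # current reduction lengthens a long-duration AP more than a short one
        K = 110.0
        d_short, d_long = 190.0, 300.0
        dI = 0.05
        move = lambda d0: K / (K / d0 - dI) - d0
        assert move(d_long) > move(d_short) > 0

    def test_underdetermined(self):
        with pytest.raises(ValueError, match="two"):
            fit_hyperbola([(100.0, 1.0)])

    def test_zero_duration(self):
        with pytest.raises(ValueError, match="positive"):
            fit_hyperbola([(0.0, 1.0), (100.0, 1.0)])


class TestCaTransient:
    def test_flat_series_zero(self, synthetic_control):
        _, trace, _, _ = synthetic_control
        assert ca_transient_amplitude(trace) == pytest.approx(0.0)

    def test_amplitude_is_peak_to_trough(self, synthetic_control):
        _, trace, _, _ = synthetic_control
        cai = 1e-4 + 5e-4 * np.exp(-((trace.t - 50) / 30.0) ** 2)
        tr = dataclasses.replace(trace, cai=cai)
        assert ca_transient_amplitude(tr) == pytest.approx(cai.max() - cai.min())
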