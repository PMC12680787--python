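"""Particle swarm optimizer and objective machinery."""

import numpy as np
import pytest

from transmural.ord import Scaling, SCALED_CURRENTS
from transmural.optimize import (Objective, PSOConfig, PSOResult, PENALTY,
                                 SurrogateBackend, evaluate_objective,
                                 pso_minimize, optimize_scaling)


def sphere(x):
    return float(np.sum(x ** 2))


def rastrigin2(x):
    return float(10 * 2 + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))


class TestPSOCore:
    def test_sphere_convergence_7d(self):
        cfg = PSOConfig(seed=3, bounds=tuple([(-1.0, 1.0)] * 7))
        res = pso_minimize(sphere, cfg)
        assert res.value < 1e-2
        assert np.all(np.abs(res.x) < 0.2)

    def test_gbest_monotone(self):
        cfg = PSOConfig(seed=5, bounds=tuple([(-1.0, 1.0)] * 7))
        res = pso_minimize(sphere, cfg)
        assert all(b <= a for a, b in zip(res.history, res.history[1:]))

    def test_rastrigin_bit_reproducible(self):
        cfg = PSOConfig(seed=11, bounds=((-5.12, 5.12), (-5.12, 5.12)),
                        n_iterations=30)
        r1 = pso_minimize(rastrigin2, cfg, dims=("a", "b"))
        r2 = pso_minimize(rastrigin2, cfg, dims=("a", "b"))
        assert r1.history == r2.history
        assert np.array_equal(r1.x, r2.x)

    def test_positions_stay_in_bounds(self):
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        cfg = PSOConfig(seed=2, bounds=((0.5, 1.5), (-2.0, -1.0)),
                        n_iterations=20)
        pso_minimize(probe, cfg, dims=("a", "b"))
        pts = np.array(seen)
        assert pts[:, 0].min() >= 0.5 and pts[:, 0].max() <= 1.5
        assert pts[:, 1].min() >= -2.0 and pts[:, 1].max() <= -1.0

    def test_warm_start_seeds_particle(self):
        cfg = PSOConfig(seed=4, bounds=tuple([(-1.0, 1.0)] * 3),
                        n_iterations=1)
        res = pso_minimize(sphere, cfg, dims=("a", "b", "c"),
                           x0=np.zeros(3))
        assert res.value == 0.0  # the seeded particle is already optimal

    def test_neighborhood_size_validated(self):
        with pytest.raises(ValueError):
            PSOConfig(n_particles=10, neighborhood_size=20)


class TestObjective:
    def test_modes_validated(self):
        with pytest.raises(ValueError, match="unknown objective"):
            Objective(mode="maximize_fun")
        with pytest.raises(ValueError, match="apd_target"):
            Objective(mode="epi_target")

    def test_min_dispersion_arithmetic(self):
        backend = lambda s: {"apds": {"EPI": 231.0, "MID": 334.0},
                             "abnormal": False}
        assert evaluate_objective(Scaling(), Objective(), backend) == 103.0

    def test_equal_apds_zero(self):
        backend = lambda s: {"apds": {"EPI": 270.0, "MID": 270.0},
                             "abnormal": False}
        assert evaluate_objective(Scaling(), Objective(), backend) == 0.0

    def test_target_mode_adds_distance(self):
        backend = lambda s: {"apds": {"EPI": 260.0, "MID": 300.0},
                             "abnormal": False}
        obj = Objective(mode="epi_target", apd_target=270.0)
        assert evaluate_objective(Scaling(), obj, backend) == 50.0

    def test_abnormal_gets_penalty(self):
        backend = lambda s: {"apds": {"EPI": 260.0, "MID": 300.0},
                             "abnormal": True}
        assert evaluate_objective(Scaling(), Objective(), backend) == PENALTY

    def test_surrogate_control_reproduces_103(self):
        assert evaluate_objective(Scaling(), Objective(),
                                  SurrogateBackend()) == pytest.approx(103.0)

    def test_surrogate_ead_region_penalized(self):
        sc = Scaling(ikr=0.0, ical=1.45)
        assert evaluate_objective(sc, Objective(),
                                  SurrogateBackend()) == PENALTY


class TestOptimizeScaling:
    def test_blockers_only_never_exceeds_control(self):
        cfg = PSOConfig(seed=1, blockers_only=True, n_iterations=25)
        best, res = optimize_scaling(Objective(), cfg, SurrogateBackend())
        assert max(best.as_dict().values()) <= 1.0
        assert res.value < 103.0  # improves on control dispersion

    def test_inactive_currents_pinned(self):
        cfg = PSOConfig(seed=1, n_iterations=10)
        best, _ = optimize_scaling(Objective(), cfg, SurrogateBackend(),
                                   active=("IKr", "IKs"))
        d = best.as_dict()
        for name in SCALED_CURRENTS:
            if name not in ("IKr", "IKs"):
                assert d[name] == 1.0

    def test_deterministic_given_seed(self):
        cfg = PSOConfig(seed=9, n_iterations=15)
        b1, r1 = optimize_scaling(Objective(), cfg, SurrogateBackend())
        b2, r2 = optimize_scaling(Objective(), cfg, SurrogateBackend())
        assert b1 == b2 and r1.history == r2.history
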