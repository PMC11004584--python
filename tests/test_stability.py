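"""Characteristic polynomial, Routh-Hurwitz, parametric stability conditions
and Lyapunov global-stability certificates."""

import numpy as np
import pytest

from kleptodyn import (characteristic_coefficients, routh_hurwitz, jacobian,
                       stability_report, interior_equilibria,
                       GlobalStabilityConfig, global_stability_predator_free,
                       global_stability_coexistence)
from kleptodyn.stability import (classify_eigenvalues,
                                 klepto_only_A4_threshold,
                                 lyapunov_derivative_predator_free,
                                 lyapunov_derivative_coexistence,
                                 search_certificate_predator_free)
from conftest import random_params


class TestCharacteristicCoefficients:
    def test_baseline_interior_values(self, base):
        eq = [e for e in interior_equilibria(base) if e.exists][0]
        c1, c2, c3 = characteristic_coefficients(jacobian(eq.state, base))
        assert c1 == pytest.approx(0.844371, abs=5e-7)
        assert c2 == pytest.approx(1.96046, abs=5e-6)
        assert c3 == pytest.approx(1.22722, abs=5e-6)

    def test_zero_matrix(self):
        assert characteristic_coefficients(np.zeros((3, 3))) == (0, 0, 0)

    def test_polynomial_roots_are_the_eigenvalues(self, rng):
        for _ in range(100):
            J = rng.normal(size=(3, 3))
            c1, c2, c3 = characteristic_coefficients(J)
            roots = np.roots([1, c1, c2, c3])
            eig = np.linalg.eigvals(J)
            assert np.allclose(np.sort_complex(roots), np.sort_complex(eig),
                               atol=1e-8)


class TestRouthHurwitz:
    def test_baseline_discriminant(self):
        rh = routh_hurwitz(0.844371, 1.96046, 1.22722)
        assert rh.stable
        assert rh.discriminant == pytest.approx(0.428135, abs=5e-6)

    def test_simple_unstable_case(self):
        rh = routh_hurwitz(1.0, 1.0, 2.0)
        assert not rh.stable and rh.discriminant == -1.0

    def test_agrees_with_eigenvalue_classification(self, rng):
        checked = 0
        for _ in range(1000):
            J = rng.normal(size=(3, 3))
            eig = np.linalg.eigvals(J)
            if np.max(np.abs(eig.real)) < 1e-8:
                continue
            verdict = classify_eigenvalues(eig)
            rh = routh_hurwitz(*characteristic_coefficients(J))
            assert rh.stable == (verdict == "stable")
            checked += 1
        assert checked > 900


class TestParametricConditions:
    def test_predator_free_scenario(self, base):
        p = base.replace(A3=0.875, A4=0.0125, A5=4.536)
        rep = stability_report(p)["E1"]
        assert rep.classification == "stable"
        assert rep.condition_report["host cannot invade (A1*A3 > A4)"]
        assert rep.condition_report["A1*A3"] == pytest.approx(0.0175)
        assert rep.condition_report["kleptoparasite cannot invade (A7 > A5)"]

    def test_host_free_scenario(self, base):
        p = base.replace(A3=2.723732, A4=0.516658, A5=9.3241)
        rep = stability_report(p)["E3"]
        assert rep.classification == "stable"
        # exact evaluation of the printed closed form (the study rounds it
        # to 2.88978; the exact value is 2.8897250)
        assert klepto_only_A4_threshold(p) == pytest.approx(2.8897250,
                                                            abs=5e-7)
        assert rep.condition_report["A4 <= A4 threshold"]

    def test_klepto_free_scenario(self, base):
        p = base.replace(A3=0.51558, A4=0.010528, A5=1.135458)
        rep = stability_report(p)["E2"]
        assert rep.classification == "stable"
        cr = rep.condition_report
        assert cr["host persists (A1*A3 < A4)"]
        assert 0.0103116 == pytest.approx(p.A1 * p.A3, rel=1e-6)
        # threshold must dominate A8 = 114.98 (printed as 170.022; exact
        # arithmetic on the same closed form gives 170.6196)
        assert cr["A8 threshold"] == pytest.approx(170.6196, rel=1e-4)
        assert cr["A8 < A8 threshold"]
        assert cr["proof-level: A7 > A7 threshold"]

    def test_parametric_verdicts_match_eigenvalues(self, rng):
        """Whenever E1/E2/E3 exists, the closed-form conditions and the
        eigenvalue classification must agree (away from marginal cases)."""
        for p in random_params(rng, 120):
            for label, rep in stability_report(p).items():
                if not rep.applicable or label in ("E0", "E4"):
                    continue
                if np.min(np.abs(rep.eigenvalues.real)) < 1e-6:
                    continue
                cr = rep.condition_report
                if label == "E1":
                    cond = (cr["host cannot invade (A1*A3 > A4)"]
                            and cr["kleptoparasite cannot invade (A7 > A5)"])
                    assert cond == (rep.classification == "stable")
                elif label in ("E2", "E3"):
                    # the parametric conditions (for E2 including the
                    # proof-level A7 inequality) are sufficient: when they
                    # all hold the equilibrium must be stable
                    conds = [v for v in cr.values()
                             if isinstance(v, (bool, np.bool_))]
                    if all(conds):
                        assert rep.classification == "stable"

    def test_interior_c1_equals_prey_density(self, rng):
        """On the nullclines z22 = z33 = 0 and z11 = -S*, so c1 = S*."""
        for p in random_params(rng, 80):
            for e in interior_equilibria(p):
                if e.exists:
                    c1, _, _ = characteristic_coefficients(jacobian(e.state, p))
                    assert c1 == pytest.approx(e.S, rel=1e-8)


class TestGlobalStabilityCertificates:
    def test_degenerate_death_rate_breaks_certificate(self, base):
        cfg = GlobalStabilityConfig((1, 1, 1), (0.1, 0.1, 0.1),
                                    (0.9, 0.9, 0.9))
        p = base.replace(A3=1e-9)
        rep = global_stability_predator_free(p, cfg)
        assert not rep.conditions["growth-dissipation inequality"]

    def test_grid_search_finds_certificate_and_it_is_lyapunov(self, base, rng):
        p = base.replace(A3=0.875, A4=0.0125, A5=4.536)   # E1-stable regime
        cfg = search_certificate_predator_free(p)
        assert cfg is not None
        rep = global_stability_predator_free(p, cfg)
        assert rep.holds
        lo, hi = np.array(cfg.lower), np.array(cfg.upper)
        for _ in range(10000):
            x = rng.uniform(lo, hi)
            assert lyapunov_derivative_predator_free(x, p, cfg) < 0

    def test_coexistence_ceiling_condition(self, base):
        eq = [e for e in interior_equilibria(base) if e.exists][0]
        cfg = GlobalStabilityConfig((1, 1, 1), (0.5, 0.001, 0.01),
                                    (0.95, 0.1, 0.9 * eq.P2))
        rep = global_stability_coexistence(base, eq, cfg)
        assert not rep.conditions["P2* <= P2 box ceiling"]

    def test_coexistence_report_margins(self, base):
        eq = [e for e in interior_equilibria(base) if e.exists][0]
        cfg = GlobalStabilityConfig((4.536, 1.0, 1.0),
                                    (0.7, 0.004, 0.05), (0.95, 0.05, 0.3))
        rep = global_stability_coexistence(base, eq, cfg)
        assert set(rep.conditions) == {
            "P2* <= P2 box ceiling", "L2 > Upsilon2",
            "cross-term positivity", "A4 < Upsilon3", "P1 floor > Upsilon4"}
        for v in rep.margins.values():
            assert np.isfinite(v)
        if rep.holds:
            rng = np.random.default_rng(7)
            lo, hi = np.array(cfg.lower), np.array(cfg.upper)
            for _ in range(10000):
                x = rng.uniform(lo, hi)
                assert lyapunov_derivative_coexistence(x, base, eq, cfg) < 0
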