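"""Continuation, fold/transcritical/Hopf detection, Sotomayor quantities."""

import numpy as np
import pytest
from scipy.optimize import brentq

from kleptodyn import (baseline, boundary_equilibria, interior_equilibria,
                       jacobian, continue_branch, detect_fold, detect_hopf,
                       detect_transcritical, sotomayor_quantities, rhs)


class TestContinueBranch:
    def test_zero_length_range(self, base):
        br = continue_branch(base, "A4", (0.4, 0.4))
        assert len(br.samples) == 1
        assert br.samples[0].equilibrium.S == pytest.approx(0.844371, abs=5e-7)

    def test_samples_are_true_equilibria(self, base):
        br = continue_branch(base, "A4", (0.2, 2.0), n_steps=60)
        for s in br.samples:
            p = base.replace(A4=s.param_value)
            assert np.linalg.norm(rhs(s.equilibrium.state, p)) < 1e-9

    def test_csv_schema(self, base):
        br = continue_branch(base, "A4", (0.2, 0.6), n_steps=10)
        df = br.to_frame()
        assert list(df.columns) == [
            "A4", "S", "P1", "P2", "re_lambda_1", "im_lambda_1",
            "re_lambda_2", "im_lambda_2", "re_lambda_3", "im_lambda_3",
            "stable"]
        assert len(df) == len(br.samples)


class TestFolds:
    @pytest.mark.parametrize("param,bounds,steps,expected", [
        ("A3", (0.01, 0.5), 200, 0.04267),
        ("A4", (11.0, 13.0), 100, 12.248),
        ("A8", (1.0, 40.0), 200, 10.2),
    ])
    def test_fold_locations(self, base, param, bounds, steps, expected):
        br = continue_branch(base, param, bounds, n_steps=steps)
        folds = detect_fold(br)
        assert len(folds) == 1
        assert folds[0].param_value == pytest.approx(expected, rel=1e-3)
        assert np.min(folds[0].state) > 1e-4   # genuinely interior
        assert abs(folds[0].diagnostics["det_J"]) < 1e-6

    def test_fold_agrees_with_root_count_oracle(self, base):
        """The fold parameter separates the 0-root and 2-root regions of a
        dense direct scan."""
        br = continue_branch(base, "A3", (0.01, 0.5), n_steps=200)
        v = detect_fold(br)[0].param_value
        n_below = len([e for e in interior_equilibria(
            base.replace(A3=v * 0.999), n_scan=100000) if e.exists])
        n_above = len([e for e in interior_equilibria(
            base.replace(A3=v * 1.001), n_scan=100000) if e.exists])
        assert n_below == 0 and n_above == 2


class TestTranscritical:
    def test_predator_free_crossing_at_A5_equal_A7(self, base):
        br = continue_branch(base, "A5", (4.0, 5.0), n_steps=50, family="E1")
        pts = [pt for pt in detect_transcritical([br])
               if pt.diagnostics.get("invading_species") == "P2"]
        assert len(pts) == 1
        assert pts[0].param_value == pytest.approx(base.A7, rel=1e-10)

    def test_interior_E3_crossing_in_A5(self, base):
        br = continue_branch(base, "A5", (4.6, 6.0), n_steps=100, family="E3")
        pts = detect_transcritical([br])
        assert len(pts) == 1
        assert pts[0].param_value == pytest.approx(5.3449, rel=1e-3)

    def test_interior_E3_crossing_in_A7(self, base):
        br = continue_branch(base, "A7", (3.0, 4.5), n_steps=100, family="E3")
        pts = detect_transcritical([br])
        assert len(pts) == 1
        assert pts[0].param_value == pytest.approx(3.857, rel=1e-3)

    def test_interior_E2_crossing_in_A8_exchanges_stability(self, base):
        br = continue_branch(base, "A8", (40.0, 50.0), n_steps=100,
                             family="E2")
        pts = detect_transcritical([br])
        assert len(pts) == 1
        v = pts[0].param_value
        # exact zero of the closed-form transverse eigenvalue
        assert v == pytest.approx(45.9911, rel=1e-4)
        below = [s for s in br.samples if s.param_value < v - 0.5][-1]
        above = [s for s in br.samples if s.param_value > v + 0.5][0]
        assert below.classification != above.classification


class TestSotomayor:
    def test_predator_free_exchange_quantities(self, base):
        p = base.replace(A5=base.A7)
        e1 = [e for e in boundary_equilibria(p) if e.label == "E1"][0]
        q1, q2, q3 = sotomayor_quantities(e1, p, "A5")
        assert q1 == pytest.approx(0.0, abs=1e-10)
        assert q2 == pytest.approx(1.0, rel=1e-6)
        assert q3 == pytest.approx(-p.A5, rel=1e-6)

    def test_klepto_free_surface_point(self, base):
        """On the E2 transcritical surface the quantities show the
        transcritical pattern (0, nonzero, nonzero)."""
        def transverse(a8):
            p = base.replace(A8=a8)
            B1 = p.A1 * p.A3 / p.A4
            C1 = (p.A4 - p.A1 * p.A3) / p.A4
            return p.A5 * B1 - p.A6 * C1 - p.A7 + p.A8 * B1 * C1
        a8s = brentq(transverse, 40, 50, xtol=1e-12)
        p = base.replace(A8=a8s)
        e2 = [e for e in boundary_equilibria(p) if e.label == "E2"][0]
        q1, q2, q3 = sotomayor_quantities(e2, p, "A8")
        assert q1 == pytest.approx(0.0, abs=1e-8)
        assert abs(q2) > 1e-3 and abs(q3) > 1e-3

    def test_requires_simple_zero_eigenvalue(self, base):
        eq = [e for e in interior_equilibria(base) if e.exists][0]
        with pytest.raises(ValueError):
            sotomayor_quantities(eq, base, "A4")


@pytest.fixture(scope="module")
def a4_hopfs(base):
    br = continue_branch(base, "A4", (0.05, 12.3), n_steps=400)
    return sorted(detect_hopf(br), key=lambda h: h.param_value)


class TestHopf:
    def test_two_hopf_points_in_A4(self, base, a4_hopfs):
        assert len(a4_hopfs) == 2
        assert a4_hopfs[0].param_value == pytest.approx(1.2252, rel=1e-3)
        assert a4_hopfs[1].param_value == pytest.approx(12.071019, rel=1e-3)

    def test_hopf_point_eigenstructure(self, base, a4_hopfs):
        """At a Hopf point the spectrum is {-c1, +i w, -i w}."""
        for pt in a4_hopfs:
            c1, c2, c3 = pt.diagnostics["char_coeffs"]
            assert abs(c3 - c1 * c2) < 1e-8
            p = base.replace(A4=pt.param_value)
            eig = np.linalg.eigvals(jacobian(pt.state, p))
            eig = eig[np.argsort(eig.imag)]
            assert eig[1].real == pytest.approx(-c1, abs=1e-7)
            assert eig[2].imag == pytest.approx(pt.diagnostics["omega"],
                                                abs=1e-7)
            assert abs(eig[2].real) < 1e-7

    def test_transversality_matches_eigenvalue_crossing_oracle(self, base,
                                                               a4_hopfs):
        """The reported crossing rate dRe(lambda)/dA4 agrees in value and
        sign with a finite-difference derivative of the critical
        eigenvalue's real part along the branch."""
        for pt in a4_hopfs:
            v, h = pt.param_value, 1e-4
            rates = []
            for vv in (v - h, v + h):
                p = base.replace(A4=vv)
                eqs = [e for e in interior_equilibria(p) if e.exists]
                eq = min(eqs, key=lambda e: abs(e.S - pt.state[0]))
                eig = np.linalg.eigvals(jacobian(eq.state, p))
                crit = eig[np.argmax(eig.imag)]
                rates.append(crit.real)
            fd = (rates[1] - rates[0]) / (2 * h)
            dre = pt.diagnostics["transversality_dre"]
            assert dre != 0
            assert np.sign(fd) == np.sign(dre)
            assert fd == pytest.approx(dre, rel=5e-2)

    def test_no_hopf_on_boundary_families(self, base):
        """The kleptoparasite-free and host-free equilibria never satisfy
        the Hopf conditions, over wide one-parameter sweeps."""
        for family, param, bounds in [
                ("E2", "A3", (0.05, 3.0)), ("E2", "A8", (1.0, 140.0)),
                ("E2", "A4", (0.05, 2.0)), ("E3", "A5", (4.6, 20.0)),
                ("E3", "A7", (0.5, 4.5)), ("E3", "A4", (0.05, 2.0))]:
            br = continue_branch(base, param, bounds, n_steps=150,
                                 family=family)
            assert detect_hopf(br) == []
            for s in br.samples:
                c1, c2, c3 = s.char_coeffs
                V = c1 * c2 - c3
                assert not (c1 > 0 and c2 > 0 and c3 > 0 and abs(V) < 1e-10)
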