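"""One- and two-parameter bifurcation analysis.

Equilibrium families (boundary E1/E2/E3 in closed form, interior families by
nullcline reduction) are continued in a single parameter by deterministic
natural-parameter stepping with continuity-based family tracking.  Detectors
locate and refine

* folds (saddle-nodes): parameter values where two interior equilibria
  coalesce, refined by bisection on the admissible-root count, with the
  vanishing coordinate test separating genuine folds from boundary exits;
* transcritical points: zero crossings of the transverse eigenvalue of a
  boundary family (where an interior family passes through it), refined with
  Brent's method on the closed-form eigenvalue;
* Hopf points: zeros of the Liu test function V = c1*c2 - c3 along an
  interior family with c1, c2, c3 > 0, with frequency omega = sqrt(c2),
  transversality (eigenvalue crossing rate) and the Hopf normal form
  attached;
* Bautin (generalized Hopf) points: sign changes of the first Lyapunov
  coefficient along a two-parameter Hopf locus, with the second Lyapunov
  coefficient evaluated at the located point.

All refinements are bisection/Brent iterations on smooth scalar test
functions; there is no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import Params, jacobian, rhs, bilinear, second_order_tensor
from .equilibria import Equilibrium, boundary_equilibria, interior_equilibria
from .stability import characteristic_coefficients, classify_eigenvalues
from .normal_form import HopfNormalForm, lyapunov_coefficients

PARAM_XTOL = 1e-10


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str                      # fold | transcritical | hopf | bautin
    param_name: str
    param_value: float
    state: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    normal_form: HopfNormalForm | None = None


@dataclass
class BranchSample:
    param_value: float
    equilibrium: Equilibrium
    eigenvalues: np.ndarray
    char_coeffs: tuple
    classification: str
    n_interior: int                # admissible interior count at this value


@dataclass
class Branch:
    """An equilibrium family continued in one parameter."""

    param_name: str
    family: str                    # "interior" or "E1"/"E2"/"E3"
    base_params: Params
    samples: list[BranchSample] = field(default_factory=list)
    events: list[BifurcationPoint] = field(default_factory=list)
    counts: list[tuple] = field(default_factory=list)  # (value, n_interior)
    truncated: bool = False

    @property
    def param_values(self) -> np.ndarray:
        return np.array([s.param_value for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            eig = np.sort_complex(s.eigenvalues)
            rows.append({
                self.param_name: s.param_value,
                "S": s.equilibrium.S, "P1": s.equilibrium.P1,
                "P2": s.equilibrium.P2,
                "re_lambda_1": eig[0].real, "im_lambda_1": eig[0].imag,
                "re_lambda_2": eig[1].real, "im_lambda_2": eig[1].imag,
                "re_lambda_3": eig[2].real, "im_lambda_3": eig[2].imag,
                "stable": s.classification == "stable",
            })
        return pd.DataFrame(rows)


def _boundary_member(p: Params, family: str) -> Equilibrium | None:
    for eq in boundary_equilibria(p):
        if eq.label == family:
            return eq if eq.exists else None
    return None


def _family_member(p: Params, family: str,
                   guess_S: float | None) -> tuple[Equilibrium | None, int]:
    """The family's equilibrium at parameters ``p`` plus interior count."""
    if family.startswith("E"):
        eq = _boundary_member(p, family)
        n = len([e for e in interior_equilibria(p) if e.exists])
        return eq, n
    eqs = [e for e in interior_equilibria(p) if e.exists]
    if not eqs:
        return None, 0
    if guess_S is not None:
        eqs = sorted(eqs, key=lambda e: abs(e.S - guess_S))
    return eqs[0], len(eqs)


def _sample(p: Params, value: float, eq: Equilibrium, n: int) -> BranchSample:
    J = jacobian(eq.state, p)
    eig = np.linalg.eigvals(J)
    return BranchSample(value, eq, eig, characteristic_coefficients(J),
                        classify_eigenvalues(eig), n)


def continue_branch(p: Params, param_name: str, bounds, n_steps: int = 400,
                    family: str = "interior",
                    start_guess_S: float | None = None) -> Branch:
    """Continue one equilibrium family across ``bounds`` = (lo, hi).

    Stepping starts from the end of ``bounds`` closest to the base parameter
    value when that value lies inside the range, otherwise from ``lo``.
    The interior family is tracked by choosing, at each step, the admissible
    root with prey density nearest the previous sample (local refinement
    halves the step when the prey density jumps by more than 0.05).  Loss of
    the family truncates the branch.
    """
    lo, hi = sorted((float(bounds[0]), float(bounds[1])))
    branch = Branch(param_name, family, p)
    if lo == hi:
        pp = p.replace(**{param_name: lo})
        eq, n = _family_member(pp, family, start_guess_S)
        branch.counts.append((lo, n))
        if eq is not None:
            branch.samples.append(_sample(pp, lo, eq, n))
        return branch
    base_val = getattr(p, param_name)
    inside = lo <= base_val <= hi
    forward = (not inside) or abs(base_val - lo) <= abs(hi - base_val)
    values = np.linspace(lo, hi, n_steps) if forward else np.linspace(hi, lo, n_steps)
    guess = start_guess_S
    if family == "interior" and guess is None and inside:
        eq0, _ = _family_member(p, family, None)
        guess = eq0.S if eq0 is not None else None

    prev_S = guess
    had_family = False
    for v in values:
        v = float(v)
        pp = p.replace(**{param_name: v})
        eq, n = _family_member(pp, family, prev_S)
        branch.counts.append((v, n))
        if eq is None:
            if had_family:
                branch.truncated = True
            continue
        if (family == "interior" and prev_S is not None and branch.samples
                and abs(eq.S - prev_S) > 0.05):
            # resolve the jump: insert midpoints between the last two values
            v_prev = branch.samples[-1].param_value
            for vv in np.linspace(v_prev, v, 8)[1:-1]:
                ppp = p.replace(**{param_name: float(vv)})
                eq2, _ = _family_member(ppp, family, prev_S)
                if eq2 is None:
                    break
                branch.samples.append(_sample(ppp, float(vv), eq2, n))
                prev_S = eq2.S
            eq, n = _family_member(pp, family, prev_S)
            if eq is None:
                branch.truncated = True
                continue
        branch.samples.append(_sample(pp, v, eq, n))
        prev_S = eq.S
        had_family = True
    if not forward:
        branch.samples.reverse()
        branch.counts.reverse()
    return branch


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _interior_count(p: Params, param_name: str, v: float) -> int:
    pp = p.replace(**{param_name: v})
    return len([e for e in interior_equilibria(pp) if e.exists])


def detect_fold(branch: Branch) -> list[BifurcationPoint]:
    """Folds of the interior family: admissible-root-count transitions that
    are not boundary exits.

    Between consecutive branch samples whose interior counts differ, the
    transition is first bracketed by bisection on the count, then refined
    to the exact double-root condition f(S) = f'(S) = 0 of the reduced
    nullcline problem (Brent iterations on the critical value of f as a
    function of the parameter).  The vanishing coordinate of the merging
    pair distinguishes a genuine fold (coordinates bounded away from zero,
    Jacobian determinant -> 0) from a transcritical exit through a
    boundary face, which is skipped here.
    """
    from .equilibria import (interior_root_function as f_of,
                             interior_root_derivative as df_of,
                             _interior_state)
    p, name = branch.base_params, branch.param_name
    out = []
    for (va, na), (vb, nb) in zip(branch.counts, branch.counts[1:]):
        if na == nb:
            continue
        lo, hi = va, vb
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if _interior_count(p, name, mid) == na:
                lo = mid
            else:
                hi = mid
        side = lo if na > nb else hi
        pp = p.replace(**{name: side})
        eqs = [e for e in interior_equilibria(pp) if e.exists]
        if len(eqs) < 2:
            continue  # single root entered/left the domain: not a fold
        ds = [(abs(eqs[i + 1].S - eqs[i].S), i) for i in range(len(eqs) - 1)]
        gap, i0 = min(ds)
        S1, S2 = eqs[i0].S, eqs[i0 + 1].S
        if min(np.min(eqs[i0].state), np.min(eqs[i0 + 1].state)) < 1e-6:
            continue  # boundary exit, not a fold
        s_ext = [brentq(lambda s: float(df_of(s, pp)), S1, S2, xtol=1e-14)]

        def critical_value(v):
            q = p.replace(**{name: v})
            delta = max(10.0 * gap, 1e-4)
            while delta < 0.5:
                a, b = max(s_ext[0] - delta, 1e-9), min(s_ext[0] + delta,
                                                        1.0 - 1e-9)
                if df_of(a, q) * df_of(b, q) < 0:
                    s_ext[0] = brentq(lambda s: float(df_of(s, q)), a, b,
                                      xtol=1e-14)
                    return float(f_of(s_ext[0], q))
                delta *= 2.0
            raise RuntimeError("lost the fold's critical point")

        v = brentq(critical_value, va, vb, xtol=PARAM_XTOL)
        critical_value(v)
        pp = p.replace(**{name: v})
        x = _interior_state(s_ext[0], pp)
        detJ = float(np.linalg.det(jacobian(x, pp)))
        out.append(BifurcationPoint(
            "fold", name, float(v), x,
            diagnostics={"det_J": detJ, "count_before": na,
                         "count_after": nb,
                         "zero_eigenvalue_residual": abs(detJ)}))
    return out


def _transverse_eigenvalue(family: str, p: Params) -> float | None:
    """Closed-form eigenvalue of a boundary family along its missing species."""
    if family == "E1":
        return None  # two transverse directions; handled separately
    if family == "E2":
        if p.A4 <= p.A1 * p.A3:
            return None
        B1 = p.A1 * p.A3 / p.A4
        C1 = (p.A4 - p.A1 * p.A3) / p.A4
        return p.A5 * B1 - p.A6 * C1 - p.A7 + p.A8 * B1 * C1
    if family == "E3":
        if p.A5 <= p.A7:
            return None
        B2 = p.A7 / p.A5
        D1 = (p.A5 - p.A7) / p.A5
        return p.A4 * B2 / (p.A1 + D1) - p.A2 * D1 - p.A3
    return None


def _e1_eigenvalues(p: Params) -> dict:
    return {"P1": p.A4 / p.A1 - p.A3, "P2": p.A5 - p.A7}


def detect_transcritical(branches: list[Branch]) -> list[BifurcationPoint]:
    """Transcritical points where a boundary family exchanges stability with
    another family crossing through it.

    For E2/E3 branches the transverse eigenvalue has a closed form whose
    zero is refined by Brent's method; for E1 both transverse eigenvalues
    are scanned.  Stability exchange is confirmed from the branch samples on
    either side.
    """
    out = []
    for branch in branches:
        if branch.family == "interior" or len(branch.samples) < 2:
            continue
        p, name = branch.base_params, branch.param_name
        values = branch.param_values

        def crossings(fn):
            vals = [fn(p.replace(**{name: float(v)})) for v in values]
            found = []
            for i in range(len(vals) - 1):
                a, b = vals[i], vals[i + 1]
                if a is None or b is None or not np.isfinite(a * b):
                    continue
                if a == 0.0 or a * b < 0:
                    found.append(brentq(
                        lambda v: fn(p.replace(**{name: float(v)})),
                        values[i], values[i + 1], xtol=PARAM_XTOL))
            return found

        if branch.family == "E1":
            for direction in ("P1", "P2"):
                for v in crossings(lambda pp, d=direction: _e1_eigenvalues(pp)[d]):
                    pp = p.replace(**{name: float(v)})
                    eq = _boundary_member(pp, "E1")
                    out.append(BifurcationPoint(
                        "transcritical", name, float(v), eq.state,
                        diagnostics={"family": "E1",
                                     "invading_species": direction}))
        else:
            for v in crossings(lambda pp: _transverse_eigenvalue(branch.family, pp)):
                pp = p.replace(**{name: float(v)})
                eq = _boundary_member(pp, branch.family)
                out.append(BifurcationPoint(
                    "transcritical", name, float(v), eq.state,
                    diagnostics={"family": branch.family}))
    return out


def sotomayor_quantities(eq: Equilibrium, p: Params, param_name: str,
                         simple_tol: float = 1e-6):
    """The three transcritical test quantities at a simple-zero-eigenvalue
    equilibrium: Q.K_mu, Q.(DK_mu)P and (1/2) Q.D2F(P,P).

    P and Q are right/left null vectors of the Jacobian, scaled so the last
    entry of largest magnitude equals +1 (the convention under which the
    worked E1 example gives exactly (0, 1, -A5)); K_mu is the parameter
    derivative of the vector field.  The second-derivative quantity uses the
    1/2 Taylor-coefficient convention, (1/2) Q.D2F(P,P).  Transcritical
    pattern: first quantity 0, other two nonzero.
    """
    J = jacobian(eq.state, p)
    w, vr = np.linalg.eig(J)
    order = np.argsort(np.abs(w))
    if abs(w[order[0]]) > simple_tol or abs(w[order[1]]) < simple_tol:
        raise ValueError("Jacobian does not have a simple (near-)zero eigenvalue")

    def _scale(v):
        v = np.real(v)
        pivots = np.nonzero(np.abs(v) > 1e-8 * np.abs(v).max())[0]
        return v / v[pivots[-1]]

    P = _scale(vr[:, order[0]])
    wl, vl = np.linalg.eig(J.T)
    Q = _scale(vl[:, int(np.argmin(np.abs(wl)))])

    h = 1e-6 * max(1.0, abs(getattr(p, param_name)))

    def K(v, x):
        return rhs(x, p.replace(**{param_name: v}))

    v0 = getattr(p, param_name)
    K_mu = (K(v0 + h, eq.state) - K(v0 - h, eq.state)) / (2 * h)
    eps = 1e-6
    DK_mu_P = ((K(v0 + h, eq.state + eps * P) - K(v0 + h, eq.state - eps * P))
               - (K(v0 - h, eq.state + eps * P) - K(v0 - h, eq.state - eps * P))
               ) / (4 * eps * h)
    H = second_order_tensor(eq.state, p)
    D2F_PP = 0.5 * bilinear(H, P, P)
    return (float(Q @ K_mu), float(Q @ DK_mu_P), float(Q @ D2F_PP))


def _liu_V(p: Params, param_name: str, v: float, guess_S: float):
    pp = p.replace(**{param_name: v})
    eqs = [e for e in interior_equilibria(pp) if e.exists]
    if not eqs:
        return None
    eq = min(eqs, key=lambda e: abs(e.S - guess_S))
    c1, c2, c3 = characteristic_coefficients(jacobian(eq.state, pp))
    return c1 * c2 - c3, eq, (c1, c2, c3)


def detect_hopf(branch: Branch, attach_normal_form: bool = True
                ) -> list[BifurcationPoint]:
    """Hopf points on an interior branch: zeros of V = c1*c2 - c3 with
    c1, c2, c3 > 0 (Liu's criterion), Brent-refined in the parameter.

    Boundary-family branches never yield Hopf points here (their test
    function has no admissible zero), matching the model's analytic result
    that E2/E3 cannot undergo Hopf bifurcation.

    Diagnostics per point: omega = sqrt(c2), critical eigenvalue pair,
    branch-derivative transversality numerator dV/dmu and eigenvalue
    crossing rate dRe(lambda)/dmu = -(dV/dmu) / (2*(c2 + c1^2)).
    """
    if branch.family != "interior":
        return []
    p, name = branch.base_params, branch.param_name
    out = []
    samples = branch.samples
    for a, b in zip(samples, samples[1:]):
        Va = a.char_coeffs[0] * a.char_coeffs[1] - a.char_coeffs[2]
        Vb = b.char_coeffs[0] * b.char_coeffs[1] - b.char_coeffs[2]
        if not (Va * Vb < 0):
            continue
        if min(a.char_coeffs[1], b.char_coeffs[1]) <= 0:
            continue
        guess = [a.equilibrium.S]

        def f(v):
            r = _liu_V(p, name, v, guess[0])
            guess[0] = r[1].S
            return r[0]

        v = brentq(f, a.param_value, b.param_value, xtol=PARAM_XTOL)
        V0, eq, (c1, c2, c3) = _liu_V(p, name, v, guess[0])
        if not (c1 > 0 and c2 > 0 and c3 > 0):
            continue
        om = float(np.sqrt(c2))
        h = 1e-6 * max(1.0, abs(v))
        rp = _liu_V(p, name, v + h, eq.S)
        rm = _liu_V(p, name, v - h, eq.S)
        dV = (rp[0] - rm[0]) / (2 * h)
        dG = (np.array(rp[2]) - np.array(rm[2])) / (2 * h)
        dre = -dV / (2.0 * (c2 + c1 ** 2))
        pp = p.replace(**{name: v})
        eig = np.linalg.eigvals(jacobian(eq.state, pp))
        nf = None
        if attach_normal_form:
            nf = lyapunov_coefficients(eq.state, pp, order=1)
        out.append(BifurcationPoint(
            "hopf", name, float(v), eq.state, normal_form=nf,
            diagnostics={
                "omega": om, "V_residual": abs(V0),
                "char_coeffs": (c1, c2, c3),
                "transversality_dV": float(dV),
                "transversality_dre": float(dre),
                "dchar_coeffs": tuple(dG),
                "critical_pair": eig[np.argsort(np.abs(eig.real))][:2],
            }))
    return out


# ---------------------------------------------------------------------------
# Two-parameter Hopf locus and Bautin points
# ---------------------------------------------------------------------------

def _hopf_location(p: Params, param_name: str, bounds, guess=None,
                   n_scan: int = 160) -> list[float]:
    """All Hopf parameter values in ``bounds`` (scan + Brent refinement)."""
    lo, hi = bounds
    values = np.linspace(lo, hi, n_scan)
    Vs = []
    for v in values:
        r = _liu_V(p, param_name, float(v), guess if guess is not None else 0.5)
        if r is not None and r[2][1] > 0:
            Vs.append((float(v), r[0]))
        else:
            Vs.append((float(v), None))
    roots = []
    for (a, Va), (b, Vb) in zip(Vs, Vs[1:]):
        if Va is None or Vb is None or not (Va * Vb < 0):
            continue
        g = [guess if guess is not None else 0.5]

        def f(v):
            r = _liu_V(p, param_name, v, g[0])
            g[0] = r[1].S
            return r[0]

        roots.append(brentq(f, a, b, xtol=PARAM_XTOL))
    return roots


def hopf_curve_and_bautin(p: Params, param_pair, ranges,
                          n_grid: int = 80) -> dict:
    """Continue the Hopf locus in two parameters and locate Bautin points.

    ``param_pair`` = (abscissa, solved-for): for each abscissa value on a
    deterministic grid over ``ranges[0]``, the second parameter is solved
    from the Hopf condition V = 0 within ``ranges[1]`` (continuity selects
    among multiple roots).  The first Lyapunov coefficient is evaluated
    along the curve; its sign changes are bisected on the abscissa and the
    second Lyapunov coefficient is computed at each located Bautin point.
    """
    name_a, name_b = param_pair
    (a_lo, a_hi), b_range = ranges
    grid = np.linspace(a_lo, a_hi, n_grid)
    curve = []          # (a, b, l1)
    prev_b = None
    for a in grid:
        pa = p.replace(**{name_a: float(a)})
        roots = _hopf_location(pa, name_b, b_range)
        if not roots:
            curve.append((float(a), None, None))
            continue
        b = (min(roots, key=lambda r: abs(r - prev_b))
             if prev_b is not None else roots[0])
        prev_b = b
        pab = pa.replace(**{name_b: float(b)})
        eqs = [e for e in interior_equilibria(pab) if e.exists]
        eq = min(eqs, key=lambda e: abs(
            characteristic_coefficients(jacobian(e.state, pab))[0]
            * characteristic_coefficients(jacobian(e.state, pab))[1]
            - characteristic_coefficients(jacobian(e.state, pab))[2]), default=None)
        if eq is None:
            curve.append((float(a), float(b), None))
            continue
        try:
            l1 = lyapunov_coefficients(eq.state, pab, order=1).l1
        except ValueError:
            l1 = None
        curve.append((float(a), float(b), l1))

    def l1_at(a, b_guess):
        pa = p.replace(**{name_a: float(a)})
        roots = _hopf_location(pa, name_b, b_range)
        b = min(roots, key=lambda r: abs(r - b_guess))
        pab = pa.replace(**{name_b: float(b)})
        eqs = [e for e in interior_equilibria(pab) if e.exists]

        def V_of(e):
            c1, c2, c3 = characteristic_coefficients(jacobian(e.state, pab))
            return abs(c1 * c2 - c3)

        eq = min(eqs, key=V_of)
        return lyapunov_coefficients(eq.state, pab, order=1).l1, b, eq, pab

    bautin = []
    pts = [(a, b, l1) for a, b, l1 in curve if l1 is not None]
    for (a1, b1, l1a), (a2, b2, l1b) in zip(pts, pts[1:]):
        if not (l1a * l1b < 0):
            continue
        bg = [0.5 * (b1 + b2)]

        def g(a):
            l1, b, _, _ = l1_at(a, bg[0])
            bg[0] = b
            return l1

        a_star = brentq(g, a1, a2, xtol=1e-8)
        l1_star, b_star, eq, pab = l1_at(a_star, bg[0])
        nf = lyapunov_coefficients(eq.state, pab, order=2)
        bautin.append(BifurcationPoint(
            "bautin", f"{name_a},{name_b}", float(a_star), eq.state,
            normal_form=nf,
            diagnostics={name_a: float(a_star), name_b: float(b_star),
                         "l1_residual": abs(l1_star), "l2": nf.l2}))
    return {"curve": curve, "bautin": bautin,
            "param_pair": (name_a, name_b)}
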