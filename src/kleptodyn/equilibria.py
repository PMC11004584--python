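"""Equilibria of the scaled model: closed-form boundary states and interior
(coexistence) states via two independent routes.

Boundary equilibria
    E0 = (0,0,0)                      total extinction (always present)
    E1 = (1,0,0)                      prey at carrying capacity
    E2 = (A1*A3/A4, 1 - A1*A3/A4, 0)  kleptoparasite-free  (needs A4 > A1*A3)
    E3 = (A7/A5, 0, 1 - A7/A5)        host-free            (needs A5 > A7)
    E4 = (0, -A7/A6, -A3/A2)          prey-free; never admissible

Interior equilibria solve the nullcline system.  The primary route reduces
it to a scalar problem: the host nullcline gives P2 as the positive root of

    A2*P2^2 + (A1*A2 + A3)*P2 + (A1*A3 - A4*S) = 0,

the prey nullcline gives P1 = 1 - S - P2, and S* is a root of the
kleptoparasite nullcline residual

    f(S) = A5*S - A6*P1(S) - A7 + A8*P1(S)*S

on (0, 1).  An independent route solves the degree-4 elimination polynomial
in S* and back-substitutes; both routes must agree and are cross-checked in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import Params, rhs

#: a coordinate counts as strictly positive above this tolerance
ADMISSIBILITY_TOL = 1e-9


@dataclass(frozen=True)
class Equilibrium:
    """A labeled root of the nullcline system."""

    label: str
    state: np.ndarray
    exists: bool
    residual: float

    @property
    def S(self) -> float:
        return float(self.state[0])

    @property
    def P1(self) -> float:
        return float(self.state[1])

    @property
    def P2(self) -> float:
        return float(self.state[2])


@dataclass(frozen=True)
class QuarticCoefficients:
    """Coefficients gamma1..gamma5 of the interior-S elimination polynomial."""

    gamma1: float
    gamma2: float
    gamma3: float
    gamma4: float
    gamma5: float

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma1, self.gamma2, self.gamma3,
                         self.gamma4, self.gamma5])


def _make(label, state, p, exists=None):
    state = np.asarray(state, dtype=float)
    res = float(np.linalg.norm(rhs(state, p)))
    if exists is None:
        exists = bool(np.all(state >= -ADMISSIBILITY_TOL))
    return Equilibrium(label, state, exists, res)


def boundary_equilibria(p: Params) -> list[Equilibrium]:
    """All boundary equilibria with their admissibility flags."""
    out = [
        _make("E0", (0.0, 0.0, 0.0), p, exists=True),
        _make("E1", (1.0, 0.0, 0.0), p, exists=True),
    ]
    # E2: kleptoparasite-free
    B1 = p.A1 * p.A3 / p.A4
    C1 = (p.A4 - p.A1 * p.A3) / p.A4
    out.append(_make("E2", (B1, C1, 0.0), p, exists=p.A4 > p.A1 * p.A3))
    # E3: host-free
    B2 = p.A7 / p.A5
    D1 = (p.A5 - p.A7) / p.A5
    out.append(_make("E3", (B2, 0.0, D1), p, exists=p.A5 > p.A7))
    # E4: prey-free, coordinates negative for any positive parameters
    C2, D2 = -p.A7 / p.A6, -p.A3 / p.A2
    out.append(Equilibrium("E4", np.array([0.0, C2, D2]), False,
                           float(np.linalg.norm(rhs((0.0, C2, D2), p)))))
    return out


def quartic_coefficients(p: Params) -> QuarticCoefficients:
    """Closed-form coefficients of the interior elimination quartic in S*.

    The same polynomial (up to the positive factor 4*A2) arises as the
    resultant of the host nullcline quadratic and the kleptoparasite
    nullcline after substituting P1 = 1 - S - P2.
    """
    A1, A2, A3, A4 = p.A1, p.A2, p.A3, p.A4
    A5, A6, A7, A8 = p.A5, p.A6, p.A7, p.A8
    g1 = 4 * A2 ** 2 * A8 ** 2
    g2 = -4 * A2 * A8 * (2 * A2 * (A5 + A6) + ((2 + A1) * A2 + A3 + A4) * A8)
    g3 = 4 * A2 * (A2 * (A5 + A6) ** 2
                   + (A3 * A5 + 2 * (A3 + A4) * A6
                      + (2 + A1) * A2 * (A5 + 2 * A6) + 2 * A2 * A7) * A8
                   + (1 + A1) * (A2 + A3) * A8 ** 2)
    g4 = -4 * A2 * (A4 * A6 ** 2 + A3 * A6 * (A5 + A6)
                    + A2 * (A5 + A6) * ((2 + A1) * A6 + 2 * A7)
                    + (A3 * (2 * (1 + A1) * A6 + A7)
                       + A2 * (2 * (1 + A1) * A6 + (2 + A1) * A7)) * A8)
    g5 = 4 * A2 * (A6 + A1 * A6 + A7) * (A3 * A6 + A2 * (A6 + A7))
    return QuarticCoefficients(g1, g2, g3, g4, g5)


def klepto_free_predator_nullcline_P2(S, p: Params):
    """Positive root P2(S) of the host nullcline quadratic.

    Real for every S > 0 (the discriminant is (A1*A2 - A3)^2 + 4*A2*A4*S plus
    a positive term); positive iff A4*S > A1*A3.
    """
    b = p.A1 * p.A2 + p.A3
    disc = b * b - 4.0 * p.A2 * (p.A1 * p.A3 - p.A4 * np.asarray(S))
    return (-b + np.sqrt(disc)) / (2.0 * p.A2)


def interior_root_function(S, p: Params):
    """Residual f(S) of the kleptoparasite nullcline on the reduced problem."""
    P2 = klepto_free_predator_nullcline_P2(S, p)
    P1 = 1.0 - np.asarray(S) - P2
    return p.A5 * np.asarray(S) - p.A6 * P1 - p.A7 + p.A8 * P1 * np.asarray(S)


def interior_root_derivative(S, p: Params):
    """d/dS of :func:`interior_root_function` (closed form)."""
    b = p.A1 * p.A2 + p.A3
    disc = b * b - 4.0 * p.A2 * (p.A1 * p.A3 - p.A4 * np.asarray(S))
    dP2 = p.A4 / np.sqrt(disc)
    dP1 = -1.0 - dP2
    P1 = 1.0 - np.asarray(S) - klepto_free_predator_nullcline_P2(S, p)
    return p.A5 - p.A6 * dP1 + p.A8 * (P1 + np.asarray(S) * dP1)


def _interior_state(S, p: Params):
    P2 = float(klepto_free_predator_nullcline_P2(S, p))
    return np.array([S, 1.0 - S - P2, P2])


def interior_equilibria(p: Params, n_scan: int = 4096,
                        tol: float = ADMISSIBILITY_TOL) -> list[Equilibrium]:
    """All admissible coexistence equilibria, labeled interior-1, interior-2,
    ... by ascending prey density S*.

    Roots of f(S) are bracketed on a uniform scan of (0, 1) and refined by
    Brent's method.  f is smooth on all of (0, 1) (its discriminant is
    bounded below by (A1*A2 - A3)^2 + 4*A2*A4*S > 0), so sign changes are
    bracketed everywhere and admissibility -- S*, P1*, P2* all above
    ``tol`` -- is judged at the refined root; this keeps roots that graze a
    boundary face inside a window narrower than the scan step.
    Deterministic: no random starts.
    """
    S = np.linspace(tol, 1.0 - tol, n_scan + 1)
    f = interior_root_function(S, p)
    roots: list[float] = []
    fn = lambda s: float(interior_root_function(s, p))
    sign_change = f[:-1] * f[1:] < 0
    for i in np.nonzero(sign_change)[0]:
        roots.append(brentq(fn, S[i], S[i + 1], xtol=1e-15, rtol=8.9e-16))
    out = []
    k = 0
    for s in sorted(roots):
        x = _interior_state(s, p)
        if np.all(x > tol):
            k += 1
            out.append(_make(f"interior-{k}", x, p, exists=True))
        else:
            out.append(_make("interior-grazing", x, p, exists=False))
    return out


def interior_from_quartic(p: Params, tol: float = 1e-7) -> list[Equilibrium]:
    """Independent interior-equilibrium route through the elimination quartic.

    Real roots of the quartic in (0, 1) are back-substituted through the
    closed forms for P2* and P1*; elimination introduces spurious roots
    (from the squared radical), so candidates are filtered by the rhs
    residual and admissibility.  Used as a consistency cross-check of
    :func:`interior_equilibria`.
    """
    gam = quartic_coefficients(p).as_array()
    out = []
    k = 0
    for r in sorted(np.roots(gam)):
        if abs(r.imag) > 1e-9 or not (0.0 < r.real < 1.0):
            continue
        x = _interior_state(float(r.real), p)
        if np.all(x > ADMISSIBILITY_TOL):
            eq = _make(f"candidate", x, p, exists=True)
            if eq.residual < tol:
                k += 1
                out.append(Equilibrium(f"interior-{k}", eq.state, True,
                                       eq.residual))
    return out
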