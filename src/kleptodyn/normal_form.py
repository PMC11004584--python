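"""Hopf normal form: first and second Lyapunov coefficients.

Two independent computations are provided.

* :func:`hopf_normal_form` implements the projection method for the first
  Lyapunov coefficient: with A q = i*omega*q, A^T p = -i*omega*p,
  <p, q> = 1 and <q, q> = 1, and B/C the second/third multilinear forms of
  the vector field,

      l1 = Re <p, C(q,q,qbar) - 2 B(q, A^{-1} B(q,qbar))
                 + B(qbar, (2 i omega I - A)^{-1} B(q,q))> / (2 omega).

  This is the invariant expression: it is unchanged by the free phase of q
  (a property exercised in the tests).

* :func:`lyapunov_coefficients` reduces the three-dimensional system to its
  two-dimensional center manifold at the Hopf point (the third eigenvalue is
  real and hyperbolic), expands the restricted system to fifth order, and
  performs a Poincare normal-form transformation numerically, yielding both
  l1 = Re(c1)/omega and l2 = Re(c2)/omega from the resonant cubic and
  quintic coefficients.  Agreement of the two l1 routes validates the
  machinery that produces l2.

The sign conventions are: l1 > 0 subcritical Hopf (unstable cycle),
l1 < 0 supercritical (stable cycle); at a Bautin point l1 = 0 and l2 != 0.
The overall positive scale of l2 depends on eigenvector normalization, so
only its sign is comparable across implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (Params, jacobian, second_order_tensor, third_order_tensor,
                    bilinear, trilinear)

HOPF_RE_TOL = 1e-8


class EigenstructureError(ValueError):
    """Raised when the Jacobian lacks a simple imaginary eigenvalue pair."""


@dataclass(frozen=True)
class HopfNormalForm:
    omega: float
    g20: complex
    g11: complex
    g21: complex
    l1: float
    l2: float | None
    q: np.ndarray
    p: np.ndarray
    normalization: str = "<q,q>=1, <p,q>=1"


def _eigentriple(A, re_tol: float = HOPF_RE_TOL):
    """Right/left eigenvectors of the critical pair and the real eigenvalue."""
    w, vr = np.linalg.eig(A)
    i_im = int(np.argmax(w.imag))
    lam = w[i_im]
    if lam.imag <= 0 or abs(lam.real) > re_tol:
        raise EigenstructureError(
            f"eigenvalues {w} do not contain a simple pair on the imaginary axis")
    om = float(lam.imag)
    q = vr[:, i_im]
    q = q / np.sqrt(np.vdot(q, q))
    wl, vl = np.linalg.eig(A.T)
    p = vl[:, int(np.argmin(np.abs(wl - np.conj(lam))))]
    p = p / np.conj(np.vdot(p, q))
    i_re = int(np.argmin(np.abs(w.imag)))
    lam3 = float(w[i_re].real)
    v = np.real(vr[:, i_re])
    v = v / np.linalg.norm(v)
    wvec = np.real(vl[:, int(np.argmin(np.abs(wl - lam3)))])
    wvec = wvec / np.dot(wvec, v)
    return om, q, p, lam3, v, wvec


def hopf_normal_form(x, p: Params, re_tol: float = HOPF_RE_TOL) -> HopfNormalForm:
    """First Lyapunov coefficient at an equilibrium with eigenvalues +-i*omega."""
    A = jacobian(x, p)
    om, q, pvec, _, _, _ = _eigentriple(A, re_tol)
    H = second_order_tensor(x, p)
    T = third_order_tensor(x, p)
    qb = np.conj(q)
    g20 = np.vdot(pvec, bilinear(H, q, q))
    g11 = np.vdot(pvec, bilinear(H, q, qb))
    h11 = np.linalg.solve(A, bilinear(H, q, qb))
    h20 = np.linalg.solve(2j * om * np.eye(3) - A, bilinear(H, q, q))
    g21 = np.vdot(pvec, trilinear(T, q, q, qb)
                  - 2.0 * bilinear(H, q, h11) + bilinear(H, qb, h20))
    l1 = float(g21.real / (2.0 * om))
    return HopfNormalForm(om, complex(g20), complex(g11), complex(g21),
                          l1, None, q, pvec)


# ---------------------------------------------------------------------------
# Polynomial series in (z, zbar): dict {(j, k): complex coefficient}
# ---------------------------------------------------------------------------

def _padd(a, b):
    out = dict(a)
    for k, v in b.items():
        out[k] = out.get(k, 0.0) + v
    return {k: v for k, v in out.items() if v != 0.0}


def _pscale(a, c):
    return {k: v * c for k, v in a.items()}


def _pmul(a, b, deg):
    out: dict = {}
    for (j1, k1), v1 in a.items():
        for (j2, k2), v2 in b.items():
            if j1 + j2 + k1 + k2 > deg:
                continue
            key = (j1 + j2, k1 + k2)
            out[key] = out.get(key, 0.0) + v1 * v2
    return out


def _ppow(a, n, deg):
    out = {(0, 0): 1.0 + 0.0j}
    for _ in range(n):
        out = _pmul(out, a, deg)
    return out


def _pconj(a):
    return {(k, j): np.conj(v) for (j, k), v in a.items()}


def _series_rhs(xstar, p: Params, u, deg):
    """Taylor series of the full vector field at xstar + u, u poly in (z,zbar).

    Only the host-growth term is non-polynomial; its 1/(A1 + P2) factor is
    expanded as a geometric series, exact to the truncation degree.
    """
    S0, P10, P20 = xstar
    u1, u2, u3 = u
    one = {(0, 0): 1.0 + 0.0j}
    S = _padd({(0, 0): S0 + 0.0j}, u1)
    P1 = _padd({(0, 0): P10 + 0.0j}, u2)
    P2 = _padd({(0, 0): P20 + 0.0j}, u3)
    F1 = _padd(_pmul(S, _padd(one, _pscale(S, -1.0)), deg),
               _pscale(_pmul(S, _padd(P1, P2), deg), -1.0))
    ub = p.A1 + P20
    inv = {}
    for m in range(deg + 1):
        inv = _padd(inv, _pscale(_ppow(u3, m, deg), (-1.0) ** m / ub ** (m + 1)))
    F2 = _padd(_pscale(_pmul(_pmul(S, P1, deg), inv, deg), p.A4),
               _padd(_pscale(_pmul(P1, P2, deg), -p.A2), _pscale(P1, -p.A3)))
    F3 = _padd(_padd(_pscale(_pmul(S, P2, deg), p.A5),
                     _padd(_pscale(_pmul(P1, P2, deg), -p.A6),
                           _pscale(P2, -p.A7))),
               _pscale(_pmul(_pmul(P1, P2, deg), S, deg), p.A8))
    return F1, F2, F3


def _restricted_field(xstar, p: Params, deg: int = 5):
    """Coefficients of zdot on the center manifold, to total degree ``deg``.

    The hyperbolic direction is one-dimensional (real eigenvalue lam3 < 0
    at a Hopf point with c3 > 0); its graph y = h(z, zbar) is solved order
    by order from the invariance equation ydot = h_z zdot + h_zbar zbardot.
    """
    A = jacobian(xstar, p)
    om, q, pvec, lam3, v, wvec = _eigentriple(A)
    h: dict = {}
    for n in range(2, deg):
        u = []
        for i in range(3):
            ui = {(1, 0): q[i], (0, 1): np.conj(q[i])}
            u.append(_padd(ui, _pscale(h, v[i])))
        F = _series_rhs(xstar, p, u, deg)
        Pz: dict = {}
        Qy: dict = {}
        for i in range(3):
            Pz = _padd(Pz, _pscale(F[i], np.conj(pvec[i])))
            Qy = _padd(Qy, _pscale(F[i], wvec[i]))
        Pz = {k: val for k, val in Pz.items() if k[0] + k[1] >= 2}
        Qy = {k: val for k, val in Qy.items() if k[0] + k[1] >= 2}
        hz = {(j - 1, k): j * val for (j, k), val in h.items() if j >= 1}
        hzb = {(j, k - 1): k * val for (j, k), val in h.items() if k >= 1}
        zdot = _padd({(1, 0): 1j * om}, Pz)
        feedback = _padd(_pmul(hz, zdot, deg), _pmul(hzb, _pconj(zdot), deg))
        for jk in [(j, n - j) for j in range(n + 1)]:
            j, k = jk
            rhs_coeff = Qy.get(jk, 0.0) - feedback.get(jk, 0.0)
            h[jk] = rhs_coeff / ((j - k) * 1j * om - lam3)
    u = []
    for i in range(3):
        ui = {(1, 0): q[i], (0, 1): np.conj(q[i])}
        u.append(_padd(ui, _pscale(h, v[i])))
    F = _series_rhs(xstar, p, u, deg)
    Pz = {}
    for i in range(3):
        Pz = _padd(Pz, _pscale(F[i], np.conj(pvec[i])))
    Pz.pop((0, 0), None)
    return om, {k: v for k, v in Pz.items() if k[0] + k[1] <= deg}


def poincare_normal_form(om: float, f: dict, deg: int = 5) -> dict:
    """Remove non-resonant terms of zdot = i om z + ... order by order.

    ``f`` maps (j, k) to the coefficient of z^j zbar^k (linear term
    included).  Returns the normal-form field, in which only resonant terms
    z^(k+1) zbar^k survive below ``deg``.
    """
    lam = 1j * om
    for n in range(2, deg + 1):
        phi = {}
        for (j, k), a in f.items():
            if j + k == n and j != k + 1:
                phi[(j, k)] = a / ((j - k - 1) * lam)
        if not phi:
            continue
        zofz = _padd({(1, 0): 1.0 + 0.0j}, phi)
        zbofz = _pconj(zofz)
        fcomp: dict = {}
        for (j, k), a in f.items():
            term = _pmul(_ppow(zofz, j, deg), _ppow(zbofz, k, deg), deg)
            fcomp = _padd(fcomp, _pscale(term, a))
        phz = {(j - 1, k): j * val for (j, k), val in phi.items() if j >= 1}
        phzb = {(j, k - 1): k * val for (j, k), val in phi.items() if k >= 1}
        g = dict(fcomp)
        for _ in range(deg):
            g = _padd(fcomp,
                      _pscale(_padd(_pmul(phz, g, deg),
                                    _pmul(phzb, _pconj(g), deg)), -1.0))
        f = {k: v for k, v in g.items() if k[0] + k[1] <= deg}
    return f


def lyapunov_coefficients(x, p: Params, order: int = 1) -> HopfNormalForm:
    """First (and optionally second) Lyapunov coefficient at a Hopf point.

    ``order=1`` returns the projection-method result; ``order=2`` runs the
    center-manifold/normal-form reduction to fifth order and fills in l2.
    """
    nf1 = hopf_normal_form(x, p)
    if order == 1:
        return nf1
    om, field = _restricted_field(x, p, deg=5)
    nf = poincare_normal_form(om, field, deg=5)
    c1 = nf.get((2, 1), 0.0)
    c2 = nf.get((3, 2), 0.0)
    return HopfNormalForm(nf1.omega, nf1.g20, nf1.g11, nf1.g21,
                          float(np.real(c1) / om), float(np.real(c2) / om),
                          nf1.q, nf1.p)
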