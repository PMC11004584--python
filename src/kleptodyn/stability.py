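"""Local and global stability analysis.

Local stability uses the characteristic polynomial lambda^3 + c1*lambda^2 +
c2*lambda + c3 of the Jacobian and the Routh-Hurwitz conditions for a cubic
(c1 > 0, c3 > 0, c1*c2 - c3 > 0).  The per-equilibrium parametric stability
conditions of the model are evaluated alongside an eigenvalue cross-check.

Global stability is handled through Lyapunov-function *certificates*: the
sufficient inequality systems for the predator-free state E1 and for the
coexistence state are evaluated over user-supplied box bounds and weights.
A failed certificate never implies instability; an optional deterministic
grid search can look for a satisfying configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .model import Params, jacobian, rhs
from .equilibria import Equilibrium, boundary_equilibria, interior_equilibria

#: |Re lambda| below this counts as marginal (needed near bifurcation points)
MARGINAL_TOL = 1e-8


def characteristic_coefficients(J) -> tuple[float, float, float]:
    """(c1, c2, c3) of lambda^3 + c1 l^2 + c2 l + c3 = det(lambda I - J).

    c1 = -trace, c2 = sum of principal 2x2 minors, c3 = -det.
    """
    J = np.asarray(J, dtype=float)
    c1 = -np.trace(J)
    c2 = (J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
          + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
          + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
    c3 = -np.linalg.det(J)
    return float(c1), float(c2), float(c3)


@dataclass(frozen=True)
class RouthHurwitz:
    c1: float
    c2: float
    c3: float

    @property
    def discriminant(self) -> float:
        """The Liu test function V = c1*c2 - c3 (zero at a Hopf point)."""
        return self.c1 * self.c2 - self.c3

    @property
    def conditions(self) -> dict:
        return {"c1 > 0": self.c1 > 0, "c3 > 0": self.c3 > 0,
                "c1*c2 - c3 > 0": self.discriminant > 0}

    @property
    def stable(self) -> bool:
        return all(self.conditions.values())


def routh_hurwitz(c1: float, c2: float, c3: float) -> RouthHurwitz:
    return RouthHurwitz(float(c1), float(c2), float(c3))


def classify_eigenvalues(eigvals, tol: float = MARGINAL_TOL) -> str:
    re = np.real(eigvals)
    if np.any(np.abs(re) <= tol):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


@dataclass(frozen=True)
class StabilityReport:
    """Stability verdict for one equilibrium at one parameter set."""

    label: str
    equilibrium: Equilibrium
    eigenvalues: np.ndarray
    char_coeffs: tuple[float, float, float]
    routh_hurwitz: RouthHurwitz
    classification: str
    condition_report: dict = field(default_factory=dict)
    applicable: bool = True


def report_for(eq: Equilibrium, p: Params, conditions=None) -> StabilityReport:
    J = jacobian(eq.state, p)
    eig = np.linalg.eigvals(J)
    c = characteristic_coefficients(J)
    return StabilityReport(
        label=eq.label, equilibrium=eq, eigenvalues=eig, char_coeffs=c,
        routh_hurwitz=routh_hurwitz(*c),
        classification=classify_eigenvalues(eig),
        condition_report=conditions or {}, applicable=eq.exists)


def _parametric_conditions(label: str, p: Params) -> dict:
    A1, A2, A3, A4 = p.A1, p.A2, p.A3, p.A4
    A5, A6, A7, A8 = p.A5, p.A6, p.A7, p.A8
    if label == "E0":
        # one eigenvalue is +1: the extinct state always repels along prey
        return {"always unstable": True}
    if label == "E1":
        return {
            "host cannot invade (A1*A3 > A4)": A1 * A3 > A4,
            "kleptoparasite cannot invade (A7 > A5)": A7 > A5,
            "A1*A3": A1 * A3, "A4": A4, "A7": A7, "A5": A5,
        }
    if label == "E2":
        a5_threshold = (A4 * A6 - A1 * A3 * A6) / (A1 * A3)
        denom = A1 ** 2 * A3 ** 2 - A1 * A3 * A4
        a8_threshold = ((A1 * A3 * A4 * A5 + A1 * A3 * A4 * A6
                         - A4 ** 2 * A6 - A4 ** 2 * A7) / denom
                        if denom != 0 else np.inf)
        a7_threshold = (A1 * A3 * A5 + A1 * A3 * A6 - A4 * A6) / A4
        return {
            "host persists (A1*A3 < A4)": A1 * A3 < A4,
            "A5 <= A5 threshold": A5 <= a5_threshold,
            "A8 < A8 threshold": A8 < a8_threshold,
            "A5 threshold": a5_threshold, "A8 threshold": a8_threshold,
            # listed inside the proof only, not in the headline statement
            "proof-level: A7 > A7 threshold": A7 > a7_threshold,
            "A7 threshold": a7_threshold,
        }
    if label == "E3":
        a4_threshold = klepto_only_A4_threshold(p)
        return {
            "kleptoparasite persists (A5 > A7)": A5 > A7,
            "A4 <= A4 threshold": A4 <= a4_threshold,
            "A4 threshold": a4_threshold,
        }
    return {}


def klepto_only_A4_threshold(p: Params) -> float:
    """Host-invasion threshold on A4 for stability of the host-free state E3:
    (A2*A5^2 - 2*A2*A5*A7 + A2*A7^2 + A3*A5^2 - A3*A5*A7) / (A5*A7)."""
    A2, A3, A5, A7 = p.A2, p.A3, p.A5, p.A7
    return (A2 * A5 ** 2 - 2 * A2 * A5 * A7 + A2 * A7 ** 2
            + A3 * A5 ** 2 - A3 * A5 * A7) / (A5 * A7)


def stability_report(p: Params) -> dict[str, StabilityReport]:
    """Stability reports for every equilibrium (boundary and interior).

    Each report carries the closed-form parametric conditions for that
    equilibrium plus the eigenvalue-based verdict; nonexistent equilibria
    are flagged not applicable.
    """
    out = {}
    for eq in boundary_equilibria(p) + interior_equilibria(p):
        out[eq.label] = report_for(eq, p, _parametric_conditions(eq.label, p))
    return out


# ---------------------------------------------------------------------------
# Global-stability certificates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlobalStabilityConfig:
    """Weights and box bounds for a Lyapunov certificate.

    ``weights`` are the positive multipliers (L1, L2, L3) of the candidate
    Lyapunov function; ``lower``/``upper`` bound the box (S, P1, P2) over
    which trajectories are assumed to range.
    """

    weights: tuple[float, float, float]
    lower: tuple[float, float, float]
    upper: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")
        if any(lo <= 0 or lo >= hi for lo, hi in zip(self.lower, self.upper)):
            raise ValueError("box bounds must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class CertificateReport:
    holds: bool
    conditions: dict
    margins: dict


def global_stability_predator_free(p: Params,
                                   cfg: GlobalStabilityConfig) -> CertificateReport:
    """Sufficient conditions for global stability of E1 = (1, 0, 0).

    With V = L1*(S - 1 - ln S) + L2*P1 + L3*P2 and trajectories confined to
    the box, dV/dt < 0 is guaranteed by the two inequalities

        A4*L2*q2*r2 < A1*G1*(A2*L2*q1 + A7*L3)
        L1*(q2 + G2) + L3*(A5 + A8*q2)*G2*r2 < A3*L2*q1

    where (r, q, G) denote the (S, P1, P2) box bounds.
    """
    L1, L2, L3 = cfg.weights
    r1, q1, G1 = cfg.lower
    r2, q2, G2 = cfg.upper
    lhs1 = p.A4 * L2 * q2 * r2
    rhs1 = p.A1 * G1 * (p.A2 * L2 * q1 + p.A7 * L3)
    lhs2 = L1 * (q2 + G2) + L3 * (p.A5 + p.A8 * q2) * G2 * r2
    rhs2 = p.A3 * L2 * q1
    conds = {"predation-gain inequality": lhs1 < rhs1,
             "growth-dissipation inequality": lhs2 < rhs2}
    margins = {"predation-gain margin": rhs1 - lhs1,
               "growth-dissipation margin": rhs2 - lhs2}
    return CertificateReport(all(conds.values()), conds, margins)


def global_stability_coexistence(p: Params, eq: Equilibrium,
                                 cfg: GlobalStabilityConfig) -> CertificateReport:
    """Sufficient conditions for global stability of an interior equilibrium.

    Evaluates the five-inequality certificate with derived thresholds
    Upsilon2 (lower bound on the weight L2), Upsilon3 (upper bound on A4) and
    Upsilon4 (lower bound on the P1 box floor); the box is (theta, vartheta,
    Theta) for (S, P1, P2).
    """
    if not eq.exists:
        raise ValueError("certificate requires an admissible interior equilibrium")
    _, L2, L3 = cfg.weights
    th1, v1, T1 = cfg.lower
    th2, v2, T2 = cfg.upper
    Ss, P1s, P2s = eq.state
    A1, A2, A4, A5, A6, A8 = p.A1, p.A2, p.A4, p.A5, p.A6, p.A8
    den2 = A2 * (v1 * T1 - P2s * v2 + P1s * (P2s - T2))
    ups2 = (L3 * (A6 * P2s * v2 + A6 * P1s * T2 + A5 * P1s * th2
                  + A8 * v2 * T2 * th2) / den2 if den2 != 0 else np.inf)
    cross = A5 * v1 * (P1s * P2s * (A6 - A8 * Ss) + A5 * (v1 * th1 - Ss * v2))
    ups3 = (A1 * A6 * v1 * T1 * L3 * (A1 + P2s)) / (
        L2 * (2 * A1 * P1s * Ss + A1 * v2 * th2 + P2s * v2 * th2))
    ups4 = (P2s * v2 + P1s * (-P2s + T2)) / T1
    conds = {
        "P2* <= P2 box ceiling": P2s <= T2,
        "L2 > Upsilon2": L2 > ups2,
        "cross-term positivity": cross > 0,
        "A4 < Upsilon3": A4 < ups3,
        "P1 floor > Upsilon4": v1 > ups4,
    }
    margins = {"Upsilon2": ups2, "Upsilon3": ups3, "Upsilon4": ups4,
               "cross-term value": cross,
               "P2 ceiling margin": T2 - P2s}
    return CertificateReport(all(conds.values()), conds, margins)


def lyapunov_derivative_predator_free(x, p: Params, cfg: GlobalStabilityConfig):
    """dV/dt along the flow for the E1 candidate function (for sampling)."""
    L1, L2, L3 = cfg.weights
    S, P1, P2 = x
    f = rhs(x, p)
    return L1 * (S - 1.0) / S * f[0] + L2 * f[1] + L3 * f[2]


def lyapunov_derivative_coexistence(x, p: Params, eq: Equilibrium,
                                    cfg: GlobalStabilityConfig):
    """dW/dt along the flow for the coexistence candidate function."""
    L1, L2, L3 = cfg.weights
    S, P1, P2 = x
    Ss, P1s, P2s = eq.state
    f = rhs(x, p)
    return (L1 * (S - Ss) / S * f[0] + L2 * (P1 - P1s) / P1 * f[1]
            + L3 * (P2 - P2s) / P2 * f[2])


def search_certificate_predator_free(p: Params) -> GlobalStabilityConfig | None:
    """Deterministic coarse search for an E1 certificate.

    The two inequalities constrain the weight ratio t = L3/L2 to an interval
    with closed-form endpoints once the box is fixed (the satisfying wedge
    in t is typically narrow), so the search walks a lattice of boxes and
    solves for t directly, with L1/L2 taken small.  Returns the first
    satisfying configuration or None; absence of a certificate proves
    nothing about instability.
    """
    # the inequalities are conservative, so the box must be thin: upper
    # bounds sit 10% above the lower ones
    for rho2 in (0.6, 0.8, 1.05, 1.2):
        for q1 in (0.001, 0.002, 0.005, 0.01, 0.02):
            q2 = 1.1 * q1
            for G1 in (0.05, 0.1, 0.2, 0.4):
                G2 = 1.1 * G1
                s = 0.05 * p.A3 * q1 / (q2 + G2)          # L1/L2
                t_hi = 0.9 * (p.A3 * q1 - s * (q2 + G2)) / (
                    (p.A5 + p.A8 * q2) * G2 * rho2)
                t_lo = (p.A4 * q2 * rho2 / (p.A1 * G1) - p.A2 * q1) / p.A7
                if t_hi <= 0 or max(t_lo, 0.0) >= t_hi:
                    continue
                t = 0.5 * (max(t_lo, 0.0) + t_hi)
                cfg = GlobalStabilityConfig(
                    (s, 1.0, t), (0.5 * rho2, q1, G1), (rho2, q2, G2))
                if global_stability_predator_free(p, cfg).holds:
                    return cfg
    return None
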