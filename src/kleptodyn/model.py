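"""Core model definitions: parameters, vector fields, Jacobian, derivative tensors.

The model describes one prey (scaled density ``S``) shared by two predators:
a *host* predator (``P1``) that hunts with a Holling type-I response, and a
*kleptoparasite* (``P2``) that both hunts the prey and steals a fraction of
the host's kills.  The host may counter-attack after being robbed; the
conversion rate of stolen food therefore grows with the kleptoparasite's
group size.  After nondimensionalization the dynamics are governed by eight
positive coefficients ``A1..A8``::

    dS/dt  = S(1 - S) - S*P1 - S*P2
    dP1/dt = A4*S*P1/(A1 + P2) - A2*P1*P2 - A3*P1
    dP2/dt = A5*S*P2 - A6*P1*P2 - A7*P2 + A8*P1*P2*S

``A1`` measures (inverse) kleptoparasitism intensity, ``A2``/``A6`` the
interspecific competition felt by each predator, ``A3``/``A7`` the predator
death rates, ``A4``/``A5`` the predators' growth from direct predation, and
``A8`` the kleptoparasite's growth from stolen food.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from itertools import permutations
from pathlib import Path

import numpy as np
import yaml

PARAM_KEYS = ("A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8")
DIMENSIONAL_KEYS = ("r1", "r2", "r3", "r4", "r5", "r6_prime",
                    "a", "k", "k1", "k2", "d2", "d3")


class ParameterError(ValueError):
    """Raised when a parameter set violates its positivity invariants."""


@dataclass(frozen=True)
class DimensionalParams:
    """Parameters of the dimensional model (original ecological units).

    ``r1``: prey intrinsic growth rate (1/time); ``r2``, ``r3``: predation
    rates of host and kleptoparasite (1/(density*time)); ``r4``, ``r5``:
    conversion efficiencies; ``r6_prime``: proportionality constant of the
    kleptoparasitic conversion rate r7(p2) = r6_prime*(1 + a*p2); ``a``:
    kleptoparasitism intensity (1/density); ``k``: prey carrying capacity;
    ``k1``, ``k2``: interspecific competition rates; ``d2``, ``d3``:
    predator death rates (1/time).
    """

    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6_prime: float
    a: float
    k: float
    k1: float
    k2: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        for key in DIMENSIONAL_KEYS:
            if not np.isfinite(getattr(self, key)) or getattr(self, key) <= 0:
                raise ParameterError(f"{key} must be strictly positive")

    @property
    def r6(self) -> float:
        """Effective kleptoparasitic conversion coefficient r6 = r6'*a*r2."""
        return self.r6_prime * self.a * self.r2


@dataclass(frozen=True)
class Params:
    """The eight nondimensional coefficients driving the scaled model."""

    A1: float
    A2: float
    A3: float
    A4: float
    A5: float
    A6: float
    A7: float
    A8: float

    def __post_init__(self) -> None:
        for key in PARAM_KEYS:
            if not np.isfinite(getattr(self, key)) or getattr(self, key) < 0:
                raise ParameterError(f"{key} must be non-negative and finite")
        # A8 = 0 (no kleptoparasitic gain) is an admissible limiting scenario;
        # every other coefficient must be strictly positive.
        for key in PARAM_KEYS[:-1]:
            if getattr(self, key) == 0:
                raise ParameterError(f"{key} must be strictly positive")

    @property
    def A9(self) -> float:
        """Host weight in the boundedness function D = S + P1/A9 + P2/A5."""
        return self.A4 / self.A1

    @property
    def A10(self) -> float:
        """Net competition-minus-theft coefficient A6 - A8 (may be negative)."""
        return self.A6 - self.A8

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_KEYS}

    def replace(self, **overrides) -> "Params":
        return replace(self, **overrides)

    @classmethod
    def from_mapping(cls, mapping) -> "Params":
        missing = [k for k in PARAM_KEYS if k not in mapping]
        if missing:
            raise ParameterError(f"missing parameter keys: {missing}")
        return cls(**{k: float(mapping[k]) for k in PARAM_KEYS})


def load_params(path) -> Params | DimensionalParams:
    """Load a parameter set from a YAML or JSON key-value file.

    The file may contain either nondimensional keys ``A1..A8`` or dimensional
    keys ``r1..r6_prime, a, k, k1, k2, d2, d3``.  Positivity is validated.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a flat key-value mapping")
    if all(k in data for k in PARAM_KEYS):
        return Params.from_mapping(data)
    if all(k in data for k in DIMENSIONAL_KEYS):
        return DimensionalParams(**{k: float(data[k]) for k in DIMENSIONAL_KEYS})
    raise ParameterError(
        f"{path}: keys must be A1..A8 or {', '.join(DIMENSIONAL_KEYS)}")


def save_params(p, path) -> None:
    data = p.as_dict() if isinstance(p, Params) else asdict(p)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def nondimensionalize(dp: DimensionalParams) -> Params:
    """Map dimensional parameters to the eight scaled coefficients.

    Uses the rescaling s = S*k, p1 = P1*r1/r2, p2 = P2*r1/r3, T = r1*t, under
    which the dimensional system maps exactly onto the scaled one (the
    equivalence is re-derived symbolically in the test-suite).
    """
    return Params(
        A1=dp.r3 / (dp.a * dp.r1),
        A2=dp.k1 / dp.r3,
        A3=dp.d2 / dp.r1,
        A4=dp.r2 * dp.r4 * dp.k * dp.r3 / (dp.a * dp.r1 ** 2),
        A5=dp.r5 * dp.k * dp.r3 / dp.r1,
        A6=dp.k2 / dp.r2,
        A7=dp.d3 / dp.r1,
        A8=dp.r6 * dp.k / dp.r2,
    )


def rhs(x, p: Params):
    """Time derivative of (S, P1, P2) for the scaled model.

    Total on the closed positive orthant: A1 > 0 keeps 1/(A1 + P2) regular.
    Each coordinate hyperplane is invariant (a component at zero stays zero).
    """
    S, P1, P2 = x
    return np.array([
        S * (1.0 - S) - S * P1 - S * P2,
        p.A4 * S * P1 / (p.A1 + P2) - p.A2 * P1 * P2 - p.A3 * P1,
        p.A5 * S * P2 - p.A6 * P1 * P2 - p.A7 * P2 + p.A8 * P1 * P2 * S,
    ])


def rhs_dimensional(x, dp: DimensionalParams):
    """Time derivative of (s, p1, p2) in original units."""
    s, p1, p2 = x
    return np.array([
        dp.r1 * s * (1.0 - s / dp.k) - s * p1 * dp.r2 - s * p2 * dp.r3,
        dp.r4 * dp.r2 * s * p1 / (1.0 + dp.a * p2) - dp.k1 * p1 * p2 - dp.d2 * p1,
        dp.r5 * s * p2 * dp.r3 - dp.k2 * p1 * p2 - dp.d3 * p2 + dp.r6 * p1 * p2 * s,
    ])


def jacobian(x, p: Params):
    """Closed-form 3x3 Jacobian of :func:`rhs` at state ``x``."""
    S, P1, P2 = x
    u = p.A1 + P2
    return np.array([
        [1.0 - 2.0 * S - P1 - P2, -S, -S],
        [p.A4 * P1 / u,
         p.A4 * S / u - p.A2 * P2 - p.A3,
         -p.A4 * S * P1 / u ** 2 - p.A2 * P1],
        [p.A5 * P2 + p.A8 * P1 * P2,
         -p.A6 * P2 + p.A8 * P2 * S,
         p.A5 * S - p.A6 * P1 - p.A7 + p.A8 * P1 * S],
    ])


def _sym_fill(T, i, idx, val):
    for pm in set(permutations(idx)):
        T[(i,) + pm] = val


def second_order_tensor(x, p: Params):
    """Symmetric second-derivative tensor H[i,j,k] = d2 F_i / dx_j dx_k."""
    S, P1, P2 = x
    u = p.A1 + P2
    H = np.zeros((3, 3, 3))
    H[0, 0, 0] = -2.0
    _sym_fill(H, 0, (0, 1), -1.0)
    _sym_fill(H, 0, (0, 2), -1.0)
    _sym_fill(H, 1, (0, 1), p.A4 / u)
    _sym_fill(H, 1, (0, 2), -p.A4 * P1 / u ** 2)
    _sym_fill(H, 1, (1, 2), -p.A4 * S / u ** 2 - p.A2)
    H[1, 2, 2] = 2.0 * p.A4 * S * P1 / u ** 3
    _sym_fill(H, 2, (0, 1), p.A8 * P2)
    _sym_fill(H, 2, (0, 2), p.A5 + p.A8 * P1)
    _sym_fill(H, 2, (1, 2), -p.A6 + p.A8 * S)
    return H


def third_order_tensor(x, p: Params):
    """Symmetric third-derivative tensor of the vector field.

    Only the host-growth term A4*S*P1/(A1+P2) and the trilinear theft term
    A8*S*P1*P2 contribute at third order.
    """
    S, P1, P2 = x
    u = p.A1 + P2
    T = np.zeros((3, 3, 3, 3))
    _sym_fill(T, 1, (0, 1, 2), -p.A4 / u ** 2)
    _sym_fill(T, 1, (0, 2, 2), 2.0 * p.A4 * P1 / u ** 3)
    _sym_fill(T, 1, (1, 2, 2), 2.0 * p.A4 * S / u ** 3)
    T[1, 2, 2, 2] = -6.0 * p.A4 * S * P1 / u ** 4
    _sym_fill(T, 2, (0, 1, 2), p.A8)
    return T


def bilinear(H, a, b):
    """B(a, b) for a second-derivative tensor H."""
    return np.einsum("ijk,j,k->i", H, a, b)


def trilinear(T, a, b, c):
    """C(a, b, c) for a third-derivative tensor T."""
    return np.einsum("ijkl,j,k,l->i", T, a, b, c)


@dataclass(frozen=True)
class BoundednessConfig:
    """Configuration of the dissipativity bound on D = S + P1/A9 + P2/A5.

    ``phi`` is the exponential decay rate used in the differential inequality
    dD/dt + phi*D <= eta; it must satisfy 0 < phi < min(A3, A7).  ``eta`` is
    derived, eta = (1 + phi)^2 / 4, and ``margin`` is the slack theta > 0
    added to the asymptotic bound eta/phi.
    """

    phi: float
    margin: float = 1e-6
    eta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ParameterError("phi must be positive")
        if self.margin <= 0:
            raise ParameterError("margin must be positive")
        object.__setattr__(self, "eta", (1.0 + self.phi) ** 2 / 4.0)

    def validate(self, p: Params) -> None:
        if self.phi >= min(p.A3, p.A7):
            raise ParameterError("phi must satisfy phi < min(A3, A7)")

    @property
    def bound(self) -> float:
        return self.eta / self.phi + self.margin
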