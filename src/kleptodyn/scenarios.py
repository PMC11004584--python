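"""Study scenarios: the baseline parameter set, named parameter regimes, and
seeded random parameter/initial-condition ensembles.

The baseline set (A1=0.02, A2=0.05, A3=2, A4=0.4, A5=4.536, A6=0.052,
A7=4.546, A8=114.98) places the system in a stably coexisting regime; every
named scenario overrides a few coefficients to move it into a qualitatively
different one (predator-free, host-free, kleptoparasite-free, oscillatory,
bistable, ...).  Expected-outcome tags are qualitative only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .model import Params

BASELINE = dict(A1=0.02, A2=0.05, A3=2.0, A4=0.4, A5=4.536,
                A6=0.052, A7=4.546, A8=114.98)


@dataclass(frozen=True)
class Scenario:
    name: str
    params: Params
    overrides: dict
    initial_conditions: tuple = ((0.5, 0.5, 0.5),)
    expected: str = ""


def baseline() -> Params:
    """The baseline nondimensional parameter set (stable coexistence)."""
    return Params(**BASELINE)


_REGISTRY: dict[str, tuple[dict, tuple, str]] = {
    "interior-stable": ({}, ((0.8, 0.01, 0.15), (0.7, 0.05, 0.2)),
                        "interior-stable"),
    "E1-stable": (dict(A3=0.875, A4=0.0125, A5=4.536),
                  ((0.5, 0.5, 0.5), (0.2, 0.8, 0.3), (0.9, 0.1, 0.6)),
                  "E1-stable"),
    "E2-stable": (dict(A3=0.51558, A4=0.010528, A5=1.135458),
                  ((0.5, 0.5, 0.5),), "E2-stable"),
    "E3-stable": (dict(A3=2.723732, A4=0.516658, A5=9.3241),
                  ((0.5, 0.5, 0.5),), "E3-stable"),
    "subcritical-regime": (dict(A4=1.2), ((0.62, 0.024, 0.35),),
                           "interior-stable inside unstable limit cycle"),
    "pre-supercritical": (dict(A4=11.0), ((0.06, 0.65, 0.30),),
                          "stable-limit-cycle"),
    "second-predator-extinct": (dict(A4=3.0), ((0.5, 0.5, 0.5),),
                                "E2-stable"),
    "first-predator-extinct": (dict(A5=5.5), ((0.8, 0.01, 0.2),),
                               "E3-stable"),
    "bistable-A8": (dict(A8=30.0), ((0.1, 0.9, 0.01), (0.82, 0.033, 0.144)),
                    "bistable: E2 and interior"),
    "no-klepto": (dict(A8=0.0), ((0.5, 0.5, 0.5),),
                  "E2-stable / second predator declines"),
}


def scenario_names() -> list[str]:
    return sorted(_REGISTRY)


def named_scenario(name: str) -> Scenario:
    """A registered scenario by name; unknown names raise with the registry."""
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}")
    overrides, ics, tag = _REGISTRY[name]
    return Scenario(name, baseline().replace(**overrides), dict(overrides),
                    tuple(tuple(ic) for ic in ics), tag)


def sample(seed: int, param_ranges: dict | None = None,
           ic_box=((0.05, 1.0), (0.05, 1.0), (0.05, 1.0)),
           n: int = 10) -> list[tuple[Params, np.ndarray]]:
    """``n`` reproducible random (Params, initial state) draws.

    ``param_ranges`` maps coefficient names to (lo, hi) intervals (positive);
    unlisted coefficients stay at baseline.  The same seed always returns
    the same draws.
    """
    rng = np.random.default_rng(seed)
    param_ranges = param_ranges or {}
    for key, (lo, hi) in param_ranges.items():
        if lo <= 0 or hi <= lo:
            raise ValueError(f"range for {key} must satisfy 0 < lo < hi")
    out = []
    for _ in range(n):
        over = {k: float(rng.uniform(lo, hi))
                for k, (lo, hi) in param_ranges.items()}
        ic = np.array([rng.uniform(lo, hi) for lo, hi in ic_box])
        out.append((baseline().replace(**over), ic))
    return out


def registry_to_yaml() -> str:
    """The scenario registry as YAML (round-trips losslessly)."""
    data = {}
    for name in scenario_names():
        sc = named_scenario(name)
        data[name] = {"overrides": sc.overrides,
                      "initial_conditions": [list(ic) for ic in
                                             sc.initial_conditions],
                      "expected": sc.expected}
    return yaml.safe_dump(data, sort_keys=True)


def registry_from_yaml(text: str) -> dict:
    return yaml.safe_load(text)
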