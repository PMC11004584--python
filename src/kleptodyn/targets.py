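"""Recompute the headline quantities of the baseline study from scratch.

Each function runs the actual pipeline (equilibrium solve, continuation,
normal form); nothing is looked up.  :func:`compute_targets` collects the
twelve scalar targets; :func:`compute_bautin_points` runs the two-parameter
analyses.  Results are deterministic; ``seed`` only feeds auxiliary random
draws where a function accepts one.
"""

from __future__ import annotations

import numpy as np

from .model import jacobian
from .equilibria import interior_equilibria
from .stability import characteristic_coefficients, klepto_only_A4_threshold
from .bifurcation import (continue_branch, detect_fold, detect_hopf,
                          detect_transcritical, hopf_curve_and_bautin)
from .scenarios import baseline, named_scenario


def baseline_characteristic() -> dict:
    """c1, c2, c3 and the Routh-Hurwitz quantity at the baseline interior
    equilibrium."""
    p = baseline()
    eq = [e for e in interior_equilibria(p) if e.exists][0]
    c1, c2, c3 = characteristic_coefficients(jacobian(eq.state, p))
    return {"c1": c1, "c2": c2, "c3": c3, "V": c1 * c2 - c3,
            "equilibrium": eq}


def hopf_points_A4() -> list:
    """Both Hopf points of the baseline interior family in A4."""
    p = baseline()
    branch = continue_branch(p, "A4", (0.05, 12.3), n_steps=400)
    return detect_hopf(branch)


def hopf_point_A5() -> list:
    p = baseline()
    branch = continue_branch(p, "A5", (1.5, 4.6), n_steps=300)
    return detect_hopf(branch)


def transcritical_A5() -> list:
    """Interior/E3 stability exchange in A5."""
    p = baseline()
    branch = continue_branch(p, "A5", (4.6, 6.0), n_steps=100, family="E3")
    return detect_transcritical([branch])


def fold_A3() -> list:
    p = baseline()
    branch = continue_branch(p, "A3", (0.01, 0.5), n_steps=200)
    return detect_fold(branch)


def fold_A8() -> list:
    p = baseline()
    branch = continue_branch(p, "A8", (1.0, 40.0), n_steps=200)
    return detect_fold(branch)


def fold_A4() -> list:
    p = baseline()
    branch = continue_branch(p, "A4", (11.0, 13.0), n_steps=100)
    return detect_fold(branch)


def compute_bautin_points() -> dict:
    """Bautin points on the (A5, A1) and (A5, A4) Hopf loci."""
    p = baseline()
    out = {}
    out[("A5", "A1")] = hopf_curve_and_bautin(
        p, ("A5", "A1"), ((0.9, 1.7), (0.01, 0.4)), n_grid=40)
    out[("A5", "A4")] = hopf_curve_and_bautin(
        p, ("A5", "A4"), ((1.0, 4.2), (0.05, 2.5)), n_grid=40)
    return out


def compute_targets(seed: int = 0) -> dict:
    """All twelve scalar targets, each recomputed by running the pipeline."""
    del seed  # the pipeline is fully deterministic
    out = {}
    base = baseline_characteristic()
    out["t1"] = {"value": base["c1"], "n": 1}
    out["t2"] = {"value": base["V"], "n": 1}
    out["t3"] = {"value": klepto_only_A4_threshold(named_scenario("E3-stable").params),
                 "n": 1}
    hopfs = sorted(hopf_points_A4(), key=lambda h: h.param_value)
    out["t4"] = {"value": hopfs[0].param_value, "n": 400}
    out["t5"] = {"value": hopfs[0].normal_form.l1, "n": 400}
    out["t6"] = {"value": hopfs[-1].param_value, "n": 400}
    out["t7"] = {"value": hopfs[-1].normal_form.l1, "n": 400}
    h5 = hopf_point_A5()
    out["t8"] = {"value": h5[0].param_value, "n": 300}
    out["t9"] = {"value": h5[0].normal_form.l1, "n": 300}
    tc = transcritical_A5()
    out["t10"] = {"value": tc[0].param_value, "n": 100}
    f3 = fold_A3()
    out["t11"] = {"value": f3[0].param_value, "n": 200}
    f8 = fold_A8()
    out["t12"] = {"value": f8[0].param_value, "n": 200}
    return {k: {"value": float(v["value"]), "n": int(v["n"])}
            for k, v in out.items()}
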