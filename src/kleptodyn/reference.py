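"""Published reference values for the baseline study, used by the ``verify``
command and the regression tests as comparison targets.

Every quantity here is recomputed from scratch by :mod:`kleptodyn.targets`;
this table only records the values reported in the source study for the
same parameter sets, together with the comparison tolerance class.
"""

REFERENCE = {
    # characteristic coefficients at the baseline coexistence equilibrium
    "t1": {"value": 0.844371, "rtol": 5e-5,
           "description": "c1 (=G11) at the baseline interior equilibrium"},
    "t2": {"value": 0.428135, "rtol": 5e-5,
           "description": "c1*c2 - c3 at the baseline interior equilibrium"},
    "t3": {"value": 2.88978, "rtol": 5e-5,
           "description": "host-invasion threshold on A4 for E3 stability"},
    # codimension-1 points (4 significant digits)
    "t4": {"value": 1.2252, "rtol": 1e-3,
           "description": "lower Hopf point in A4"},
    "t5": {"value": 0.0971749, "rtol": 1e-2,
           "description": "l1 at the lower A4 Hopf point (subcritical)"},
    "t6": {"value": 12.071019, "rtol": 1e-3,
           "description": "upper Hopf point in A4"},
    "t7": {"value": -2.30622, "rtol": 1e-2,
           "description": "l1 at the upper A4 Hopf point (supercritical)"},
    "t8": {"value": 2.007197, "rtol": 1e-3,
           "description": "Hopf point in A5"},
    "t9": {"value": -0.190703, "rtol": 1e-2,
           "description": "l1 at the A5 Hopf point (supercritical)"},
    "t10": {"value": 5.3449, "rtol": 1e-3,
            "description": "interior/E3 transcritical in A5"},
    "t11": {"value": 0.04267, "rtol": 1e-3,
            "description": "fold in A3 (minimum host death rate for coexistence)"},
    "t12": {"value": 10.2, "rtol": 1e-3,
            "description": "fold in A8 (birth of coexistence equilibria)"},
}

#: Bautin (generalized Hopf) points: locations to 3 significant digits,
#: second Lyapunov coefficient compared by sign only.
BAUTIN_REFERENCE = {
    ("A5", "A1"): [((1.0216, 0.1367), -1), ((1.4996, 0.1045), +1)],
    ("A5", "A4"): [((1.1230, 0.2896), -1), ((3.8733, 0.9586), +1)],
}
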