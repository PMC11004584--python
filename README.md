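# kleptodyn

Equilibrium, stability and bifurcation analysis of a three-species food-web
model in which one predator steals the other's kills.

## The model

Two predators share one prey. The *host* predator hunts the prey with a
Holling type-I (linear) functional response; the *kleptoparasite* both hunts
the prey and robs the host of a fraction of its kills. Because the host may
retaliate after being robbed, the conversion rate of stolen food grows with
the kleptoparasite's group size (larger groups defend stolen food better).
After rescaling prey density by the carrying capacity, predator densities by
growth/predation ratios, and time by the prey's intrinsic growth rate, the
dynamics of the scaled densities S (prey), P1 (host), P2 (kleptoparasite)
are

    dS/dt  = S(1 − S) − S·P1 − S·P2
    dP1/dt = A4·S·P1/(A1 + P2) − A2·P1·P2 − A3·P1
    dP2/dt = A5·S·P2 − A6·P1·P2 − A7·P2 + A8·P1·P2·S

with eight positive coefficients: A1 (inverse kleptoparasitism intensity),
A2/A6 (interspecific competition), A3/A7 (predator death rates), A4/A5
(growth from direct predation) and A8 (kleptoparasitic gain). The package
provides:

* **model** — dimensional and scaled vector fields, the nondimensionalization
  map, closed-form Jacobian and higher derivative tensors;
* **equilibria** — the boundary states E0–E4 in closed form and all interior
  (coexistence) states by a nullcline reduction, cross-checked against the
  degree-4 elimination polynomial;
* **stability** — Routh–Hurwitz classification (stable iff c1>0, c3>0,
  c1·c2−c3>0 for the characteristic cubic), per-equilibrium parametric
  stability conditions, and Lyapunov-function certificates for global
  stability;
* **dynamics** — stiff-capable simulation in log coordinates (positivity by
  construction), attractor classification (equilibrium / limit cycle),
  basin probing and dissipativity monitoring;
* **bifurcation** — one-parameter continuation with fold, transcritical
  (Sotomayor test quantities) and Hopf detection (Liu's criterion
  c1·c2−c3 = 0 with c1,c2,c3 > 0), first/second Lyapunov coefficients via
  the projection method and an independent center-manifold normal-form
  reduction, and two-parameter Hopf-curve tracing with Bautin
  (generalized-Hopf) point location;
* **scenarios** — the baseline parameter set, every named study regime, and
  seeded random ensembles.

## Worked example

At the baseline coefficients (A1=0.02, A2=0.05, A3=2, A4=0.4, A5=4.536,
A6=0.052, A7=4.546, A8=114.98) the system has a unique coexistence state:

```
$ kleptodyn equilibria --scenario interior-stable
label                   S           P1           P2  exists    verdict
E0                      0            0            0    True   unstable
E1                      1            0            0    True   unstable
E2                    0.1          0.9            0    True   unstable
E3             1.00220459            0 -0.00220458554   False        n/a
E4                      0  -87.4230769          -40   False        n/a
interior-1    0.844371172 0.00737817527  0.148250653    True     stable
```

Prey settle at 84.4% of carrying capacity; the host persists at low density
(0.0074) because theft diverts most of its intake to the kleptoparasite
(0.148). Raising the host's growth rate A4 destabilizes this state through
a *subcritical* Hopf bifurcation:

```
$ kleptodyn hopf --param A4 --range 1.0,1.5
Hopf at A4 = 1.22519347 (subcritical)
  equilibrium: 0.619471144, 0.0243917662, 0.35613709
  omega = 2.23972969  l1 = 0.0971989576
  g20 = 5.13970046-2.74765946j  g11 = -0.6935528+3.96869732j  g21 = 0.435398783+7.71901539j
  dRe(lambda)/dA4 = 0.0845388102
```

The positive first Lyapunov coefficient (l1 = 0.0972) means an *unstable*
cycle bounds the basin of the coexistence state: just below A4 = 1.2252,
populations inside the cycle spiral into equilibrium while populations
outside it never reach it. A second, supercritical Hopf point at
A4 = 12.0710 (l1 = −2.306) hands the dynamics over to a stable
three-species oscillation, which persists until coexistence is destroyed at
a fold at A4 = 12.248.

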