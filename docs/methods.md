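# Methods

## Model and assumptions

The package analyses a two-predator–one-prey system with kleptoparasitism.
The prey grows logistically; both predators take it with Holling type-I
(linear) responses, so handling time is assumed negligible. The second
predator (kleptoparasite) steals a fraction 1 − ψ of the first predator's
(host's) kills, with ψ(p2) = 1/(1 + a·p2) and `a` the kleptoparasitism
intensity: theft is negligible when `a` → 0 and total when `a` → ∞. The
host's counter-attack after theft is modelled through the conversion rate
of stolen food, r7(p2) = r6′(1 + a·p2), which rises with kleptoparasite
group size (larger groups defend stolen food better, so less of it is lost
to reprisals). The predators also compete interspecifically and die at
constant per-capita rates. There is no spatial structure, stochasticity,
delay, or saturating functional response.

Rescaling s = S·k, p1 = P1·r1/r2, p2 = P2·r1/r3, T = r1·t reduces the 13
dimensional parameters to eight coefficients A1..A8. The typeset source
from which the coefficient definitions were transcribed is ambiguous about
fraction bars; the implemented parse (A1 = r3/(a·r1), A4 = r2·r4·k·r3/(a·r1²),
A5 = r5·k·r3/r1, A8 = r6·k/r2 with r6 = r6′·a·r2, plus the unambiguous
A2 = k1/r3, A3 = d2/r1, A6 = k2/r2, A7 = d3/r1) is the unique one under
which the substitution maps the dimensional system exactly onto the scaled
one; a sympy verification of this equivalence ships in the test-suite.
Derived quantities: A9 = A4/A1 weights the host in the dissipativity
function D = S + P1/A9 + P2/A5, and A10 = A6 − A8 is the net
competition-minus-theft coefficient (negative at the baseline, where theft
conversion dominates competition).

## Parameters

The baseline set A1=0.02, A2=0.05, A3=2, A4=0.4, A5=4.536, A6=0.052,
A7=4.546, A8=114.98 (all dimensionless) describes an intense-theft regime:
A8 ≫ A6 means the kleptoparasite's gain from stolen food dwarfs its
competitive loss, and A1 ≪ 1 means theft pressure saturates the host's
intake quickly. Named scenarios override a few coefficients to reach each
qualitative regime (predator-free, host-free, kleptoparasite-free,
oscillatory, bistable); every override value is taken from the study being
reproduced, and each scenario's registered initial conditions were placed
inside numerically verified basins of attraction (see below).

## Equilibria

Boundary equilibria are closed-form. Interior equilibria are found by
reducing the nullcline system to a scalar problem: the host nullcline is a
quadratic in P2 whose positive branch is P2(S) (real for all S > 0 because
its discriminant is bounded below by (A1·A2 − A3)² + 4·A2·A4·S; positive
iff A4·S > A1·A3), the prey nullcline gives P1 = 1 − S − P2, and the
kleptoparasite nullcline leaves a smooth scalar function f(S) whose roots
in (0, 1) are bracketed on a uniform 4096-interval scan and polished by
Brent's method to |f| ≈ 1e−15. Admissibility is judged at the refined root
(every coordinate > 1e−9), which keeps roots whose admissible window is
narrower than a scan step; inadmissible roots are reported as grazing,
without an existence flag. An independent route through the degree-4
elimination polynomial (whose closed-form coefficients the test-suite
verifies against a sympy resultant, equal up to the common factor 4·A2)
back-substitutes and filters by residual; the two routes agree to 1e−8 on
thousand-draw random ensembles. At any interior equilibrium the trace
identity c1 = S* holds (the host and kleptoparasite diagonal Jacobian
entries vanish on their nullclines), which the baseline reproduction uses
as a cross-check.

## Stability

Local stability uses the characteristic cubic λ³ + c1λ² + c2λ + c3 with
c1 = −tr J, c2 = Σ principal 2×2 minors, c3 = −det J, and the
Routh–Hurwitz conditions c1 > 0, c3 > 0, c1·c2 − c3 > 0. Verdicts are
always cross-checked against eigenvalues; |Re λ| ≤ 1e−8 is reported as
marginal (needed next to bifurcation points). The per-equilibrium
parametric conditions include, for the kleptoparasite-free state, the
fourth inequality that appears only inside the source's proof; random-draw
testing confirms the four together are sufficient while the three headline
ones alone are occasionally not.

Global stability is treated through checkable certificates: the published
sufficient inequality systems for the predator-free state (two
inequalities in the weights L1..L3 and box bounds) and for the coexistence
state (five conditions with derived thresholds Υ2, Υ3, Υ4) are evaluated
with margins. A deterministic search walks a lattice of boxes and solves
the weight ratio L3/L2 in closed form from the two predator-free
inequalities — the satisfying set is a thin wedge that a naive weight grid
misses, and the inequalities are conservative enough that only thin boxes
(upper bounds ≈ 10% above lower) admit any certificate. A failed or absent
certificate never asserts instability.

## Simulation

The system factors as dx_i/dt = x_i·φ_i(x), so strictly positive
components are integrated in log coordinates (du_i/dt = φ_i(e^u)) with
LSODA at rtol 1e−9, atol 1e−12 — in log space these control *relative*
accuracy per population. This choice is load-bearing: trajectories of this
model routinely make near-extinction excursions twenty or more orders of
magnitude deep and then recover, and a raw-coordinate solver that steps
slightly negative can reach the vector-field pole at P2 = −A1 and stall.
In log coordinates positivity holds by construction. Components starting
at exactly zero lie on invariant hyperplanes and are pinned to zero.

Attractor classification discards the transient (first half), calls the
tail an equilibrium when the last 10% stays within 1e−6 of the final
state, and a limit cycle when the prey component of the last 25% shows ≥ 5
peaks with < 1% period drift *and* < 2% peak-to-peak amplitude drift
between the window's halves — the amplitude condition keeps slowly damped
spirals near a Hopf point from being mislabelled as cycles; everything
else is unresolved, with the amplitude trend reported. Basin probing
labels a set of initial conditions and flags bistability when two
attractors differ in label or by more than 1e−4 in equilibrium position.

A caveat this analysis surfaced: at the baseline coefficients the symmetric
initial condition (0.5, 0.5, 0.5) does **not** lie in the coexistence
state's basin. Three independent integrators agree (to four digits in log
space) that it enters ever-deepening boundary excursions instead; claims
to the contrary are artifacts of loose-tolerance integration, where
round-off ejects the trajectory from the excursions. The coexistence state
is locally stable — certified by Routh–Hurwitz, eigenvalues, and
convergence from its actual basin — but its basin excludes much of the
orthant in this intense-theft regime.

The dissipativity monitor evaluates D = S + P1/A9 + P2/A5 against the
asymptotic bound η/φ (η = (1+φ)²/4, 0 < φ < min(A3, A7)). The bound's
derivation needs A10 = A6 − A8 ≥ 0, which fails at the baseline; the
monitor therefore reports whether the derivation applies, and the
empirical check of the bound is run on weak-theft ensembles (A8 < A6)
where it is in force.

## Bifurcation analysis

Continuation is natural-parameter on a uniform grid (default 400 steps)
with continuity-based family tracking (nearest prey density), local step
halving when the family jumps, and per-sample recording of the
admissible-root count. Detectors refine events on smooth scalar test
functions, deterministically:

* **Fold**: a root-count transition is bisected, then polished on the exact
  double-root condition f(S) = f′(S) = 0 of the reduced problem (f′ is
  closed-form), driving |det J| to ~1e−12 at the reported point. A
  transition whose merging root has a vanishing coordinate is a boundary
  exit, not a fold, and is skipped.
* **Transcritical**: boundary families have closed-form transverse
  eigenvalues whose zeros are Brent-refined; stability exchange is
  confirmed from samples on either side. Sotomayor-type test quantities
  (Q·K_μ, Q·(DK_μ)P, ½·Q·D²F(P,P)) use null vectors scaled so the last
  pivot entry is +1 — the convention under which the predator-free
  exchange gives exactly (0, 1, −A5).
* **Hopf**: zeros of the Liu test function V = c1·c2 − c3 along an
  interior family with c1, c2, c3 > 0; ω = √c2, and the eigenvalue
  crossing rate is computed as dRe λ/dμ = −(dV/dμ)/(2(c2 + c1²)) with
  branch-total derivatives. The sign convention follows from perturbing
  the critical cubic: V ≈ −2·Re λ·(c2 + c1²) near criticality, so losing
  stability (Re λ increasing) requires V decreasing. The reported rate is
  validated against a finite-difference eigenvalue oracle in the tests.
* **Bautin**: the Hopf locus in a parameter pair is traced on a grid of
  the first parameter, solving the second from V = 0 with continuity
  selection; sign changes of l1 along the curve are bisected and l2 is
  evaluated at the located point (regularity requires l2 ≠ 0).

## Hopf normal form

The first Lyapunov coefficient uses the projection method with
⟨q,q⟩ = 1, ⟨p,q⟩ = 1:

l1 = Re⟨p, C(q,q,q̄) − 2B(q, A⁻¹B(q,q̄)) + B(q̄, (2iωI − A)⁻¹B(q,q))⟩ / (2ω),

with B and C assembled from closed-form second/third derivative tensors of
the vector field (only the host-growth term A4·S·P1/(A1+P2) and the
trilinear theft term contribute beyond the quadratic). This expression is
invariant under the free phase of q, which the tests exercise; the
individual g20, g11, g21 are phase-dependent and are reported for
diagnostics only. l1 > 0 marks a subcritical Hopf (unstable cycle),
l1 < 0 supercritical (stable cycle).

The second Lyapunov coefficient comes from an independent reduction: the
hyperbolic direction (the real eigenvalue, nonzero wherever c3 > 0) is
eliminated by solving the center-manifold invariance equation order by
order to degree 4, the restricted planar field is expanded to degree 5 —
the only non-polynomial term is expanded as an exact geometric series —
and a numeric Poincaré normal-form transformation removes non-resonant
terms, leaving ż = iωz + c1·z|z|² + c2·z|z|⁴ with l_k = Re(c_k)/ω. The
machinery is validated by its agreement with the projection-method l1 (and,
for the pure planar case, with the classical textbook formula, also
tested). The overall positive scale of l2 depends on eigenvector
normalization, so across implementations only its sign is comparable; at a
Bautin point (l1 = 0) the sign of l2 is well-defined and is what the
package reports as decisive.

## Problem sizes and tolerances

Default sizes — 4096 scan intervals for interior roots, 400 continuation
steps, 40–80 grid points per two-parameter Hopf curve, bisection to 1e−10
in the parameter — resolve every reproduced bifurcation value to at least
four significant digits while keeping a full reproduction run (all twelve
scalar targets plus both Bautin curves) under ten seconds on one core.
Random-ensemble tests use seeded generators throughout; seeds are recorded
in outputs where sampling is exposed.

## Known limitations

* Limit cycles are studied by simulation only; there is no cycle
  continuation, and period-doubling/torus/homoclinic phenomena are out of
  scope.
* The two-parameter Hopf tracer assumes the locus is a graph over the
  abscissa parameter within the supplied ranges (true for the curves
  analysed here); a fold of the Hopf curve itself would need arclength
  continuation.
* Global-stability certificates are sufficient conditions evaluated over
  user-supplied boxes; they are far from sharp, and the boxes that satisfy
  them are thin.
* The synthetic ensembles draw coefficients independently and uniformly
  within ecologically plausible ranges; real parameter sets are correlated
  (e.g. conversion efficiencies bounded by predation rates), so ensemble
  pass rates speak to numerical robustness, not to ecological prevalence
  of any regime.
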