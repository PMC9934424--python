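# Methods

## Model and reduction chain

The package treats the continuum PB equation

    R_tt − (a1 + 3 a2 R_x²) R_xx − 2 η ζ e^{−ηR}(e^{−ηR} − 1) = 0

as the single source of truth.  The traveling reduction (ξ = x − ωt), the
first integral, and the exponential substitution s = e^{−ηr} are *derived*
inside `pbdna.model`, not transcribed: the first-integral coefficients are
fixed by undetermined-coefficient matching against the identity
dF/dξ ≡ r′ · (reduced ODE), which the constructor checks symbolically and
the test suite re-checks.  This makes the chain self-certifying — any
transcription ambiguity in secondary sources is irrelevant, because a wrong
coefficient cannot pass the identity.

Parameter conventions: η ≠ 0 is required (it scales the Morse exponent);
a1 ≠ 0 is required only by the MI operations, which divide by it.  Physical
positivity of (a1, a2, η, ζ) is recorded but not enforced: several solution
branches only exist on specific sign sets (see below) and the evaluators
check those per family.  The first-integral constant C defaults to 0 in
user-facing parameter sets, but every solved branch *implies* a specific C
and records it (`SolutionBranch.C_implied`); the solitary benchmark branch,
for instance, has C ≈ 0.068 rather than 0.

## The unified-method engine

For each family the ansatz (polynomial s = A0 + A1λ + A2λ², or rational
s = (A0 + A1λ)/(C0 + C1λ)) and an auxiliary ODE (λ′)^q = Σ B_k λ^k are
substituted into the transformed ODE.  Only even powers of s′ occur, so
(λ′)² can be replaced by a polynomial in λ without clearing radicals.
Collecting λ powers yields 9–14 polynomial equations for 5–6 unknowns
(the A's, constrained B's or C0, ω² and C).

The solver:

1. gauge-fixes the rational ansatz (C1 = 1; the solution is rescaled by C1
   afterwards — s is invariant under common rescaling of numerator and
   denominator, and leaving the gauge free makes the solution set
   non-isolated);
2. case-splits the rational families on A1 = 0 versus A1 ≠ 0;
3. saturates the nondegeneracy condition (A2 ≠ 0, or A0C1 − A1C0 ≠ 0) with
   a Rabinowitsch variable z (z · cond = 1), which removes the degenerate
   positive-dimensional components that otherwise stall elimination;
4. computes a grevlex Gröbner basis of the saturated system and back-solves
   it in lex order (`solve_poly_system`).

The A1 ≠ 0 case of both rational families reduces to the basis {1} — an
inconsistency certificate, i.e. a *proof* that no such branch exists, not a
failed search.  Every returned branch is verified by numeric
back-substitution at a canonical parameter point (relative residual below
1e−9 against the sum of term magnitudes) and, in the test suite,
symbolically.  Branches are ordered deterministically; the ∓ pair of the
coefficient radical is labeled by the sign of the leading coefficient at a
canonical positive parameter point, and a second selector (`root+`/`root-`,
`quartic`/`reduced`) distinguishes double roots of the constrained
denominator coefficient and the B0 = 0 sub-branch of the quartic family.

Derived branch structure (engine output, confirmed by back-substitution):

* solitary: A_k = ∓2√3 B_k B2 √(a2/ζ)/η², ω² = a1 + (3B1² − 12B0B2)a2/η²
  ∓ 2√(3 a2 ζ);
* soliton: A0 = 0, A1 = ∓√3 B1 √(a2/ζ)/η², A2 = 2A1B2/B1,
  B0 = B1²/(4B2);
* elliptic: A1 = 0, B0 = B2²/(4B4) — this constraint forces the Jacobi
  modulus to 1, so the sn solution degenerates to tanh (the general
  quartic auxiliary with unconstrained coefficients does return a genuine
  sn form);
* periodic-rational: A1 = 0, C0 = ±C1 B0/B2;
* soliton-rational: A1 = 0, C0 = C1(B1 ± √(B1² − 4B0B2))/(2B2) — the
  denominator root coincides with a root of the auxiliary polynomial, which
  is exactly the pole-order balance condition for the rational ansatz.

All branch coefficients carry the radical √(a2/ζ): real branches need
a2 ζ > 0.  Evaluators raise a structured `RealityError` naming the violated
inequality (a2/ζ > 0; B2 > 0 for the exponential soliton case; B2 < 0 < B4
for the quartic elliptic branch; ω² > 0 for a real wave speed — a1 only
shifts ω², so raising a1 is the generic cure).

## Auxiliary-equation library

`integrate_auxiliary` performs case analysis and *verifies every returned
λ(ξ) symbolically* against its ODE at construction time (for Jacobi sn
after rewriting even powers of cn/dn through sn):

* q = 1 quadratic (Riccati): tan (Δ < 0), tanh (Δ > 0), rational pole
  (Δ = 0), exponential and linear degenerations;
* q = 2, λ² · (perfect-square quadratic): exponential forms E1/E2 (the two
  orientations), plus the complementary integration branch E1b/E2b with the
  opposite sign of the integration multiplier.  The E1/E2 forms live
  *outside* the two Riccati fixed points (they have a pole); the E1b/E2b
  forms are the bounded orbits *between* the fixed points.  Only the
  bounded forms give the sign-negative soliton branch a nonempty real
  validity domain, which is why both are provided;
* q = 2, λ² · (non-square quadratic): solved through μ = 1/λ (sech-type);
* q = 2 even quartic: A·sn(B(ξ+c1), m) with A, B, m derived from the
  coefficient ratios (modulus-1 inputs return tanh directly);
* q = 2 quadratic: cosh / sinh / sine / exp / parabolic / linear cases by
  the signs of the leading coefficient and discriminant.

csgn-style ambiguities do not arise: all case selections are made on real
numeric coefficients, and symbolic-coefficient requests return the formal
form(s) whose verification is sign-independent.

## Closed-form evaluation

R = −(1/η) ln s is real exactly where s > 0; evaluation masks s ≤ 0 and
non-finite points instead of emitting complex values.  Two numerical
safeguards matter:

* hyperbolic closed forms are rewritten to rational-in-exponential form
  before lambdification — `1 − tanh²` cancels catastrophically on the wings
  (it rounds to 0 beyond |ξ| ≈ 38) while `4e^u/(e^u+1)²` evaluates by pure
  products down to underflow;
* the master residual check (`families.max_residual`) evaluates the PDE
  with analytic derivatives in extended precision (complex longdouble) and
  measures the residual *relative to the magnitudes of the three PDE
  terms*, restricted to the well-conditioned part of the validity domain
  (1e−8 < |s| < 1e8).  Next to a log singularity the individual terms grow
  without bound and no finite-precision residual is meaningful; inside the
  cap the worst relative residual over all ten (family, sign) branches is
  ~5e−8, comfortably below the 1e−6 contract.

Each (family, sign) pair ships a verification parameter set under which
that branch has a nonempty validity domain and a real speed
(`families.verification_sets`).  Two of them deserve a note: the
sign-negative soliton branch uses the bounded E1b auxiliary form (see
above), and the sign-positive elliptic branch uses the reduced (B0 = 0)
sub-branch, because the quartic branch's s is a negative multiple of sech²
for every real parameter choice on that sign.

## Profile classification

One time slice, ≥ 100 points.  Background = median of the outer decile of
valid points (robust to a localized core).  Labels: `singular` if the
validity mask has interior holes; `periodic` if the dominant orientation
shows ≥ 2 regularly spaced peaks within 20% of each other in height
(gap coefficient of variation ≤ 10%); otherwise `bright`/`dark` by the sign
of the dominant deviation; `invalid` for all-masked or flat slices.

## Figure fixtures

The three figure parameter sets are shipped with every ambiguous token
resolved into named variants and the raw caption strings attached:

* the caption token "ξ = −0.001" is exposed as ζ (ξ is the co-moving
  coordinate and cannot be a constant).  With the printed sign every
  coefficient is imaginary (a2 ζ < 0), so the default variants use
  ζ = +0.001 and the raw-sign variant is retained, raising `RealityError`
  on evaluation;
* the η tokens ("769", "599") ship as variants etaA/etaB/etaC
  (7/69, 7.69, 769 and 5/99, 5.99, 599), default etaB;
* the fig4 caption's C0 = 0.6 and C2 = 0.5 name coefficients the rational
  ansatz does not take as inputs (C0 is branch-determined; C2 does not
  exist); they are read as the otherwise missing auxiliary coefficients
  B0 = 0.6, B2 = 0.5, recorded as an interpretation;
* the printed fig4 branch signs (A0 negative with the + denominator root)
  give s < 0 everywhere, i.e. a complex R — consistent with the source
  plotting |R|.  The default fixture is the real-valued variant (positive
  sign, − root, whose denominator touches zero at the core and produces the
  modulus spike).

Classification of the fixtures follows what the figures display: fig2/fig3
are classified on R over the full window (a localized dip → dark); fig4 is
classified on |R(x, t)| over a window about the core, where the spike is a
localized elevation → bright.  On the full window the real part of fig4 is
a dip; both readings are computed by the tests, only the figure-faithful
one is asserted.

## Modulation instability

Implemented exactly as the analysis prints it: κ(Ω) = ±√((−Ω² −
2(1+Z0)ζη²)/a1), stable ⇔ κ real, marginal on the boundary (radicand within
1e−12 of 0), gain h = 2|Im κ|.  The printed linearized equation
Γ_tt + a1 Γ_xx + 2η²ζ(Z0 + Γ) = 0 is *not* consistent with that dispersion
relation: plane-wave substitution into it gives a1κ² = 2ζη² − Ω²
(Z0-independent), and Γ ≡ 0 leaves the constant forcing 2η²ζZ0, so the
steady state is not an exact solution.  `linearized_residual` and
`consistent_kappa_sq` expose both facts; the module documents the
inconsistency rather than repairing it, and the prose claim that larger Z0
lowers the growth rate is not asserted (the closed form is increasing in Z0
for ζ > 0, which the tests do check as a property of the formula).

## Simulator

Method of lines: classical RK4 over 2nd-order centered periodic
differences, first-order system (R, V = R_t).  The quasilinear term is
discretized pointwise as (a1 + 3a2 (D1R)²) D2R rather than in flux form
(the difference is O(dx²); the pointwise form matches the analytic
residual operator used everywhere else).  CFL: dt ≤ 0.4 dx / c_max with
c_max = √(a1 + 3a2 max R_x²) recomputed each step; requested steps above
the bound are shrunk and logged; NaN halts the run with a report.  Energy
is the discrete Hamiltonian ½V² + ½a1Rx² + ¼a2Rx⁴ + ζ(e^{−ηR}−1)² with the
same centered gradient, summed over the periodic grid.

The exact traveling profiles of this model do **not** decay at infinity:
s → 0 on the wings, so R grows *linearly* (slope 2κ/η) — the Morse force
vanishes there and any linear profile is locally exact.  A literal periodic
wrap of such a profile has a derivative jump, so the benchmark grafts the
closed form onto a constant background through a C∞ window (exactly 1 on
the core region, exactly 0 near the edges).  The graft regions are not
exact-solution data; they radiate.  Two consequences, both handled by
causality: (i) comparisons against the translated closed form are made in a
core window whose domain of dependence stays inside exact-solution data for
the simulated times; (ii) the energy contract applies to the full grafted
field, which is smooth and periodic, so conservation holds regardless.
Profiles with steep wings shock-steepen under the quasilinear term (the
radiation gradient grows until the centered scheme breaks down), so the
benchmark uses η = 5, a1 = 5, κ = 1/2: wing slope 0.2, core width ≈ 4,
ω ≈ 1.287, safely in the smooth regime for the runs below.

Problem sizes (the package's reference choices): domain [−60, 60), graft
window 1 on |x| ≤ 30 and 0 within 8 of the edges; energy-conservation run
n = 4096, T = 10 (relative drift 2.7e−7; the same run at n = 2048 gives
~1e−6, consistent with the O(dx²) defect of the non-conservative pointwise
discretization); convergence study n = 256/512/1024 to T = 2 in a ±10 core
window (observed orders 2.01, 2.00); speed recovery n = 1024, T = 5
(relative error ~4e−4 against the branch ω); time-reversal at dt =
CFL/16 over 50 steps (defect ~1e−13).  Core tracking uses the global
extremum of R carrying the larger |R_xx| (a dip and a bump alike),
quadratically interpolated and periodically unwrapped; speed is the
least-squares slope.

## Known limitations

* Continuum only — no site-indexed PB lattice Hamiltonian.
* The ansatz families are limited to p = 2 (n = 2) and n = m = 1; the
  balance routine computes general degrees, but p ≥ 3 systems are not
  enumerated.
* All derived real branches are unbounded (linear growth) or singular at
  isolated points; none decays to the R = 0 ground state, so the simulator
  can only exercise them through the grafting described above, and no
  numerical MI growth-rate measurement is attempted (the printed
  linearization does not linearize the PDE about an exact steady state, so
  there is no model-defined target to compare against).
* The master residual tolerance is certified on the conditioning-capped
  validity domain; immediately adjacent to log singularities no floating-
  point statement is made.
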