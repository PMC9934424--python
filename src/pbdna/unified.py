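"""The unified-method engine.

Given the transformed polynomial ODE in s(xi) (from :mod:`pbdna.model`), the
engine expands s in powers -- or ratios of powers -- of an auxiliary function
lambda(xi) obeying a low-order ODE (lambda')^q = sum_k B_k lambda^k, collects
powers of lambda into an algebraic system for the expansion coefficients, and
solves that system into closed branches.  Five ansatz families are built in:

========================  ====  =======================================
family                    q     auxiliary equation
========================  ====  =======================================
solitary                  1     lambda' = B0 + B1 l + B2 l^2
soliton                   2     lambda'^2 = l^2 (B0 + B1 l + B2 l^2)
elliptic                  2     lambda'^2 = B0 + B2 l^2 + B4 l^4
periodic_rational         2     lambda'^2 = B0^2 - B2^2 l^2
soliton_rational          2     lambda'^2 = B0 + B1 l + B2 l^2
========================  ====  =======================================

The first three expand s = A0 + A1 l + A2 l^2; the last two use the rational
form s = (A0 + A1 l)/(C0 + C1 l).

Solving strategy (recorded in docs/methods.md): the lambda-power system is
saturated against degeneracies with a Rabinowitsch variable, reduced with a
grevlex Groebner basis, and back-solved in lex order; the rational families
are gauge-fixed (C1 = 1) and case-split on A1 = 0 / A1 != 0 (the latter case
is discharged by an inconsistency certificate).  Every branch is verified by
back-substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import sympy as sp

from . import model
from .elliptic import reduce_squares, sn
from .params import SYM

__all__ = [
    "LAM",
    "FAMILIES",
    "AnsatzSpec",
    "AuxiliaryODE",
    "Ansatz",
    "AlgebraicSystem",
    "SolutionBranch",
    "AuxSolution",
    "ClosedForm",
    "balance_exponents",
    "build_ansatz",
    "derive_algebraic_system",
    "solve_branches",
    "solved_branches",
    "integrate_auxiliary",
    "assemble_R",
]

LAM = sp.Symbol("lam")
A0, A1, A2 = sp.symbols("A0 A1 A2")
B0, B1, B2, B4 = sp.symbols("B0 B1 B2 B4")
C0, C1 = sp.symbols("C0 C1")
CINT = sp.Symbol("Cint")
W = model.W_  # omega**2
_Z = sp.Symbol("z_sat")

FAMILIES = ("solitary", "soliton", "elliptic", "periodic_rational", "soliton_rational")


@dataclass(frozen=True)
class AnsatzSpec:
    """Expansion degrees: polynomial s of degree n, or rational with
    numerator degree n over denominator degree m; q is the auxiliary
    exponent, p the balance parameter of the auxiliary polynomial."""

    form: str  # 'polynomial' | 'rational'
    n: int
    m: int = 0
    q: int = 1
    p: int = 2

    def __post_init__(self):
        if self.form not in ("polynomial", "rational"):
            raise ValueError(f"unknown ansatz form {self.form!r}")
        if self.q not in (1, 2):
            raise ValueError("q must be 1 or 2")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.form == "rational" and not (self.n >= self.m >= 0):
            raise ValueError("rational form needs n >= m >= 0")


@dataclass(frozen=True)
class AuxiliaryODE:
    """(lambda')^q = rhs(lambda)."""

    q: int
    rhs: sp.Expr

    @property
    def coeffs(self) -> dict[int, sp.Expr]:
        p = sp.Poly(sp.expand(self.rhs), LAM)
        return {int(m[0]): c for m, c in zip(p.monoms(), p.coeffs()) if c != 0}

    @property
    def discriminant(self) -> Optional[sp.Expr]:
        """b1^2 - 4 b0 b2 for a quadratic right-hand side, else None."""
        c = self.coeffs
        if c and max(c) <= 2:
            b0, b1, b2 = c.get(0, 0), c.get(1, 0), c.get(2, 0)
            return sp.expand(b1**2 - 4 * b0 * b2)
        return None

    def residual(self, lam_expr, xi=SYM.xi) -> sp.Expr:
        """(d lambda/d xi)^q - rhs(lambda) for a candidate solution."""
        return sp.diff(lam_expr, xi) ** self.q - self.rhs.subs(LAM, lam_expr)


@dataclass(frozen=True)
class Ansatz:
    family: str
    spec: AnsatzSpec
    s_expr: sp.Expr  # in LAM and coefficient symbols
    aux: AuxiliaryODE
    unknowns: tuple  # coefficient symbols solved for (incl. W, CINT)
    free_coeffs: tuple  # symbols left free (B's, C1)
    nondegeneracy: sp.Expr  # must be nonzero on admissible branches
    split_var: Optional[sp.Symbol] = None  # case-split variable (rational)
    gauge: dict = field(default_factory=dict)  # e.g. {C1: 1}


def _family_defs() -> dict[str, Ansatz]:
    poly_s = A0 + A1 * LAM + A2 * LAM**2
    rat_s = (A0 + A1 * LAM) / (C0 + C1 * LAM)
    return {
        "solitary": Ansatz(
            family="solitary",
            spec=AnsatzSpec("polynomial", n=2, q=1, p=2),
            s_expr=poly_s,
            aux=AuxiliaryODE(1, B0 + B1 * LAM + B2 * LAM**2),
            unknowns=(CINT, W, A0, A1, A2),
            free_coeffs=(B0, B1, B2),
            nondegeneracy=A2,
        ),
        "soliton": Ansatz(
            family="soliton",
            spec=AnsatzSpec("polynomial", n=2, q=2, p=2),
            s_expr=poly_s,
            aux=AuxiliaryODE(2, LAM**2 * (B0 + B1 * LAM + B2 * LAM**2)),
            unknowns=(CINT, W, A0, A1, A2, B0),
            free_coeffs=(B1, B2),
            nondegeneracy=A2,
        ),
        "elliptic": Ansatz(
            family="elliptic",
            spec=AnsatzSpec("polynomial", n=2, q=2, p=2),
            s_expr=poly_s,
            aux=AuxiliaryODE(2, B0 + B2 * LAM**2 + B4 * LAM**4),
            unknowns=(CINT, W, A0, A1, A2, B0),
            free_coeffs=(B2, B4),
            nondegeneracy=A2,
        ),
        "periodic_rational": Ansatz(
            family="periodic_rational",
            spec=AnsatzSpec("rational", n=1, m=1, q=2),
            s_expr=rat_s,
            aux=AuxiliaryODE(2, B0**2 - B2**2 * LAM**2),
            unknowns=(CINT, W, A0, A1, C0),
            free_coeffs=(B0, B2, C1),
            nondegeneracy=(A0 * C1 - A1 * C0),
            split_var=A1,
            gauge={C1: sp.S.One},
        ),
        "soliton_rational": Ansatz(
            family="soliton_rational",
            spec=AnsatzSpec("rational", n=1, m=1, q=2),
            s_expr=rat_s,
            aux=AuxiliaryODE(2, B0 + B1 * LAM + B2 * LAM**2),
            unknowns=(CINT, W, A0, A1, C0),
            free_coeffs=(B0, B1, B2, C1),
            nondegeneracy=(A0 * C1 - A1 * C0),
            split_var=A1,
            gauge={C1: sp.S.One},
        ),
    }


_FAMILY_DEFS = None


def build_ansatz(family) -> Ansatz:
    """Return the ansatz template for a family tag or a matching AnsatzSpec."""
    global _FAMILY_DEFS
    if _FAMILY_DEFS is None:
        _FAMILY_DEFS = _family_defs()
    if isinstance(family, AnsatzSpec):
        matches = [a for a in _FAMILY_DEFS.values() if a.spec == family]
        if not matches:
            raise ValueError(f"no built-in family matches spec {family}")
        return matches[0]
    if family not in _FAMILY_DEFS:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    return _FAMILY_DEFS[family]


# --------------------------------------------------------------------------
# balance


def balance_exponents(form: str = "polynomial", p_or_n: int = 2, transformed=None):
    """Homogeneous-balance degree for the transformed ODE.

    For the polynomial form the expansion degree n is *computed* by equating
    the lambda-degrees of the highest-derivative term (s'^4) and the highest
    power term (s^6) of the transformed ODE, with deg lambda' = p: a degree-n
    ansatz makes deg s'^4 = 4(n - 1 + p) and deg s^6 = 6n; their equality is
    solved for n.  Non-integer balances are reported, never rounded.

    For the rational form the degree relation m - l = 2(n - 1) is returned
    (as an integer once n is given).
    """
    if form == "rational":
        n = p_or_n
        return 2 * (n - 1)
    p = p_or_n
    T = transformed if transformed is not None else model.transformed_poly(CINT)
    n = sp.Symbol("n_deg", positive=True)
    poly = sp.Poly(T, model.S_, model.SP_)
    best_pow = None  # degree expr of the highest-derivative term
    best_s = None  # degree expr of the highest pure power of s
    max_dsp = max(m[1] for m in poly.monoms())
    max_ds = max(m[0] for m in poly.monoms() if m[1] == 0)
    for ds, dsp in poly.monoms():
        deg = ds * n + dsp * (n - 1 + p)
        if dsp == max_dsp:
            best_pow = deg
        if dsp == 0 and ds == max_ds:
            best_s = deg
    sols = sp.solve(sp.Eq(sp.expand(best_pow), sp.expand(best_s)), n)
    sols = [s for s in sols if s.is_positive is not False]
    if len(sols) != 1:
        raise RuntimeError(f"balance did not yield a unique degree: {sols}")
    nval = sols[0]
    if nval.is_number and not nval.is_integer:
        raise ValueError(f"no closed balance: n = {nval} is not an integer")
    return int(nval) if nval.is_number else sp.expand(nval)


# --------------------------------------------------------------------------
# algebraic system


@dataclass(frozen=True)
class AlgebraicSystem:
    family: str
    ansatz: Ansatz
    equations: tuple  # polynomial equations (lambda-power coefficients)
    unknowns: tuple
    free: tuple

    def __len__(self):
        return len(self.equations)

    def residuals(self, assignment: dict) -> list[sp.Expr]:
        return [sp.expand(e.subs(assignment)) for e in self.equations]


def _substitute_ansatz(T: sp.Expr, ansatz: Ansatz) -> sp.Expr:
    """Replace (s, s') in the transformed ODE by the ansatz; clear denominators."""
    s_l = sp.diff(ansatz.s_expr, LAM)
    lam2 = ansatz.aux.rhs if ansatz.aux.q == 2 else ansatz.aux.rhs**2
    sp2 = s_l**2 * lam2  # (s')^2 expressed in lambda
    poly = sp.Poly(T, model.SP_)
    expr = sp.S.Zero
    for (k,), coeff in zip(poly.monoms(), poly.coeffs()):
        if k % 2:
            raise ValueError("transformed ODE has odd powers of s'; cannot clear radical")
        expr += coeff * sp2 ** (k // 2)
    expr = expr.subs(model.S_, ansatz.s_expr)
    return sp.numer(sp.cancel(sp.together(expr)))


def derive_algebraic_system(family, transformed=None) -> AlgebraicSystem:
    """Collect lambda-power coefficients of the substituted ODE into equations."""
    ansatz = family if isinstance(family, Ansatz) else build_ansatz(family)
    T = transformed if transformed is not None else model.transformed_poly(CINT)
    expr = _substitute_ansatz(T, ansatz)
    eqs = [sp.expand(c) for c in sp.Poly(sp.expand(expr), LAM).all_coeffs()]
    eqs = tuple(e for e in eqs if e != 0)
    if not eqs:
        raise ValueError("ansatz produced the zero system (degenerate ansatz)")
    return AlgebraicSystem(
        family=ansatz.family,
        ansatz=ansatz,
        equations=eqs,
        unknowns=tuple(ansatz.unknowns),
        free=tuple(ansatz.free_coeffs) + (SYM.a1, SYM.a2, SYM.eta, SYM.zeta),
    )


# --------------------------------------------------------------------------
# branch solving


@dataclass(frozen=True)
class SolutionBranch:
    """One solved coefficient assignment of an algebraic system.

    ``assignment`` maps every solved symbol (A_k, constrained B_k or C0, the
    squared speed W = omega^2 and the implied first-integral constant CINT)
    to its expression in the free coefficients and model constants.
    """

    family: str
    assignment: dict
    ansatz: Ansatz
    sign: int  # -+ selector of the coefficient radical
    variant: Optional[str]  # secondary root selector where applicable

    @property
    def omega_sq(self) -> sp.Expr:
        return self.assignment[W]

    @property
    def C_implied(self) -> sp.Expr:
        """First-integral constant this branch implies (the printed
        derivation silently sets it; the engine records it)."""
        return self.assignment[CINT]

    def omega(self, sign: int = 1) -> sp.Expr:
        return sign * sp.sqrt(self.omega_sq)

    def s_of_lam(self) -> sp.Expr:
        return self.ansatz.s_expr.subs(self.assignment)

    def aux_rhs(self) -> sp.Expr:
        return self.ansatz.aux.rhs.subs(self.assignment)

    def coefficients(self) -> dict[str, sp.Expr]:
        names = {W: "omega_sq", CINT: "C"}
        return {names.get(k, str(k)): v for k, v in self.assignment.items()}

    def sort_key(self) -> str:
        return str(sorted((str(k), str(v)) for k, v in self.assignment.items()))

    def verify_numeric(self, system: AlgebraicSystem, subs: dict) -> float:
        """Max relative |equation| after numeric back-substitution (complex-safe).

        The scale of each equation is the sum of the magnitudes of its
        additive terms, so cancellation is measured, not absolute size.
        """
        worst = 0.0
        for eq in system.equations:
            e = sp.expand(eq.subs(self.assignment))
            terms = [complex(sp.N(t.subs(subs), 30)) for t in sp.Add.make_args(e)]
            val = abs(sum(terms))
            scale = max(1.0, sum(abs(t) for t in terms))
            worst = max(worst, val / scale)
        return worst

    def verify_symbolic(self, system: AlgebraicSystem) -> bool:
        """Every system equation simplifies to exactly zero under this branch."""
        for eq in system.equations:
            r = sp.simplify(sp.radsimp(sp.expand(eq.subs(self.assignment))))
            if sp.simplify(r) != 0:
                return False
        return True


# canonical positive test points used only to *label* the -+ branches
_CANON = {SYM.a1: 1, SYM.a2: 1, SYM.eta: 1, SYM.zeta: 1}
_CANON_B = {
    "solitary": {B0: 1, B1: 1, B2: 1},
    "soliton": {B1: 1, B2: 1},
    "elliptic": {B2: 1, B4: 1},
    "periodic_rational": {B0: 1, B2: 1, C1: 1},
    "soliton_rational": {B0: 1, B1: 3, B2: 1, C1: 1},
}


def _classify(family: str, assignment: dict) -> tuple[int, Optional[str]]:
    subs = {**_CANON, **_CANON_B[family]}
    lead = A0 if family.endswith("rational") else A2
    val = complex(sp.N(assignment[lead].subs(subs), 30))
    sign = 1 if val.real >= 0 else -1
    variant = None
    if family == "soliton_rational":
        v = complex(sp.N((2 * B2 * assignment[C0] - B1).subs(subs), 30))
        variant = "root+" if v.real >= 0 else "root-"
    elif family == "periodic_rational":
        v = complex(sp.N(assignment[C0].subs(subs), 30))
        variant = "root+" if v.real >= 0 else "root-"
    elif family == "elliptic":
        variant = "reduced" if assignment.get(B0, sp.S.One) == 0 else "quartic"
    return sign, variant


def solve_branches(system: AlgebraicSystem) -> list[SolutionBranch]:
    """Enumerate all consistent branches of the algebraic system.

    Returns branches sorted deterministically; raises if a candidate fails
    numeric back-substitution.  An empty list means no consistent branch.
    """
    ansatz = system.ansatz
    gauge = dict(ansatz.gauge)
    eqs_g = [sp.expand(e.subs(gauge)) for e in system.equations]
    unknowns_g = [u for u in system.unknowns if u not in gauge]
    nondeg = ansatz.nondegeneracy.subs(gauge)

    cases: list[tuple[dict, sp.Expr]] = []
    if ansatz.split_var is not None:
        v = ansatz.split_var
        # v = 0 branch: saturate what nondegeneracy reduces to
        cases.append(({v: sp.S.Zero}, sp.expand(nondeg.subs(v, 0))))
        cases.append(({}, sp.expand(v * nondeg)))
    else:
        cases.append(({}, nondeg))

    raw: list[dict] = []
    eliminated: list[str] = []
    for zero_subs, sat in cases:
        eqs_c = [sp.expand(e.subs(zero_subs)) for e in eqs_g]
        eqs_c = [e for e in eqs_c if e != 0]
        unk_c = [u for u in unknowns_g if u not in zero_subs]
        G = sp.groebner(eqs_c + [_Z * sat - 1], _Z, *unk_c, order="grevlex")
        if list(G.exprs) == [sp.S.One]:
            eliminated.append(f"case {zero_subs or 'generic'}: inconsistent (Groebner basis [1])")
            continue
        sols = sp.solve_poly_system(list(G.exprs), _Z, *unk_c, order="lex")
        for tup in sols:
            assignment = dict(zip(unk_c, tup[1:]))
            assignment.update({k: v for k, v in zero_subs.items()})
            raw.append(assignment)

    branches = []
    seen = set()
    for assignment in raw:
        # undo the gauge: numerator and denominator coefficients scale with C1
        if gauge:
            scale = C1
            for k in (A0, A1, C0):
                if k in assignment:
                    assignment[k] = sp.radsimp(assignment[k] * scale)
        assignment = {k: sp.radsimp(sp.simplify(v)) for k, v in assignment.items()}
        sign, variant = _classify(system.family, assignment)
        br = SolutionBranch(
            family=system.family,
            assignment=assignment,
            ansatz=ansatz,
            sign=sign,
            variant=variant,
        )
        if br.sort_key() in seen:
            continue
        seen.add(br.sort_key())
        # numeric back-substitution safeguard at the canonical point
        subs = {**_CANON, **_CANON_B[system.family]}
        worst = br.verify_numeric(system, subs)
        if worst > 1e-9:
            raise RuntimeError(
                f"branch failed back-substitution ({system.family}): residual {worst:g}"
            )
        branches.append(br)
    branches.sort(key=lambda b: (-b.sign, b.variant or "", b.sort_key()))
    if not branches and eliminated:
        import logging

        logging.getLogger(__name__).info("no consistent branch; %s", "; ".join(eliminated))
    return branches


@lru_cache(maxsize=None)
def solved_branches(family: str) -> tuple:
    """Cached symbolic solve of a family's algebraic system."""
    return tuple(solve_branches(derive_algebraic_system(family)))


# --------------------------------------------------------------------------
# auxiliary-equation integration


@dataclass(frozen=True)
class AuxSolution:
    """A verified closed form lambda(xi) for an auxiliary ODE."""

    expr: sp.Expr  # in SYM.xi (and c1 if symbolic)
    label: str
    aux: AuxiliaryODE

    def __iter__(self):  # convenience unpacking
        yield self.expr
        yield self.label


def _verify_aux(aux: AuxiliaryODE, lam_expr, label: str) -> None:
    res = aux.residual(lam_expr)
    res = reduce_squares(res) if res.atoms(sn) else res
    res = sp.simplify(sp.expand(res))
    if res != 0:
        res = sp.simplify(sp.radsimp(sp.expand_trig(res)))
    if res != 0:
        raise RuntimeError(f"auxiliary solution {label!r} failed verification: {res}")


def _is_zero(e) -> bool:
    e = sp.simplify(e)
    return e == 0


def integrate_auxiliary(aux: AuxiliaryODE, c1=None, verify: bool = True) -> list[AuxSolution]:
    """Closed-form solutions lambda(xi) of (lambda')^q = rhs(lambda).

    Case analysis on q and the structure of the right-hand side; every
    returned form is verified against the auxiliary ODE symbolically (for
    Jacobi-sn forms after reduction by the elliptic square identities).
    Unrecognized structures raise ``ValueError`` -- never a guessed form.
    """
    xi = SYM.xi
    c1 = sp.Symbol("c1") if c1 is None else sp.sympify(c1)
    u = xi + c1
    coeffs = aux.coeffs
    if not coeffs:
        raise ValueError("degenerate auxiliary equation: all coefficients zero")
    deg = max(coeffs)
    sols: list[AuxSolution] = []

    if aux.q == 1:
        if deg > 2:
            raise ValueError("q=1 auxiliary equations are supported up to degree 2")
        b0, b1, b2 = (coeffs.get(k, sp.S.Zero) for k in (0, 1, 2))
        if b2 == 0 and b1 == 0:
            sols.append(AuxSolution(b0 * u, "linear", aux))
        elif b2 == 0:
            sols.append(AuxSolution(-b0 / b1 + sp.exp(b1 * u), "exponential", aux))
        else:
            disc = sp.expand(b1**2 - 4 * b0 * b2)
            if disc.is_number:
                if disc == 0:
                    sols.append(AuxSolution(-b1 / (2 * b2) - 1 / (b2 * u), "rational", aux))
                elif disc.is_negative:
                    rt = sp.sqrt(-disc)
                    sols.append(AuxSolution(
                        (-b1 + rt * sp.tan(rt * u / 2)) / (2 * b2), "trigonometric", aux))
                else:
                    rt = sp.sqrt(disc)
                    sols.append(AuxSolution(
                        (-b1 - rt * sp.tanh(rt * u / 2)) / (2 * b2), "hyperbolic", aux))
            else:
                # symbolic discriminant: both the trigonometric and the
                # hyperbolic writing solve the ODE formally; return both
                rt = sp.sqrt(-disc)
                sols.append(AuxSolution(
                    (-b1 + rt * sp.tan(rt * u / 2)) / (2 * b2), "trigonometric", aux))
                rt = sp.sqrt(disc)
                sols.append(AuxSolution(
                    (-b1 - rt * sp.tanh(rt * u / 2)) / (2 * b2), "hyperbolic", aux))
    else:  # q == 2
        rhs = sp.expand(aux.rhs)
        if deg == 4 and coeffs.get(3, 0) == 0 and coeffs.get(1, 0) == 0 and 0 in coeffs:
            # even quartic: Jacobi sn with modulus from the coefficient ratios
            b0, b2, b4 = coeffs.get(0), coeffs.get(2, sp.S.Zero), coeffs.get(4)
            if _is_zero(b0 - b2**2 / (4 * b4)):
                # the branch-constrained case degenerates to modulus 1
                Bhat = sp.sqrt(-b2 / 2)
                Ahat = sp.sqrt(-b2 / (2 * b4))
                sols.append(AuxSolution(Ahat * sp.tanh(Bhat * u), "elliptic_sn_m1", aux))
            else:
                rho = sp.simplify(b2**2 / (b0 * b4))
                m2 = sp.Rational(1, 2) * (rho - 2 - sp.sqrt(rho * (rho - 4)))
                m = sp.sqrt(m2)
                Bhat = sp.sqrt(-b2 / (1 + m2))
                Ahat = sp.sqrt(b0) / Bhat
                sols.append(AuxSolution(Ahat * sn(Bhat * u, m), "elliptic_sn", aux))
        elif min(coeffs) >= 2:
            # rhs = lam^2 * g(lam)
            g = sp.expand(sp.cancel(rhs / LAM**2))
            gp = sp.Poly(g, LAM)
            if gp.degree() > 2:
                raise ValueError("unrecognized auxiliary equation (lam^2 * deg>2)")
            g0 = gp.nth(0)
            g1 = gp.nth(1)
            g2 = gp.nth(2)
            if _is_zero(g1**2 - 4 * g0 * g2):
                # perfect square: Bernoulli/Riccati with exponential solutions
                b = g1 / (2 * sp.sqrt(g2))
                c = sp.sqrt(g2)
                E1 = sp.exp(b * u)
                E2 = sp.exp(-b * u)
                sols.append(AuxSolution(b * E1 / (1 - c * E1), "E1", aux))
                sols.append(AuxSolution(b * E2 / (1 - c * E2), "E2", aux))
                # the complementary integration branch (negative integration
                # multiplier): bounded between the Riccati fixed points
                sols.append(AuxSolution(-b * E1 / (1 + c * E1), "E1b", aux))
                sols.append(AuxSolution(-b * E2 / (1 + c * E2), "E2b", aux))
            else:
                # invert: mu = 1/lam obeys mu'^2 = g2 + g1 mu + g0 mu^2
                inner = integrate_auxiliary(
                    AuxiliaryODE(2, g2 + g1 * LAM + g0 * LAM**2), c1, verify=False
                )
                for s_ in inner:
                    sols.append(AuxSolution(sp.cancel(1 / s_.expr), f"inverse_{s_.label}", aux))
        elif deg <= 2:
            b0, b1, b2 = (coeffs.get(k, sp.S.Zero) for k in (0, 1, 2))
            if b2 == 0 and b1 == 0:
                sols.append(AuxSolution(sp.sqrt(b0) * u, "linear", aux))
            elif b2 == 0:
                sols.append(AuxSolution(b1 * u**2 / 4 - b0 / b1, "parabolic", aux))
            else:
                disc = sp.expand(b1**2 - 4 * b0 * b2)
                pos2 = b2.is_positive if b2.is_number else None
                if pos2 is None:
                    raise ValueError(
                        "q=2 quadratic auxiliary equation needs a numeric lambda^2 "
                        "coefficient to select the circular/hyperbolic case"
                    )
                if pos2:
                    if disc.is_number and disc == 0:
                        sols.append(AuxSolution(
                            -b1 / (2 * b2) + sp.exp(sp.sqrt(b2) * u), "exp", aux))
                    elif disc.is_number and disc.is_negative:
                        sols.append(AuxSolution(
                            (-b1 + sp.sqrt(-disc) * sp.sinh(sp.sqrt(b2) * u)) / (2 * b2),
                            "sinh", aux))
                    else:
                        sols.append(AuxSolution(
                            (-b1 + sp.sqrt(disc) * sp.cosh(sp.sqrt(b2) * u)) / (2 * b2),
                            "cosh", aux))
                else:
                    amp = sp.sqrt(disc / (4 * b2**2))
                    sols.append(AuxSolution(
                        -b1 / (2 * b2) + amp * sp.sin(sp.sqrt(-b2) * u), "sine", aux))
        else:
            raise ValueError(f"unrecognized auxiliary equation: (lam')^2 = {rhs}")

    if not sols:
        raise ValueError(f"unrecognized auxiliary equation: {aux}")
    if verify:
        for s_ in sols:
            _verify_aux(aux, s_.expr, s_.label)
    return sols


# --------------------------------------------------------------------------
# assembly


@dataclass
class ClosedForm:
    """An assembled closed-form solution R = -(1/eta) ln s(lambda(xi))."""

    family: str
    branch: SolutionBranch
    label: str  # auxiliary-case label
    s_xi: sp.Expr
    s_eval: sp.Expr  # numerically stable equivalent of s_xi
    R_xi: sp.Expr
    R_xt: sp.Expr
    omega: sp.Expr
    subs: dict  # numeric substitutions applied (possibly empty)

    def r_xi_prime(self) -> sp.Expr:
        return sp.diff(self.R_xi, SYM.xi)

    def _lamb(self, expr, args):
        from .elliptic import NUMERIC_MODULES

        return sp.lambdify(args, expr, modules=NUMERIC_MODULES)

    def s_func(self):
        return self._lamb(self.s_eval, (SYM.xi,))

    def R_func(self):
        return self._lamb(self.R_xt, (SYM.x, SYM.t))

    def Rt_func(self):
        return self._lamb(sp.diff(self.R_xt, SYM.t), (SYM.x, SYM.t))

    def eval_grid(self, x, t):
        """FieldGrid of real R values; points with s <= 0 (or non-finite) masked."""
        from .grids import FieldGrid

        x = np.asarray(x, float)
        t = np.asarray(t, float)
        om = complex(sp.N(self.omega))
        if abs(om.imag) > 1e-10 * (1 + abs(om.real)):
            raise ValueError(f"branch wave speed is not real: omega = {om}")
        sf = self.s_func()
        xi = x[:, None] - om.real * t[None, :]
        with np.errstate(all="ignore"):
            sv = np.asarray(sf(xi.astype(complex)), dtype=complex) + np.zeros_like(xi, dtype=complex)
        eta = self.subs.get(SYM.eta, SYM.eta)
        real = np.abs(sv.imag) <= 1e-10 * (1.0 + np.abs(sv.real))
        ok = real & np.isfinite(sv.real) & (sv.real > 0)
        R = np.zeros_like(xi)
        with np.errstate(all="ignore"):
            R[ok] = -np.log(sv.real[ok]) / float(eta)
        return FieldGrid(x=x, t=t, R=R, mask=ok)


def assemble_R(
    branch: SolutionBranch,
    aux_sol: AuxSolution,
    subs: dict | None = None,
    omega_sign: int = 1,
) -> ClosedForm:
    """Assemble R(xi) and R(x, t) from a branch and an auxiliary solution.

    ``subs`` maps free symbols (model constants, free B's, C1, c1) to
    numbers; leave empty for a fully symbolic closed form.  The validity
    domain is {xi : s(xi) > 0}; evaluation masks the complement rather than
    returning complex values.
    """
    subs = dict(subs or {})
    eta = SYM.eta.subs(subs) if SYM.eta in subs else SYM.eta
    s_lam = branch.s_of_lam()
    s_xi = s_lam.subs(LAM, aux_sol.expr)
    if subs:
        s_xi = s_xi.subs(subs)
    s_xi = sp.cancel(sp.together(s_xi)) if not s_xi.has(sn) else s_xi
    # hyperbolic forms like 1 - tanh^2 cancel catastrophically in floating
    # point on the wings; the equivalent rational-in-exponentials form
    # evaluates by pure products and stays accurate to underflow
    s_eval = s_xi
    if s_xi.has(sp.tanh, sp.cosh, sp.sinh, sp.sech, sp.csch, sp.coth):
        s_eval = sp.cancel(sp.together(s_xi.rewrite(sp.exp)))
    R_xi = -sp.log(s_eval) / eta
    omega = branch.omega(omega_sign)
    if subs:
        omega = omega.subs(subs)
    R_xt = R_xi.subs(SYM.xi, SYM.x - omega * SYM.t)
    return ClosedForm(
        family=branch.family,
        branch=branch,
        label=aux_sol.label,
        s_xi=s_xi,
        s_eval=s_eval,
        R_xi=R_xi,
        R_xt=R_xt,
        omega=omega,
        subs=subs,
    )
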