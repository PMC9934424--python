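"""Unified-method engine: balance, ansatz, system, branches, auxiliary library."""

import numpy as np
import pytest
import sympy as sp

from pbdna import model, unified
from pbdna.params import SYM
from pbdna.unified import (
    A0, A1, A2, B0, B1, B2, B4, C0, C1, CINT, LAM, W,
    AnsatzSpec, AuxiliaryODE, SolutionBranch,
    balance_exponents, build_ansatz, derive_algebraic_system,
    integrate_auxiliary, assemble_R, solved_branches,
)


class TestBalance:
    def test_polynomial_p2(self):
        assert balance_exponents("polynomial", 2) == 2

    def test_polynomial_p3(self):
        assert balance_exponents("polynomial", 3) == 4

    def test_rational_relation(self):
        assert balance_exponents("rational", 1) == 0
        assert balance_exponents("rational", 2) == 2

    def test_enumeration_oracle(self):
        """Brute force: only n = 2 equalizes the top lambda-degrees of the
        s'^4 and s^6 terms for a degree-2 auxiliary polynomial (p = 2)."""
        p = 2
        good = []
        for n in range(1, 7):
            a = sp.symbols(f"a0:{n + 1}")
            s = sum(a[k] * LAM**k for k in range(n + 1))
            lamp = sum(sp.Symbol(f"b{k}") * LAM**k for k in range(p + 1))
            sprime = sp.diff(s, LAM) * lamp
            deg_pow = sp.degree(sp.expand(sprime**4), LAM)
            deg_s6 = sp.degree(sp.expand(s**6), LAM)
            if deg_pow == deg_s6:
                good.append(n)
        assert good == [2]


class TestBuildAnsatz:
    def test_solitary_template(self):
        a = build_ansatz("solitary")
        assert a.s_expr == A0 + A1 * LAM + A2 * LAM**2
        assert a.aux.q == 1
        assert sp.expand(a.aux.rhs - (B0 + B1 * LAM + B2 * LAM**2)) == 0

    def test_soliton_template_is_lambda_times_radical(self):
        a = build_ansatz("soliton")
        assert a.aux.q == 2
        assert sp.expand(a.aux.rhs - LAM**2 * (B0 + B1 * LAM + B2 * LAM**2)) == 0

    def test_rational_template_shape(self):
        a = build_ansatz("soliton_rational")
        num, den = sp.fraction(sp.together(a.s_expr))
        assert sp.expand(num - (A0 + A1 * LAM)) == 0
        assert sp.expand(den - (C0 + C1 * LAM)) == 0

    def test_lookup_by_spec(self):
        assert build_ansatz(AnsatzSpec("polynomial", n=2, q=1)).family == "solitary"

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown family"):
            build_ansatz("spiral")

    def test_discriminant(self):
        assert sp.expand(
            AuxiliaryODE(1, B0 + B1 * LAM + B2 * LAM**2).discriminant
            - (B1**2 - 4 * B0 * B2)
        ) == 0


class TestAlgebraicSystem:
    def test_solitary_unknowns_and_degree(self):
        sys_ = derive_algebraic_system("solitary")
        assert set(sys_.unknowns) == {A0, A1, A2, W, CINT}
        # highest collected power matches the balance bookkeeping:
        # deg s'^4 = 4(n - 1 + p) = 12 at n = p = 2
        assert len(sys_.equations) == 13

    def test_zero_assignment_rejected(self):
        # the zero polynomial is never stored as an equation
        for fam in unified.FAMILIES:
            sys_ = derive_algebraic_system(fam)
            assert all(e != 0 for e in sys_.equations)

    def test_branch_zeroes_system(self):
        sys_ = derive_algebraic_system("solitary")
        br = solved_branches("solitary")[0]
        assert all(
            sp.simplify(r) == 0 for r in sys_.residuals(br.assignment)
        ) or br.verify_symbolic(sys_)


class TestBranches:
    def test_solitary_proportionality(self):
        """Eq-structure check: A0:A1:A2 = B0:B1:B2 exactly."""
        for br in solved_branches("solitary"):
            a = br.assignment
            assert sp.simplify(a[A1] / a[A2] - B1 / B2) == 0
            assert sp.simplify(a[A0] / a[A2] - B0 / B2) == 0

    def test_soliton_A0_zero_and_quarter_constraint(self):
        for br in solved_branches("soliton"):
            a = br.assignment
            assert a[A0] == 0
            assert sp.simplify(a[B0] * B2 / B1**2 - sp.Rational(1, 4)) == 0

    def test_elliptic_structure(self):
        quartic = [b for b in solved_branches("elliptic") if b.variant == "quartic"]
        assert len(quartic) == 2
        for br in quartic:
            assert br.assignment[A1] == 0
            assert sp.simplify(br.assignment[B0] - B2**2 / (4 * B4)) == 0

    def test_rational_structure(self):
        for fam in ("periodic_rational", "soliton_rational"):
            brs = solved_branches(fam)
            assert len(brs) == 4  # two signs x two denominator roots
            for br in brs:
                assert br.assignment[A1] == 0
                assert br.assignment[C0].has(C1)

    def test_soliton_rational_C0_roots(self):
        """C0 = C1 (B1 +- sqrt(B1^2 - 4 B0 B2)) / (2 B2), as printed."""
        roots = {
            sp.simplify(
                (2 * B2 * br.assignment[C0] / C1 - B1) ** 2 - (B1**2 - 4 * B0 * B2)
            )
            for br in solved_branches("soliton_rational")
        }
        assert roots == {0}

    def test_sign_pairs(self):
        for fam in unified.FAMILIES:
            signs = sorted(b.sign for b in solved_branches(fam))
            assert -1 in signs and 1 in signs

    def test_numeric_backsubstitution(self):
        """Coefficients satisfy the system to < 1e-12 at a numeric point.

        With zeta = +1 the branch is real; with zeta = -1 the same assignment
        still zeroes the system over the complex numbers (the coefficient
        radical sqrt(a2/zeta) is then imaginary -- recorded, not hidden).
        """
        sys_ = derive_algebraic_system("soliton")
        br = solved_branches("soliton")[0]
        for zeta in (1, -1):
            subs = {SYM.a1: 1, SYM.a2: 1, SYM.eta: 1, SYM.zeta: zeta, B1: 0.5, B2: 1}
            assert br.verify_numeric(sys_, subs) < 1e-12
        vals = [complex(sp.N(br.assignment[k].subs(
            {SYM.a1: 1, SYM.a2: 1, SYM.eta: 1, SYM.zeta: 1, B1: 0.5, B2: 1})))
            for k in (A1, A2)]
        assert all(abs(v.imag) < 1e-14 for v in vals)

    def test_omega_is_plus_minus_root(self):
        br = solved_branches("solitary")[0]
        assert sp.simplify(br.omega(1) + br.omega(-1)) == 0
        assert sp.simplify(br.omega(1) ** 2 - br.omega_sq) == 0

    def test_branch_records_first_integral_constant(self):
        # the printed derivation silently drops C; every branch records its value
        for br in solved_branches("solitary"):
            assert br.C_implied != 0


AUX_CASES = [
    # (q, rhs, expected label fragment)
    (1, 1 + LAM**2, "trigonometric"),  # Delta = -4 -> tan
    (1, -sp.Rational(1, 4) + LAM**2, "hyperbolic"),  # Delta = 1 -> tanh
    (1, sp.Rational(1, 4) + LAM + LAM**2, "rational"),  # Delta = 0
    (1, LAM, "exponential"),  # B0 = 0, B1 = 1, B2 = 0
    (1, sp.Integer(3), "linear"),
    (2, LAM**2 * (1 + 2 * LAM + LAM**2), "E"),  # perfect square -> E1/E2
    (2, 1 - sp.Rational(3, 2) * LAM**2 + sp.Rational(1, 2) * LAM**4, "elliptic_sn"),
    (2, 4 - sp.Rational(1, 2) * LAM**2 + sp.Rational(1, 64) * LAM**4, "elliptic_sn_m1"),
    (2, 4 - LAM**2, "sine"),  # B0^2 - B2^2 lam^2
    (2, 1 + 3 * LAM + LAM**2, "cosh"),
    (2, 4 + LAM + LAM**2, "sinh"),
    (2, LAM**2 * (2 + 3 * LAM**2), "inverse"),  # non-square lam^2 factor
    (2, 2 + 3 * LAM, "parabolic"),
]


class TestAuxiliaryLibrary:
    @pytest.mark.parametrize("q,rhs,label", AUX_CASES)
    def test_every_case_verifies_symbolically(self, q, rhs, label):
        """Each returned lambda satisfies its auxiliary ODE exactly (the
        residual simplifies to zero) -- construction runs the verification."""
        sols = integrate_auxiliary(AuxiliaryODE(q, rhs), c1=sp.Symbol("c1"))
        assert any(label in s.label for s in sols)
        for s in sols:
            res = AuxiliaryODE(q, rhs).residual(s.expr)
            from pbdna.elliptic import reduce_squares, sn

            res = reduce_squares(res) if res.atoms(sn) else res
            assert sp.simplify(sp.expand_trig(sp.expand(res))) in (0, sp.S.Zero)

    def test_tan_example(self):
        sol = integrate_auxiliary(AuxiliaryODE(1, 1 + LAM**2), c1=sp.Symbol("c1"))[0]
        assert sol.expr == sp.tan(SYM.xi + sp.Symbol("c1"))

    def test_exp_example(self):
        sol = integrate_auxiliary(AuxiliaryODE(1, LAM), c1=sp.Symbol("c1"))[0]
        assert sol.expr == sp.exp(SYM.xi + sp.Symbol("c1"))

    def test_constrained_quartic_degenerates_to_modulus_one(self):
        """B0 = B2^2/(4 B4) forces Jacobi modulus 1: sn -> tanh."""
        aux = AuxiliaryODE(2, B2**2 / (4 * B4) + B2 * LAM**2 + B4 * LAM**4)
        (sol,) = integrate_auxiliary(aux, c1=0)
        assert sol.label == "elliptic_sn_m1"
        assert sol.expr.has(sp.tanh)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            integrate_auxiliary(AuxiliaryODE(1, sp.Integer(0)), c1=0)

    def test_unrecognized_reported(self):
        with pytest.raises(ValueError, match="supported up to degree 2"):
            integrate_auxiliary(AuxiliaryODE(1, 1 + LAM**3), c1=0)


class TestAssembly:
    def test_degenerate_unit_s_gives_zero_R(self):
        ansatz = build_ansatz("solitary")
        br = SolutionBranch(
            family="solitary",
            assignment={A0: sp.S.One, A1: sp.S.Zero, A2: sp.S.Zero,
                        W: sp.S.One, CINT: sp.S.Zero},
            ansatz=ansatz,
            sign=1,
            variant=None,
        )
        lam = integrate_auxiliary(AuxiliaryODE(1, 1 + LAM**2), c1=0)[0]
        cf = assemble_R(br, lam, subs={SYM.eta: 1.0})
        assert sp.simplify(cf.R_xi) == 0

    def test_solitary_trig_shape_reciprocal_of_one_plus_cos(self):
        """The trigonometric solitary closed form satisfies
        s(xi) * (1 + cos(sqrt(4 B0 B2 - B1^2) (xi + c1))) = const > 0,
        i.e. it is the reciprocal writing of the (1 + cos) form."""
        from pbdna.families import closed_form, verification_sets

        fp = [v for v in verification_sets() if v.family == "solitary" and v.sign == 1][0]
        cf = closed_form(fp)
        disc = fp.coeffs["B1"] ** 2 - 4 * fp.coeffs["B0"] * fp.coeffs["B2"]
        rt = sp.sqrt(sp.nsimplify(-disc, rational=True))
        prod = sp.simplify(cf.s_xi * (1 + sp.cos(rt * SYM.xi)))
        assert prod.is_number and prod > 0

    def test_invalid_sign_flagged_not_complex(self):
        """A branch whose s < 0 on the whole line yields an all-masked grid,
        never silent complex output."""
        from pbdna import families

        fp = families.FamilyParams(
            family="solitary",
            params=__import__("pbdna").ModelParams(a1=1, a2=1, eta=1, zeta=1),
            coeffs={"B0": -0.25, "B1": 0.0, "B2": 1.0},
            sign=1,  # the sech^2 profile with the positive sign: s < 0
        )
        fg = families.eval_family(fp, np.linspace(-5, 5, 100), np.linspace(0, 0.5, 5))
        assert not fg.mask.any()
        assert np.isfinite(fg.R).all()
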