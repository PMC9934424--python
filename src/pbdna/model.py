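"""The continuum PB model: PDE residuals, traveling reduction, first integral.

The chain implemented here is

1. the PDE  R_tt - (a1 + 3 a2 R_x^2) R_xx - 2 eta zeta e^{-eta R}(e^{-eta R}-1) = 0,
2. its reduction under R(x,t) = r(xi), xi = x - omega t,
3. the first integral obtained by multiplying the reduced ODE by r' and
   integrating (the fractional coefficients are *derived* here by
   undetermined-coefficient matching, so the identity dF/dxi = r' * ODE holds
   exactly by construction),
4. the exponential substitution s = e^{-eta r}, which turns the first
   integral into a polynomial ODE in (s, s') -- the object the unified-method
   engine expands in powers of the auxiliary function.
"""

from __future__ import annotations

import numpy as np
import sympy as sp

from .grids import FieldGrid
from .params import SYM, ModelParams

__all__ = [
    "pde_expr",
    "pde_residual",
    "analytic_residual",
    "traveling_reduce",
    "first_integral",
    "first_integral_residual",
    "exp_substitute",
    "transformed_poly",
    "energy",
    "energy_density_expr",
]

# Dedicated symbols for the polynomial form of the transformed ODE:
# S stands for s(xi), SP for s'(xi), W for omega**2.
S_ = sp.Symbol("S_")
SP_ = sp.Symbol("SP_")
W_ = sp.Symbol("W_")


def _morse_force(R, params=None):
    """The Morse restoring term 2 eta zeta e^{-eta R}(e^{-eta R} - 1)."""
    eta = SYM.eta if params is None else params.eta
    zeta = SYM.zeta if params is None else params.zeta
    return 2 * eta * zeta * sp.exp(-eta * R) * (sp.exp(-eta * R) - 1)


def pde_expr(params: ModelParams | None = None):
    """Left-hand side of the PB PDE as a sympy expression in R(x, t)."""
    a1 = SYM.a1 if params is None else params.a1
    a2 = SYM.a2 if params is None else params.a2
    R = SYM.R(SYM.x, SYM.t)
    Rx = sp.diff(R, SYM.x)
    return (
        sp.diff(R, SYM.t, 2)
        - (a1 + 3 * a2 * Rx**2) * sp.diff(R, SYM.x, 2)
        - _morse_force(R, params)
    )


def pde_residual(field: FieldGrid, params: ModelParams) -> FieldGrid:
    """Finite-difference PDE residual on interior points.

    Second-order central stencils in both x and t; the one-point boundary
    layer is masked out, as are points whose stencil touches a masked point.
    """
    if field.x.size < 5 or field.t.size < 5:
        raise ValueError("need >= 5 points in each of x and t for the residual stencil")
    R = field.R
    dx, dt = field.dx, field.dt
    res = np.zeros_like(R)
    Rtt = (R[:, 2:] - 2 * R[:, 1:-1] + R[:, :-2]) / dt**2
    Rxx = (R[2:, :] - 2 * R[1:-1, :] + R[:-2, :]) / dx**2
    Rx = (R[2:, :] - R[:-2, :]) / (2 * dx)
    inner = np.zeros_like(R)
    e = np.exp(-params.eta * R)
    inner[1:-1, 1:-1] = (
        Rtt[1:-1, :]
        - (params.a1 + 3 * params.a2 * Rx[:, 1:-1] ** 2) * Rxx[:, 1:-1]
        - 2 * params.eta * params.zeta * e[1:-1, 1:-1] * (e[1:-1, 1:-1] - 1)
    )
    res[:] = inner
    mask = np.zeros_like(field.mask)
    # valid where the full 5-point cross of the stencil is valid
    m = field.mask
    mask[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[2:, 1:-1] & m[:-2, 1:-1] & m[1:-1, 2:] & m[1:-1, :-2]
    )
    res[~mask] = 0.0
    return FieldGrid(x=field.x, t=field.t, R=res, mask=mask)


def analytic_residual(
    R_xt, params: ModelParams, x: np.ndarray, t: np.ndarray, relative: bool = False
) -> np.ndarray:
    """Evaluate the PDE residual of a closed form R(x, t) with *analytic* derivatives.

    ``R_xt`` is a sympy expression in SYM.x, SYM.t.  Returns a complex array
    (nx, nt); for an exact solution its magnitude is at rounding level
    wherever the solution is valid.

    With ``relative=True`` the residual is divided by the sum of the
    magnitudes of the three PDE terms (acceleration, dispersion, Morse force,
    floored at 1): near a log singularity of the solution the individual
    terms grow without bound, and only the term-relative residual is a
    numerically meaningful measure of exactness there.
    """
    from .elliptic import NUMERIC_MODULES

    Rx = sp.diff(R_xt, SYM.x)
    terms = [
        sp.diff(R_xt, SYM.t, 2),
        -(params.a1 + 3 * params.a2 * Rx**2) * sp.diff(R_xt, SYM.x, 2),
        -2
        * params.eta
        * params.zeta
        * sp.exp(-params.eta * R_xt)
        * (sp.exp(-params.eta * R_xt) - 1),
    ]
    X, T = np.meshgrid(np.asarray(x, float), np.asarray(t, float), indexing="ij")
    vals = []
    for term in terms:
        f = sp.lambdify((SYM.x, SYM.t), term, modules=NUMERIC_MODULES)
        with np.errstate(all="ignore"):
            # extended precision absorbs the cancellation amplification that
            # double precision suffers next to the log singularities
            v = f(X.astype(np.clongdouble), T.astype(np.clongdouble))
        vals.append((np.asarray(v) + np.zeros_like(X, dtype=np.clongdouble)).astype(complex))
    res = vals[0] + vals[1] + vals[2]
    if relative:
        scale = np.maximum(sum(np.abs(v) for v in vals), 1.0)
        res = res / scale
    return res


def traveling_reduce(params: ModelParams | None = None, omega=None):
    """Reduced traveling-wave ODE in r(xi): substitute R = r(x - omega t)."""
    w = SYM.omega if omega is None else omega
    a1 = SYM.a1 if params is None else params.a1
    a2 = SYM.a2 if params is None else params.a2
    r = SYM.r(SYM.xi)
    rp = sp.diff(r, SYM.xi)
    rpp = sp.diff(r, SYM.xi, 2)
    return w**2 * rpp - (a1 + 3 * a2 * rp**2) * rpp - _morse_force(r, params)


def first_integral(params: ModelParams | None = None, omega=None, C=None):
    """First integral F of the reduced ODE, with coefficients derived.

    F = c_2 r'^2 + c_4 r'^4 + zeta e^{-eta r}(e^{-eta r} - 2) + C, where
    (c_2, c_4) are fixed by requiring dF/dxi == r' * (reduced ODE) as a
    symbolic identity.  The derivation, not any printed form, is normative.
    """
    r = SYM.r(SYM.xi)
    rp = sp.diff(r, SYM.xi)
    c2, c4 = sp.symbols("c2 c4")
    # derive with exact symbols; numeric values are substituted only at the end
    F = (
        c2 * rp**2
        + c4 * rp**4
        + SYM.zeta * sp.exp(-SYM.eta * r) * (sp.exp(-SYM.eta * r) - 2)
        + SYM.C
    )
    target = rp * traveling_reduce(None, None)
    diff = sp.expand(sp.diff(F, SYM.xi) - target)
    # match coefficients of the independent structures r' r'' and r'^3 r''
    rpp = sp.diff(r, SYM.xi, 2)
    eq_c2 = diff.coeff(rpp).coeff(rp, 1)
    eq_c4 = diff.coeff(rpp).coeff(rp, 3)
    sol = sp.solve([eq_c2, eq_c4], [c2, c4], dict=True)
    if len(sol) != 1:
        raise RuntimeError("first-integral coefficient matching failed")
    F = F.subs(sol[0])
    # the Morse parts must now cancel identically
    check = sp.simplify(sp.diff(F, SYM.xi) - target)
    if check != 0:
        raise RuntimeError(f"first-integral identity violated: {check}")
    subs = {}
    if params is not None:
        subs.update(params.subs())
        subs.pop(SYM.C, None)
    if omega is not None:
        subs[SYM.omega] = omega
    if C is not None:
        subs[SYM.C] = C
    return F.subs(subs)


def first_integral_residual(r_expr, params: ModelParams, omega: float, C: float | None = None):
    """F(xi) for a concrete profile r(xi) = ``r_expr`` (sympy expr in SYM.xi).

    Constant (== 0 for the branch-implied C) exactly when the profile solves
    the reduced ODE.
    """
    Cv = params.C if C is None else C
    F = first_integral(params, omega, Cv)
    return F.subs(SYM.r(SYM.xi), r_expr).doit()


def exp_substitute(params: ModelParams | None = None, omega=None, C=None):
    """Polynomial ODE in s(xi) obtained from the first integral via s = e^{-eta r}.

    Returns the expression

        (omega^2 - a1)/(2 eta^2) s^2 s'^2 - 3 a2/(4 eta^4) s'^4
            + zeta s^5 (s - 2) + C s^4

    derived by substituting r = -ln(s)/eta and clearing s^4 (the fraction
    placement follows from the derivation in :func:`first_integral`).
    """
    eta = SYM.eta if params is None else params.eta
    s = SYM.s(SYM.xi)
    F = first_integral(params, omega, C)
    F = F.subs(SYM.r(SYM.xi), -sp.log(s) / eta).doit()
    expr = sp.expand(sp.cancel(sp.expand(F * s**4)))
    return expr


def transformed_poly(C_symbol=None):
    """The transformed ODE as a polynomial in the plain symbols (S_, SP_).

    Uses W_ = omega^2 and symbolic model constants; this is the input the
    unified-method engine expands with the ansatz.  Returned expression is
    polynomial in S_ and even in SP_.
    """
    Cc = SYM.C if C_symbol is None else C_symbol
    w = sp.sqrt(W_)
    expr = exp_substitute(None, w, Cc)
    s = SYM.s(SYM.xi)
    expr = expr.subs(sp.Derivative(s, SYM.xi), SP_).subs(s, S_)
    return sp.expand(expr)


def energy_density_expr(params: ModelParams | None = None):
    """Hamiltonian density: (1/2)R_t^2 + (1/2)a1 R_x^2 + (1/4)a2 R_x^4 + zeta(e^{-eta R}-1)^2.

    Its integral over a periodic domain is conserved by the PDE (the time
    derivative reduces to a total x-flux; checked symbolically in the tests).
    """
    a1 = SYM.a1 if params is None else params.a1
    a2 = SYM.a2 if params is None else params.a2
    eta = SYM.eta if params is None else params.eta
    zeta = SYM.zeta if params is None else params.zeta
    R = SYM.R(SYM.x, SYM.t)
    Rt = sp.diff(R, SYM.t)
    Rx = sp.diff(R, SYM.x)
    return (
        Rt**2 / 2 + a1 * Rx**2 / 2 + a2 * Rx**4 / 4 + zeta * (sp.exp(-eta * R) - 1) ** 2
    )


def energy(R: np.ndarray, V: np.ndarray, dx: float, params: ModelParams) -> float:
    """Discrete energy on a periodic grid (trapezoid == rectangle sum on a loop).

    ``R`` and ``V = R_t`` are samples on a uniform periodic grid of spacing
    ``dx`` (right endpoint excluded).  R_x uses the centered periodic stencil,
    matching the simulator's discretization so that conservation is a
    property of the scheme, not of interpolation.
    """
    R = np.asarray(R, float)
    V = np.asarray(V, float)
    Rx = (np.roll(R, -1) - np.roll(R, 1)) / (2 * dx)
    e = np.exp(-params.eta * R)
    dens = 0.5 * V**2 + 0.5 * params.a1 * Rx**2 + 0.25 * params.a2 * Rx**4 + params.zeta * (e - 1) ** 2
    return float(dens.sum() * dx)
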