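"""Minimal symbolic Jacobi elliptic functions sn, cn, dn.

sympy has no symbolic Jacobi elliptic functions, so the three needed here are
defined with their differentiation rules (d/du sn = cn dn, etc.) and modulus
conventions: ``sn(u, m)`` with *modulus* m (so dn^2 = 1 - m^2 sn^2).  The
degenerations m -> 1 (tanh/sech) and m -> 0 (sin/cos) are evaluated eagerly,
which is what the quartic auxiliary equation of the engine actually produces
(its branch constraint forces m = 1).

:func:`reduce_squares` rewrites even powers of cn and dn through sn using the
Pythagorean identities, which is enough to verify any auxiliary-equation
solution symbolically.  Numeric evaluation maps onto scipy's ``ellipj``
(whose parameter is m^2).
"""

from __future__ import annotations

import sympy as sp
from scipy import special as _special

__all__ = ["sn", "cn", "dn", "reduce_squares", "NUMERIC_MODULES"]


class sn(sp.Function):
    nargs = 2

    @classmethod
    def eval(cls, u, m):
        if m == 1:
            return sp.tanh(u)
        if m == -1:
            return sp.tanh(u)
        if m == 0:
            return sp.sin(u)
        if u == 0:
            return sp.S.Zero

    def fdiff(self, argindex=1):
        if argindex != 1:
            raise sp.ArgumentIndexError(self, argindex)
        u, m = self.args
        return cn(u, m) * dn(u, m)


class cn(sp.Function):
    nargs = 2

    @classmethod
    def eval(cls, u, m):
        if m == 1 or m == -1:
            return sp.sech(u)
        if m == 0:
            return sp.cos(u)
        if u == 0:
            return sp.S.One

    def fdiff(self, argindex=1):
        if argindex != 1:
            raise sp.ArgumentIndexError(self, argindex)
        u, m = self.args
        return -sn(u, m) * dn(u, m)


class dn(sp.Function):
    nargs = 2

    @classmethod
    def eval(cls, u, m):
        if m == 1 or m == -1:
            return sp.sech(u)
        if m == 0:
            return sp.S.One
        if u == 0:
            return sp.S.One

    def fdiff(self, argindex=1):
        if argindex != 1:
            raise sp.ArgumentIndexError(self, argindex)
        u, m = self.args
        return -(m**2) * sn(u, m) * cn(u, m)


def reduce_squares(expr):
    """Rewrite cn^2 -> 1 - sn^2 and dn^2 -> 1 - m^2 sn^2, repeatedly.

    After this rewrite a polynomial identity among sn/cn/dn that holds on the
    elliptic curve becomes a literal polynomial identity in sn (with cn, dn
    left at most to first power).
    """

    def _pow_repl(b, e):
        if isinstance(b, cn) and e.is_Integer and e >= 2:
            u, m = b.args
            return (1 - sn(u, m) ** 2) ** (e // 2) * b ** (e % 2)
        if isinstance(b, dn) and e.is_Integer and e >= 2:
            u, m = b.args
            return (1 - m**2 * sn(u, m) ** 2) ** (e // 2) * b ** (e % 2)
        return b**e

    prev = None
    e = sp.expand(expr)
    while e != prev:
        prev = e
        e = sp.expand(e.replace(sp.Pow, _pow_repl))
    return e


def _sn_num(u, m):
    return _special.ellipj(u, m**2)[0]


def _cn_num(u, m):
    return _special.ellipj(u, m**2)[1]


def _dn_num(u, m):
    return _special.ellipj(u, m**2)[2]


#: extra lambdify module for numeric evaluation of sn/cn/dn
NUMERIC_MODULES = [{"sn": _sn_num, "cn": _cn_num, "dn": _dn_num}, "numpy"]
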