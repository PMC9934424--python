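"""Model parameters and the traveling-wave frame.

The continuum Peyrard-Bishop (PB) model describes the hydrogen-bond
stretching field R(x, t) of a DNA duplex:

    R_tt - (a1 + 3 a2 R_x^2) R_xx - 2 eta zeta e^{-eta R} (e^{-eta R} - 1) = 0

``a1`` is the harmonic inter-site (strand) coupling, ``a2`` the anharmonic
correction to it, and ``(eta, zeta)`` are the inverse width and strength of
the Morse potential binding the two strands.  Traveling-wave reductions use
the co-moving coordinate xi = x - omega*t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import sympy as sp

__all__ = ["SYM", "ModelParams", "WaveFrame"]


class _Symbols:
    """Canonical sympy symbols shared by all symbolic routines."""

    x = sp.Symbol("x", real=True)
    t = sp.Symbol("t", real=True)
    xi = sp.Symbol("xi", real=True)
    a1 = sp.Symbol("a1", real=True)
    a2 = sp.Symbol("a2", real=True)
    eta = sp.Symbol("eta", real=True, nonzero=True)
    zeta = sp.Symbol("zeta", real=True)
    omega = sp.Symbol("omega", real=True)
    C = sp.Symbol("C", real=True)
    # traveling profile r(xi), field R(x,t), auxiliary-substitution s(xi)
    r = sp.Function("r")
    R = sp.Function("R")
    s = sp.Function("s")


SYM = _Symbols()


@dataclass(frozen=True)
class ModelParams:
    """The four PB model constants plus the first-integral constant C.

    ``eta`` must be nonzero (it scales the Morse exponent); ``a1`` must be
    nonzero for the modulation-instability operations, which divide by it.
    Positivity of the physical constants is *recorded*, not enforced: several
    solution families only exist for sign combinations (e.g. a2*zeta > 0)
    that evaluators check individually.
    """

    a1: float
    a2: float
    eta: float
    zeta: float
    C: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "eta", "zeta", "C"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ValueError(f"ModelParams.{name} must be finite, got {v!r}")
        if self.eta == 0:
            raise ValueError("ModelParams.eta must be nonzero")

    def require_a1(self) -> None:
        """Raise if a1 == 0 (needed wherever the dispersion divides by a1)."""
        if self.a1 == 0:
            raise ValueError("operation requires a1 != 0 (division by a1)")

    def subs(self) -> dict[sp.Symbol, float]:
        """Substitution map onto the canonical symbols."""
        return {
            SYM.a1: self.a1,
            SYM.a2: self.a2,
            SYM.eta: self.eta,
            SYM.zeta: self.zeta,
            SYM.C: self.C,
        }

    def to_dict(self) -> dict[str, float]:
        return {
            "a1": float(self.a1),
            "a2": float(self.a2),
            "eta": float(self.eta),
            "zeta": float(self.zeta),
            "C": float(self.C),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class WaveFrame:
    """Traveling frame xi = x - omega*t with the auxiliary integration constant c1."""

    omega: float
    c1: float = 0.0

    def xi(self, x, t):
        return x - self.omega * t
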