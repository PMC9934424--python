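"""Discrete space-time fields.

A :class:`FieldGrid` holds real values R on a uniform x-by-t lattice together
with a validity mask (closed-form solutions have log singularities that must
be masked, and finite-difference residuals are undefined on boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldGrid", "check_uniform"]

_UNIFORM_RTOL = 1e-12


def check_uniform(v: np.ndarray, name: str = "grid") -> float:
    """Return the spacing of a strictly increasing uniform 1-d grid.

    Raises ``ValueError`` with a diagnostic if the spacing varies by more
    than 1e-12 relative or the grid is not increasing.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name} must be 1-d with at least 2 points")
    d = np.diff(v)
    if np.any(d <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    h = float(d[0])
    if np.max(np.abs(d - h)) > _UNIFORM_RTOL * max(abs(h), np.abs(v).max()):
        raise ValueError(
            f"{name} is not uniform: spacing varies between {d.min():g} and {d.max():g}"
        )
    return h


@dataclass
class FieldGrid:
    """R values on the lattice ``x[i], t[j] -> R[i, j]`` with validity mask."""

    x: np.ndarray
    t: np.ndarray
    R: np.ndarray
    mask: np.ndarray = field(default=None)  # True where valid

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        check_uniform(self.x, "x")
        check_uniform(self.t, "t")
        if self.R.shape != (self.x.size, self.t.size):
            raise ValueError(
                f"R has shape {self.R.shape}, expected {(self.x.size, self.t.size)}"
            )
        if self.mask is None:
            self.mask = np.ones_like(self.R, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.R.shape:
                raise ValueError("mask shape must match R")
        if not np.all(np.isfinite(self.R[self.mask])):
            raise ValueError("R contains non-finite values at unmasked points")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @classmethod
    def from_function(cls, f, x, t) -> "FieldGrid":
        """Sample ``f(x, t)`` (vectorized) on the lattice; mask non-finite output."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(t, dtype=float)
        vals = np.asarray(f(x[:, None], t[None, :]), dtype=complex)
        vals = vals + np.zeros((x.size, t.size), dtype=complex)
        real = np.abs(vals.imag) <= 1e-12 * (1.0 + np.abs(vals.real))
        R = np.where(real, vals.real, np.nan)
        mask = real & np.isfinite(R)
        R = np.where(mask, R, 0.0)
        return cls(x=x, t=t, R=R, mask=mask)

    def slice_t(self, j: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (x, R[:, j], mask[:, j]) for one time slice."""
        return self.x, self.R[:, j], self.mask[:, j]
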