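"""Modulation instability (MI) of the PB model, exactly as the analysis prints it.

The steady state of incident power Z0 is perturbed by plane waves
Gamma ~ e^{i(kappa x - Omega t)}; the dispersion relation

    kappa(Omega) = +- sqrt( (-Omega^2 - 2 (1 + Z0) zeta eta^2) / a1 )

classifies each frequency as stable (kappa real) or unstable (kappa
imaginary, exponential growth), with gain spectrum h(Omega) = 2 Im kappa.

A caveat the module documents rather than repairs: the printed linearized
equation Gamma_tt + a1 Gamma_xx + 2 eta^2 zeta (Z0 + Gamma) = 0 does *not*
reproduce the (1 + Z0) factor of the dispersion relation above (plane-wave
substitution into it gives a1 kappa^2 = 2 zeta eta^2 - Omega^2, independent
of Z0, plus a constant forcing 2 eta^2 zeta Z0 showing the steady state is
not an exact solution).  :func:`linearized_residual` exposes the printed
linearization so the mismatch is measurable; the dispersion and gain above
remain the module's contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import FieldGrid
from .params import ModelParams

__all__ = [
    "MISpectrum",
    "dispersion_kappa",
    "classify_stability",
    "gain_spectrum",
    "linearized_residual",
    "consistent_kappa_sq",
]

#: radicands within this of zero are classified marginal-stable
_MARGINAL_TOL = 1e-12


def _radicand(Omega, params: ModelParams, Z0: float):
    params.require_a1()
    Omega = np.asarray(Omega, dtype=float)
    return (-(Omega**2) - 2 * (1 + Z0) * params.zeta * params.eta**2) / params.a1


def dispersion_kappa(Omega, params: ModelParams, Z0: float):
    """Both roots +-kappa(Omega) of the dispersion relation (complex).

    The principal branch (Im kappa >= 0, and Re kappa >= 0 where real) is
    returned first; the two roots always sum to zero.
    """
    rad = _radicand(Omega, params, Z0)
    kappa = np.sqrt(rad.astype(complex))
    return kappa, -kappa


def classify_stability(params: ModelParams, Z0: float, Omega):
    """'stable' where kappa is real, 'unstable' where imaginary, 'marginal'
    on the boundary (radicand == 0 within tolerance)."""
    scalar = np.ndim(Omega) == 0
    rad = np.atleast_1d(_radicand(Omega, params, Z0))
    labels = np.where(rad > 0, "stable", "unstable").astype(object)
    labels[np.abs(rad) <= _MARGINAL_TOL] = "marginal"
    return str(labels[0]) if scalar else labels


@dataclass
class MISpectrum:
    """Gain spectrum on a frequency grid."""

    Omega: np.ndarray
    kappa: np.ndarray  # principal root, complex
    h: np.ndarray  # gain 2 |Im kappa| >= 0
    labels: np.ndarray  # stability label per frequency
    Z0: float
    params: ModelParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "Omega": self.Omega,
                "Re_kappa": self.kappa.real,
                "Im_kappa": self.kappa.imag,
                "h": self.h,
                "label": self.labels,
            }
        )


def gain_spectrum(Omega, params: ModelParams, Z0: float) -> MISpectrum:
    """Gain h(Omega) = 2 Im kappa over a frequency grid.

    Equal to 2 sqrt((Omega^2 + 2 (1 + Z0) zeta eta^2) / a1) where that
    radicand is positive (the unstable band) and exactly 0 where kappa is
    real.
    """
    Omega = np.atleast_1d(np.asarray(Omega, dtype=float))
    kappa, _ = dispersion_kappa(Omega, params, Z0)
    h = 2 * np.abs(kappa.imag)
    return MISpectrum(
        Omega=Omega,
        kappa=kappa,
        h=h,
        labels=classify_stability(params, Z0, Omega),
        Z0=Z0,
        params=params,
    )


def consistent_kappa_sq(Omega: float, params: ModelParams, Z0: float = 0.0) -> float:
    """kappa^2 that actually solves the printed linearized equation:
    a1 kappa^2 = 2 zeta eta^2 - Omega^2 (independent of Z0)."""
    params.require_a1()
    return (2 * params.zeta * params.eta**2 - Omega**2) / params.a1


def linearized_residual(gamma_field: FieldGrid, params: ModelParams, Z0: float) -> FieldGrid:
    """Central-difference residual of the printed linearization
    Gamma_tt + a1 Gamma_xx + 2 eta^2 zeta (Z0 + Gamma) on interior points."""
    if gamma_field.x.size < 5 or gamma_field.t.size < 5:
        raise ValueError("need >= 5 points in each of x and t")
    G = gamma_field.R
    dx, dt = gamma_field.dx, gamma_field.dt
    res = np.zeros_like(G)
    Gtt = (G[:, 2:] - 2 * G[:, 1:-1] + G[:, :-2]) / dt**2
    Gxx = (G[2:, :] - 2 * G[1:-1, :] + G[:-2, :]) / dx**2
    res[1:-1, 1:-1] = (
        Gtt[1:-1, :]
        + params.a1 * Gxx[:, 1:-1]
        + 2 * params.eta**2 * params.zeta * (Z0 + G[1:-1, 1:-1])
    )
    mask = np.zeros_like(gamma_field.mask)
    m = gamma_field.mask
    mask[1:-1, 1:-1] = (
        m[1:-1, 1:-1] & m[2:, 1:-1] & m[:-2, 1:-1] & m[1:-1, 2:] & m[1:-1, :-2]
    )
    res[~mask] = 0.0
    return FieldGrid(x=gamma_field.x, t=gamma_field.t, R=res, mask=mask)
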