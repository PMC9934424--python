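"""Four-panel field plots and the MI gain figure.

Panels mirror the figure layout used for this model: (a) 3-d surface of
R (or |R|), (b) line in x at fixed t, (c) line in t at fixed x, (d) contour.
Rendering is deterministic for fixed backend settings (no timestamps are
embedded).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .grids import FieldGrid
from .mi import MISpectrum

__all__ = ["render_panels", "render_gain"]

_SAVEFIG = dict(dpi=110, metadata={"Software": None})


def render_panels(field: FieldGrid, out_dir, stem: str = "field", absolute: bool = False):
    """Write the four panel PNGs; returns the list of paths."""
    if not field.mask.any():
        raise ValueError("cannot render an all-masked field")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Z = np.where(field.mask, np.abs(field.R) if absolute else field.R, np.nan)
    X, T = np.meshgrid(field.x, field.t, indexing="ij")
    label = "|R(x,t)|" if absolute else "R(x,t)"
    paths = []

    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(X, T, Z, cmap="viridis", rstride=4, cstride=1)
    ax.set_xlabel("x"), ax.set_ylabel("t"), ax.set_title(label)
    p = out_dir / f"{stem}_surface.png"
    fig.savefig(p, **_SAVEFIG); plt.close(fig); paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(field.x, Z[:, 0])
    ax.set_xlabel("x"), ax.set_ylabel(label), ax.set_title(f"t = {field.t[0]:g}")
    p = out_dir / f"{stem}_line_x.png"
    fig.savefig(p, **_SAVEFIG); plt.close(fig); paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.2))
    mid = field.x.size // 2
    ax.plot(field.t, Z[mid, :])
    ax.set_xlabel("t"), ax.set_ylabel(label), ax.set_title(f"x = {field.x[mid]:g}")
    p = out_dir / f"{stem}_line_t.png"
    fig.savefig(p, **_SAVEFIG); plt.close(fig); paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 3.6))
    ax.contourf(field.x, field.t, Z.T, levels=30, cmap="viridis")
    ax.set_xlabel("x"), ax.set_ylabel("t"), ax.set_title(label)
    p = out_dir / f"{stem}_contour.png"
    fig.savefig(p, **_SAVEFIG); plt.close(fig); paths.append(p)
    return paths


def render_gain(spectra: list[MISpectrum], out_path):
    """Gain curves h(Omega) for several incident powers Z0 on one axis."""
    fig, ax = plt.subplots(figsize=(5, 3.6))
    for spec in spectra:
        ax.plot(spec.Omega, spec.h, label=f"$Z_0$ = {spec.Z0:g}")
    ax.set_xlabel(r"$\Omega$"), ax.set_ylabel(r"gain $h(\Omega)$")
    ax.legend()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, **_SAVEFIG)
    plt.close(fig)
    return out_path
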