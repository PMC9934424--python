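"""Serialization: field CSV, branch JSON, spectrum CSV, resolved configs.

Plain-text formats only.  Fields are long-format CSV with columns
(x, t, R, mask) plus a JSON sidecar for parameters; symbolic expressions are
serialized as sympy strings (canonical infix) and parsed back with sympify.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp

from .grids import FieldGrid
from .mi import MISpectrum
from .params import ModelParams
from .unified import SolutionBranch, solved_branches

__all__ = [
    "write_field",
    "read_field",
    "branch_to_dict",
    "write_branches",
    "read_branch_exprs",
    "write_spectrum",
    "read_spectrum",
    "write_resolved_config",
    "expr_to_str",
    "str_to_expr",
]

SPECTRUM_COLUMNS = ["Omega", "Re_kappa", "Im_kappa", "h", "label"]


def expr_to_str(expr) -> str:
    return sp.sstr(sp.sympify(expr), order="lex")


def str_to_expr(s: str):
    from .elliptic import cn, dn, sn
    from .params import SYM

    # 'eta'/'zeta' must parse as the model symbols, not sympy's special functions
    names = {
        "sn": sn, "cn": cn, "dn": dn,
        "eta": SYM.eta, "zeta": SYM.zeta, "omega": SYM.omega,
        "a1": SYM.a1, "a2": SYM.a2, "xi": SYM.xi, "x": SYM.x, "t": SYM.t,
    }
    return sp.sympify(s, locals=names)


def write_field(path, field: FieldGrid, params: ModelParams | None = None, meta: dict | None = None):
    """Field CSV (x, t, R, mask) + JSON sidecar '<path>.json' for metadata."""
    path = Path(path)
    X, T = np.meshgrid(field.x, field.t, indexing="ij")
    df = pd.DataFrame(
        {
            "x": X.ravel(),
            "t": T.ravel(),
            "R": field.R.ravel(),
            "mask": field.mask.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)
    sidecar = {"nx": field.x.size, "nt": field.t.size}
    if params is not None:
        sidecar["params"] = params.to_dict()
    if meta:
        sidecar["meta"] = meta
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field(path) -> tuple[FieldGrid, dict]:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as e:  # pragma: no cover - pandas reports the line itself
        raise ValueError(f"malformed field CSV {path}: {e}") from e
    missing = {"x", "t", "R", "mask"} - set(df.columns)
    if missing:
        raise ValueError(f"field CSV {path} lacks columns {sorted(missing)}")
    x = np.unique(df["x"].to_numpy())
    t = np.unique(df["t"].to_numpy())
    R = df["R"].to_numpy().reshape(x.size, t.size)
    mask = df["mask"].to_numpy().astype(bool).reshape(x.size, t.size)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return FieldGrid(x=x, t=t, R=R, mask=mask), sidecar


def branch_to_dict(branch: SolutionBranch) -> dict:
    return {
        "family": branch.family,
        "sign": branch.sign,
        "variant": branch.variant,
        "coefficients": {k: expr_to_str(v) for k, v in branch.coefficients().items()},
        "omega_sq": expr_to_str(branch.omega_sq),
        "C_implied": expr_to_str(branch.C_implied),
        "s_of_lambda": expr_to_str(branch.s_of_lam()),
        "auxiliary": {
            "q": branch.ansatz.aux.q,
            "rhs": expr_to_str(branch.aux_rhs()),
        },
        "validity": "s(lambda(xi)) > 0",
    }


def write_branches(path, family: str):
    payload = {
        "family": family,
        "branches": [branch_to_dict(b) for b in solved_branches(family)],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return payload


def read_branch_exprs(path) -> list[dict]:
    """Parse a branch JSON back to sympy expressions."""
    payload = json.loads(Path(path).read_text())
    out = []
    for b in payload["branches"]:
        out.append(
            {
                "family": b["family"],
                "sign": b["sign"],
                "variant": b["variant"],
                "coefficients": {k: str_to_expr(v) for k, v in b["coefficients"].items()},
                "omega_sq": str_to_expr(b["omega_sq"]),
            }
        )
    return out


def write_spectrum(path, spec: MISpectrum):
    df = spec.to_frame()
    assert list(df.columns) == SPECTRUM_COLUMNS
    df.to_csv(path, index=False)


def read_spectrum(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != SPECTRUM_COLUMNS:
        raise ValueError(
            f"spectrum CSV must have columns {SPECTRUM_COLUMNS}, got {list(df.columns)}"
        )
    return df


def write_resolved_config(out_dir, config: dict, name: str = "resolved_config.json"):
    """Every run drops the fully resolved configuration next to its outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / name).write_text(json.dumps(config, indent=1, sort_keys=True))
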