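"""Versioned text (JSON) schemas for parameters, rotamer libraries and
training manifests; atomic writes.

Floats are serialized via Python's repr (shortest round-trip
representation), so load -> save -> load is bit-exact for IEEE doubles.
The loader validates the block structure (210 side-chain pair types with
62 spline coefficients each, 100 bead-backbone pairs with 54, one
environment curve per residue type) and raises ``SchemaError`` naming the
offending block on any mismatch; an unknown schema version is a hard
``UnsupportedVersionError``, never a silent reinterpretation.
"""

from __future__ import annotations

import json
import os
import tempfile

import numpy as np

from .core import AMINO_ACIDS
from .errors import SchemaError, UnsupportedVersionError
from .potentials import (
    BB_CUTOFF,
    BB_KNOTS,
    SC_CUTOFF,
    SC_KNOTS,
    EnvPotentialParams,
    HBondParams,
    PairPotentialParams,
    ParameterSet,
    RamaTable,
    bb_pair_keys,
    sc_pair_keys,
)

PARAM_SCHEMA_VERSION = 1

__all__ = [
    "save_parameters",
    "load_parameters",
    "save_rotamer_library",
    "load_rotamer_library",
    "atomic_write_text",
]


def atomic_write_text(path, text: str) -> None:
    """Write-temp-then-rename so readers never see partial files."""
    path = str(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _pair_to_dict(pp: PairPotentialParams) -> dict:
    return {
        "kappa": pp.kappa,
        "radial": pp.radial.coef.tolist(),
        "angular": pp.angular.coef.tolist(),
        "ang1": pp.ang1.coef.tolist(),
        "ang2": pp.ang2.coef.tolist(),
    }


def _pair_from_dict(d: dict, knots, cutoff, block: str) -> PairPotentialParams:
    pp = PairPotentialParams.zeros(knots, cutoff)
    expect = {
        "radial": knots[0], "angular": knots[1],
        "ang1": knots[2], "ang2": knots[3],
    }
    for name, kn in expect.items():
        if len(d[name]) != kn:
            raise SchemaError(
                f"{block}: curve {name!r} has {len(d[name])} coefficients, "
                f"expected {kn}"
            )
    pp.kappa = float(d["kappa"])
    pp.radial.coef = np.array(d["radial"], float)
    pp.angular.coef = np.array(d["angular"], float)
    pp.ang1.coef = np.array(d["ang1"], float)
    pp.ang2.coef = np.array(d["ang2"], float)
    return pp


def save_parameters(pset: ParameterSet, path) -> None:
    doc = {
        "schema": "cgfold-parameters",
        "version": PARAM_SCHEMA_VERSION,
        "layout": {
            "sc_knots": list(SC_KNOTS), "sc_cutoff": SC_CUTOFF,
            "bb_knots": list(BB_KNOTS), "bb_cutoff": BB_CUTOFF,
        },
        "sc_pairs": {
            f"{a}-{b}": _pair_to_dict(pp)
            for (a, b), pp in sorted(pset.sc_pairs.items())
        },
        "bb_pairs": {
            f"{s}-{a}": _pair_to_dict(pp)
            for (s, a), pp in sorted(pset.bb_pairs.items())
        },
        "env": {a: c.coef.tolist() for a, c in sorted(pset.env.curves.items())},
        "rama": {
            "sheet_bias": pset.rama.sheet_bias,
            "grids": {
                ctx: g.tolist() for ctx, g in sorted(pset.rama.grids.items())
            },
        },
        "hbond": {"magnitude": pset.hbond.magnitude},
    }
    atomic_write_text(path, json.dumps(doc, indent=1))


def load_parameters(path) -> ParameterSet:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != "cgfold-parameters":
        raise SchemaError("not a parameter file")
    if doc.get("version") != PARAM_SCHEMA_VERSION:
        raise UnsupportedVersionError(
            f"parameter schema version {doc.get('version')!r}; "
            f"this build reads version {PARAM_SCHEMA_VERSION}"
        )
    sc = {}
    want = {f"{a}-{b}" for a, b in sc_pair_keys()}
    got = set(doc["sc_pairs"])
    if got != want:
        raise SchemaError(
            f"sc_pairs: expected {len(want)} pair types, found {len(got)}"
        )
    for key, d in doc["sc_pairs"].items():
        a, b = key.split("-")
        sc[(a, b)] = _pair_from_dict(d, SC_KNOTS, SC_CUTOFF, f"sc_pairs[{key}]")
    bb = {}
    want = {f"{s}-{a}" for s, a in bb_pair_keys()}
    if set(doc["bb_pairs"]) != want:
        raise SchemaError(
            f"bb_pairs: expected {len(want)} site/residue pairs, "
            f"found {len(doc['bb_pairs'])}"
        )
    for key, d in doc["bb_pairs"].items():
        s, a = key.split("-")
        bb[(s, a)] = _pair_from_dict(d, BB_KNOTS, BB_CUTOFF, f"bb_pairs[{key}]")
    env = EnvPotentialParams.zeros()
    if set(doc["env"]) != set(AMINO_ACIDS):
        raise SchemaError("env: expected one curve per amino-acid type")
    for a, coefs in doc["env"].items():
        if len(coefs) != env.curves[a].n_coef:
            raise SchemaError(
                f"env[{a}]: {len(coefs)} coefficients, "
                f"expected {env.curves[a].n_coef}"
            )
        env.curves[a].coef = np.array(coefs, float)
    rama = RamaTable(
        grids={
            ctx: np.array(g, float) for ctx, g in doc["rama"]["grids"].items()
        },
        sheet_bias=float(doc["rama"]["sheet_bias"]),
    )
    if "general" not in rama.grids:
        raise SchemaError("rama: missing required 'general' context grid")
    ps = ParameterSet(
        sc_pairs=sc, bb_pairs=bb, env=env, rama=rama,
        hbond=HBondParams(magnitude=float(doc["hbond"]["magnitude"])),
    )
    return ps


def save_rotamer_library(library, path) -> None:
    atomic_write_text(path, json.dumps(library.to_dict(), indent=1))


def load_rotamer_library(path):
    from .sidechain import RotamerLibrary

    with open(path) as fh:
        return RotamerLibrary.from_dict(json.load(fh))
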