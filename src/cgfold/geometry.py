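"""Differentiable geometric primitives.

Every construction used to place derived coordinates (carbonyl O, amide H,
pseudo-Cbeta, side-chain bead frames) is built from a small set of
primitives -- vector differences, normalization, cross products -- each of
which carries an analytic Jacobian.  Forces on derived sites are pulled back
to the dynamical backbone atoms by composing these Jacobians (chain rule),
so the correctness of everything downstream rests on this module.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "skew",
    "dihedral",
    "dihedral_grad",
    "rotation_about_axis",
    "residue_frame",
]


def unit(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize ``v``; return the unit vector and its 3x3 Jacobian.

    d(v/|v|)/dv = (I - u u^T) / |v|
    """
    r = float(np.linalg.norm(v))
    if r < 1e-12:
        raise ZeroDivisionError("cannot normalize a near-zero vector")
    u = v / r
    J = (np.eye(3) - np.outer(u, u)) / r
    return u, J


def skew(v: np.ndarray) -> np.ndarray:
    """Matrix S(v) with S(v) @ w = v x w."""
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians, in (-pi, pi]) of four points."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m @ n2)
    return float(np.arctan2(y, x))


def dihedral_grad(p0, p1, p2, p3):
    """Dihedral angle and its gradient w.r.t. the four points.

    Differentiates phi = atan2(m.n2, n1.n2) (m = n1 x b2hat) directly via
    the chain rule in skew-matrix form; translation invariance (gradients
    summing to zero) follows from the construction.
    """
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    u, Ju = unit(b2)
    m = np.cross(n1, u)
    x = float(n1 @ n2)
    y = float(m @ n2)
    phi = float(np.arctan2(y, x))
    denom = x * x + y * y

    # Jacobians of b-vectors w.r.t. the four points (as +/- identity).
    db = {
        "b1": {0: -1.0, 1: 1.0},
        "b2": {1: -1.0, 2: 1.0},
        "b3": {2: -1.0, 3: 1.0},
    }
    S_b1, S_b2 = skew(b1), skew(b2)
    S_n1, S_u = skew(n1), skew(u)
    grads = []
    for a in range(4):
        # d n1 = d b1 x b2 + b1 x d b2 ; d n2 = d b2 x b3 + b2 x d b3
        Jn1 = db["b1"].get(a, 0.0) * (-S_b2) + db["b2"].get(a, 0.0) * S_b1
        Jn2 = db["b2"].get(a, 0.0) * (-skew(b3)) + db["b3"].get(a, 0.0) * S_b2
        Juv = db["b2"].get(a, 0.0) * Ju
        Jm = -S_u @ Jn1 + S_n1 @ Juv
        gx = Jn1.T @ n2 + Jn2.T @ n1
        gy = Jm.T @ n2 + Jn2.T @ m
        grads.append((x * gy - y * gx) / denom)
    return phi, tuple(grads)


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis by ``angle``."""
    u, _ = unit(axis)
    K = skew(u)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def residue_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Orthonormal frame attached to a residue's backbone triad.

    Columns of R: e_x along the in-plane bisector of the Ca->N and Ca->C
    bonds (flipped to point away from the backbone), e_z normal to the
    N-Ca-C plane, e_y completing the right-handed set.  Also returns the
    Jacobian dR[a, i, j, k] = d R[j, k] / d atom_a[i] for atoms (N, Ca, C).
    """
    b1, Jb1 = unit(ca - n)   # d b1/d ca = Jb1, d b1/d n = -Jb1
    b2, Jb2 = unit(ca - c)
    # e_x: bisector of b1 and b2
    ex, Jex = unit(b1 + b2)
    # e_z: plane normal
    cr = np.cross(b1, b2)
    ez, Jez = unit(cr)
    ey = np.cross(ez, ex)

    # chain rule: d b / d atoms
    db1 = {"n": -Jb1, "ca": Jb1, "c": np.zeros((3, 3))}
    db2 = {"n": np.zeros((3, 3)), "ca": Jb2, "c": -Jb2}
    dcr_db1 = -skew(b2)
    dcr_db2 = skew(b1)

    dR = np.zeros((3, 3, 3, 3))  # atom, input-xyz, row, col
    atoms = ("n", "ca", "c")
    for a, name in enumerate(atoms):
        dex = Jex @ (db1[name] + db2[name])
        dez = Jez @ (dcr_db1 @ db1[name] + dcr_db2 @ db2[name])
        # ey = ez x ex
        dey = -skew(ex) @ dez + skew(ez) @ dex
        for i in range(3):
            dR[a, i, :, 0] = dex[:, i]
            dR[a, i, :, 1] = dey[:, i]
            dR[a, i, :, 2] = dez[:, i]
    R = np.column_stack([ex, ey, ez])
    return R, dR
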