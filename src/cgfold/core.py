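"""Backbone topology, deterministic virtual sites, burial geometry, pullback.

The only dynamical degrees of freedom are the N, Ca, C atoms of each residue.
Everything else -- carbonyl O, amide H, a (pseudo-)Cbeta, residue-local
frames for side-chain beads, and the smooth burial count N_i -- is a
deterministic function of the backbone.  Each placement stores its Jacobian
with respect to its parent atoms so that gradients of any energy expressed
in derived coordinates can be pulled back to the backbone exactly (chain
rule / adjoint of the placement map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ChainBreakError, GeometryError, MissingAtomError
from .geometry import residue_frame, unit

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Ideal backbone geometry (A, degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.6
ANGLE_C_N_CA = 121.9

BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.530
# Cbeta direction in the residue frame: d = ct*e_x + st*e_z (L chirality).
_CB_CT = 0.61830
_CB_ST = float(np.sqrt(1.0 - _CB_CT**2))

N, CA, C = 0, 1, 2
ATOM_NAMES = ("N", "CA", "C")


@dataclass
class Sequence:
    """Amino-acid sequence using three-letter canonical codes."""

    residues: list[str]

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("sequence must have at least 2 residues")
        for i, r in enumerate(self.residues):
            if r not in AA_INDEX:
                raise ValueError(f"residue {i + 1}: unknown amino acid {r!r}")

    @classmethod
    def from_string(cls, s: str) -> "Sequence":
        return cls([ONE_TO_THREE[c.upper()] for c in s])

    def __len__(self):
        return len(self.residues)

    @property
    def indices(self) -> np.ndarray:
        return np.array([AA_INDEX[r] for r in self.residues])


@dataclass
class BackboneState:
    """Positions (n_res, 3, 3) of N/Ca/C and matching momenta."""

    sequence: Sequence
    positions: np.ndarray
    momenta: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.sequence)
        if self.positions.shape != (n, 3, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, 3, 3)"
            )
        if self.momenta is None:
            self.momenta = np.zeros_like(self.positions)
        else:
            self.momenta = np.asarray(self.momenta, dtype=float)

    @property
    def n_res(self) -> int:
        return len(self.sequence)

    def copy(self) -> "BackboneState":
        return BackboneState(
            self.sequence, self.positions.copy(), self.momenta.copy()
        )

    def flat_positions(self) -> np.ndarray:
        return self.positions.reshape(-1, 3)


def validate_backbone(state: BackboneState, tol: float = 0.20) -> None:
    """Check bonded distances are within ``tol`` (fraction) of ideal."""
    x = state.positions
    if not np.all(np.isfinite(x)):
        raise GeometryError("non-finite coordinates")
    d_nca = np.linalg.norm(x[:, CA] - x[:, N], axis=1)
    d_cac = np.linalg.norm(x[:, C] - x[:, CA], axis=1)
    d_cn = np.linalg.norm(x[1:, N] - x[:-1, C], axis=1)
    for d, ideal, name in (
        (d_nca, BOND_N_CA, "N-CA"),
        (d_cac, BOND_CA_C, "CA-C"),
        (d_cn, BOND_C_N, "C-N"),
    ):
        bad = np.abs(d - ideal) > tol * ideal
        if np.any(bad):
            i = int(np.argmax(bad))
            raise GeometryError(
                f"bond {name} of residue {i + 1} is {d[i]:.3f} A, outside "
                f"{100 * tol:.0f}% of ideal {ideal:.3f} A"
            )


def build_topology(sequence: Sequence, coords: dict) -> BackboneState:
    """Assemble a BackboneState from raw per-residue atom records.

    ``coords`` maps (residue_index_1based, atom_name) -> 3-vector; only
    N/CA/C entries are consulted.  Raises on missing atoms or chain breaks
    rather than silently reindexing.
    """
    n = len(sequence)
    pos = np.zeros((n, 3, 3))
    for i in range(n):
        for a, name in enumerate(ATOM_NAMES):
            key = (i + 1, name)
            if key not in coords:
                raise MissingAtomError(residue=i + 1, atom=name)
            pos[i, a] = np.asarray(coords[key], dtype=float)
    d_cn = np.linalg.norm(pos[1:, N] - pos[:-1, C], axis=1)
    for i, d in enumerate(d_cn):
        if d > 2.0:
            raise ChainBreakError(residue=i + 1, distance=float(d))
    return BackboneState(sequence, pos)


@dataclass
class DerivedFrame:
    """Deterministic derived coordinates and their placement Jacobians.

    ``jac[site]`` is a list over residues; each entry is a list of
    (flat_backbone_atom_index, 3x3 Jacobian d site / d atom).  ``R`` and
    ``dR`` hold the residue-local orthonormal frames used to place
    side-chain beads and the burial hemisphere axis.
    """

    O: np.ndarray          # (n, 3); last residue from an extrapolated frame
    H: np.ndarray          # (n, 3); row 0 is NaN (no preceding carbonyl)
    has_H: np.ndarray      # (n,) bool
    CB: np.ndarray         # (n, 3); pseudo-Cbeta for glycine too
    R: np.ndarray          # (n, 3, 3) residue frames
    dR: np.ndarray         # (n, 3 atoms, 3, 3, 3)
    jac: dict = field(default_factory=dict)
    burial: np.ndarray = None  # type: ignore[assignment]


def _flat(i: int, atom: int) -> int:
    return 3 * i + atom


def place_virtual_sites(state: BackboneState) -> DerivedFrame:
    """Place O, H, Cbeta and residue frames with analytic Jacobians.

    O lies in the peptide plane 1.231 A from C along the outward bisector
    of the Ca-C and N(i+1)-C bond directions (extrapolated pseudo-N(i+1)
    for the last residue).  H lies 1.010 A from N along the outward
    bisector of the Ca-N and C(i-1)-N directions; the first residue has no
    H.  Cbeta sits at the ideal tetrahedral position from the N/Ca/C triad
    (pseudo-Cbeta for glycine, used by the burial and environment terms).
    """
    x = state.positions
    n = state.n_res
    O = np.zeros((n, 3))
    H = np.full((n, 3), np.nan)
    has_H = np.zeros(n, dtype=bool)
    CB = np.zeros((n, 3))
    R = np.zeros((n, 3, 3))
    dR = np.zeros((n, 3, 3, 3, 3))
    jac = {"O": [], "H": [], "CB": []}

    for i in range(n):
        Ni, Cai, Ci = x[i, N], x[i, CA], x[i, C]
        try:
            Ri, dRi = residue_frame(Ni, Cai, Ci)
        except ZeroDivisionError as exc:
            raise GeometryError(f"degenerate backbone frame at residue {i + 1}") from exc
        if abs(np.linalg.det(Ri)) < 1e-6:
            raise GeometryError(f"colinear backbone triplet at residue {i + 1}")
        R[i], dR[i] = Ri, dRi

        # Cbeta from the residue frame.
        d_dir = _CB_CT * Ri[:, 0] + _CB_ST * Ri[:, 2]
        CB[i] = Cai + BOND_CA_CB * d_dir
        entries = []
        for a, atom in enumerate((N, CA, C)):
            J = BOND_CA_CB * (
                _CB_CT * dRi[a, :, :, 0].T + _CB_ST * dRi[a, :, :, 2].T
            )
            if atom == CA:
                J = J + np.eye(3)
            entries.append((_flat(i, atom), J))
        jac["CB"].append(entries)

        # Carbonyl O.
        if i + 1 < n:
            Nn = x[i + 1, N]
            u1, Ju1 = unit(Cai - Ci)
            u2, Ju2 = unit(Nn - Ci)
            w, Jw = unit(u1 + u2)
            O[i] = Ci - BOND_C_O * w
            jac["O"].append([
                (_flat(i, CA), -BOND_C_O * (Jw @ Ju1)),
                (_flat(i + 1, N), -BOND_C_O * (Jw @ Ju2)),
                (_flat(i, C), np.eye(3) + BOND_C_O * (Jw @ (Ju1 + Ju2))),
            ])
        else:
            # Extrapolated pseudo-N along the N->C direction.
            un, Jun = unit(Ci - Ni)
            Nn = Ci + BOND_C_N * un
            u1, Ju1 = unit(Cai - Ci)
            u2, Ju2 = unit(Nn - Ci)
            w, Jw = unit(u1 + u2)
            O[i] = Ci - BOND_C_O * w
            # dNn/dC = I + b*Jun ; dNn/dN = -b*Jun ; du2 = Ju2 @ (dNn - dC)
            dNn_dC = np.eye(3) + BOND_C_N * Jun
            dNn_dN = -BOND_C_N * Jun
            jac["O"].append([
                (_flat(i, CA), -BOND_C_O * (Jw @ Ju1)),
                (_flat(i, N), -BOND_C_O * (Jw @ (Ju2 @ dNn_dN))),
                (
                    _flat(i, C),
                    np.eye(3)
                    - BOND_C_O * (Jw @ (-Ju1 + Ju2 @ (dNn_dC - np.eye(3)))),
                ),
            ])

        # Amide H.
        if i > 0:
            Cp = x[i - 1, C]
            u1, Ju1 = unit(Cai - Ni)
            u2, Ju2 = unit(Cp - Ni)
            w, Jw = unit(u1 + u2)
            H[i] = Ni - BOND_N_H * w
            has_H[i] = True
            jac["H"].append([
                (_flat(i, CA), -BOND_N_H * (Jw @ Ju1)),
                (_flat(i - 1, C), -BOND_N_H * (Jw @ Ju2)),
                (_flat(i, N), np.eye(3) + BOND_N_H * (Jw @ (Ju1 + Ju2))),
            ])
        else:
            jac["H"].append([])

    frame = DerivedFrame(O=O, H=H, has_H=has_H, CB=CB, R=R, dR=dR, jac=jac)
    return frame


@dataclass
class BurialConfig:
    """Smooth hemisphere burial-count geometry (all config-exposed)."""

    radius: float = 7.0        # logistic radial switch center (A)
    radial_width: float = 1.0  # logistic width (A)
    cos_width: float = 0.2     # angular logistic width in cos(theta)

    def radial_switch(self, r):
        return 1.0 / (1.0 + np.exp((r - self.radius) / self.radial_width))

    def radial_switch_deriv(self, r):
        s = self.radial_switch(r)
        return -s * (1.0 - s) / self.radial_width

    def angular_switch(self, c):
        return 1.0 / (1.0 + np.exp(-c / self.cos_width))

    def angular_switch_deriv(self, c):
        s = self.angular_switch(c)
        return s * (1.0 - s) / self.cos_width


def burial_counts(
    state: BackboneState,
    frame: DerivedFrame,
    config: BurialConfig | None = None,
) -> np.ndarray:
    """Smooth count N_i of side chains in the hemisphere above each Cbeta."""
    Ni, _, _ = burial_counts_with_grad(state, frame, config)
    return Ni


def burial_counts_with_grad(
    state: BackboneState,
    frame: DerivedFrame,
    config: BurialConfig | None = None,
):
    """Burial counts plus dense gradients.

    Returns (N, dN_dCB, dN_dCA) where dN_dCB[i, j] = dN_i/dCB_j (n, n, 3)
    and dN_dCA[i] = dN_i/dCA_i (the hemisphere axis runs along Ca->Cbeta).
    Each neighbor j != i contributes sigma_r(|CB_j - CB_i|) *
    sigma_a(u_i . rhat_ij), a weight in (0, 1).
    """
    cfg = config or BurialConfig()
    n = state.n_res
    CB = frame.CB
    CAx = state.positions[:, CA]
    Nvals = np.zeros(n)
    dN_dCB = np.zeros((n, n, 3))
    dN_dCA = np.zeros((n, 3))
    for i in range(n):
        u, Ju = unit(CB[i] - CAx[i])
        for j in range(n):
            if j == i:
                continue
            d = CB[j] - CB[i]
            r = float(np.linalg.norm(d))
            if r < 1e-9:
                continue
            rhat = d / r
            c = float(u @ rhat)
            sr = float(cfg.radial_switch(r))
            sa = float(cfg.angular_switch(c))
            Nvals[i] += sr * sa
            dsr = float(cfg.radial_switch_deriv(r))
            dsa = float(cfg.angular_switch_deriv(c))
            # dr/dCB_j = rhat, d rhat/dCB_j = (I - rhat rhat^T)/r
            Jr = (np.eye(3) - np.outer(rhat, rhat)) / r
            dc_dCBj = Jr @ u
            g_j = dsr * sa * rhat + sr * dsa * dc_dCBj
            dN_dCB[i, j] += g_j
            # CB_i enters through -d and through u
            dc_dCBi = -dc_dCBj + Ju @ rhat
            dN_dCB[i, i] += -dsr * sa * rhat + sr * dsa * dc_dCBi
            dN_dCA[i] += sr * dsa * (-(Ju @ rhat))
    return Nvals, dN_dCB, dN_dCA


def pullback_gradients(frame: DerivedFrame, site_grads: dict) -> np.ndarray:
    """Map gradients on derived sites to gradients on backbone atoms.

    ``site_grads`` maps "O"/"H"/"CB" to (n, 3) arrays (NaN-safe: rows for
    absent sites are ignored).  Returns (n_res, 3, 3).  The operation is the
    exact adjoint of the placement maps and is linear in ``site_grads``.
    """
    n = frame.O.shape[0]
    out = np.zeros((n, 3, 3))
    flat = out.reshape(-1, 3)
    for site, grads in site_grads.items():
        entries = frame.jac[site]
        for i in range(n):
            g = grads[i]
            if not np.all(np.isfinite(g)):
                continue
            if not entries[i]:
                continue
            for idx, J in entries[i]:
                flat[idx] += J.T @ g
    return out
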