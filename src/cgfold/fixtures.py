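"""Synthetic inputs: idealized backbones, toy parameter sets, toy systems.

Everything any test or demo needs is generated here deterministically from
a seed -- idealized mini-proteins (helix, hairpin/strand, coil), random but
schema-valid parameter sets, a fixture rotamer library, and an exactly
solvable double-well toy used by the sampler and training tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .core import BackboneState, Sequence
from .geometry import dihedral, unit

__all__ = [
    "FixtureSpec",
    "make_backbone",
    "backbone_from_dihedrals",
    "make_toy_parameters",
    "make_two_basin_toy",
    "TwoBasinToy",
]

HELIX_PHI_PSI = (np.deg2rad(-57.0), np.deg2rad(-47.0))
STRAND_PHI_PSI = (np.deg2rad(-120.0), np.deg2rad(130.0))


@dataclass
class FixtureSpec:
    kind: str = "helix"          # helix | strand | coil | dipeptide
    n_res: int = 10
    sequence: str | None = None  # one-letter string; default poly-ALA
    seed: int = 0
    noise: float = 0.0           # Gaussian coordinate noise amplitude (A)


def _next_atom(p0, p1, p2, bond, angle, dih):
    """Place the next atom from three predecessors (internal coordinates)."""
    b2, _ = unit(p2 - p1)
    b1, _ = unit(p1 - p0)
    n, _ = unit(np.cross(b1, b2))
    m = np.cross(n, b2)
    d = (
        -np.cos(angle) * b2
        + np.sin(angle) * (np.cos(dih) * m - np.sin(dih) * n)
    )
    return p2 + bond * d


def backbone_from_dihedrals(
    sequence: Sequence, phi: np.ndarray, psi: np.ndarray
) -> BackboneState:
    """Build an ideal-geometry chain realizing the given (phi, psi) angles.

    phi[0] and psi[-1] are ignored (undefined at chain ends); omega is
    fixed at 180 degrees (trans peptide bonds).
    """
    n = len(sequence)
    a_ncac = np.deg2rad(core.ANGLE_N_CA_C)
    a_cacn = np.deg2rad(core.ANGLE_CA_C_N)
    a_cnca = np.deg2rad(core.ANGLE_C_N_CA)
    pos = np.zeros((n, 3, 3))
    pos[0, core.N] = (0.0, 0.0, 0.0)
    pos[0, core.CA] = (core.BOND_N_CA, 0.0, 0.0)
    pos[0, core.C] = pos[0, core.CA] + core.BOND_CA_C * np.array(
        [-np.cos(a_ncac), np.sin(a_ncac), 0.0]
    )
    for i in range(1, n):
        pos[i, core.N] = _next_atom(
            pos[i - 1, core.N], pos[i - 1, core.CA], pos[i - 1, core.C],
            core.BOND_C_N, a_cacn, psi[i - 1],
        )
        pos[i, core.CA] = _next_atom(
            pos[i - 1, core.CA], pos[i - 1, core.C], pos[i, core.N],
            core.BOND_N_CA, a_cnca, np.pi,
        )
        pos[i, core.C] = _next_atom(
            pos[i - 1, core.C], pos[i, core.N], pos[i, core.CA],
            core.BOND_CA_C, a_ncac, phi[i],
        )
    return BackboneState(sequence, pos)


def measure_phi_psi(state: BackboneState):
    """(phi, psi) arrays in radians; NaN where undefined (chain ends)."""
    x = state.positions
    n = state.n_res
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(n):
        if i > 0:
            phi[i] = dihedral(
                x[i - 1, core.C], x[i, core.N], x[i, core.CA], x[i, core.C]
            )
        if i + 1 < n:
            psi[i] = dihedral(
                x[i, core.N], x[i, core.CA], x[i, core.C], x[i + 1, core.N]
            )
    return phi, psi


def make_backbone(spec: FixtureSpec, rama_table=None) -> BackboneState:
    """Generate an idealized backbone for the requested fixture kind.

    ``coil`` draws per-residue (phi, psi) from ``rama_table`` (or uniformly
    at random if none is given).  Gaussian noise of amplitude ``spec.noise``
    is added to all coordinates afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        seq = Sequence.from_string(spec.sequence)
        if len(seq) != spec.n_res:
            raise ValueError("sequence length does not match n_res")
    else:
        seq = Sequence(["ALA"] * spec.n_res)
    n = spec.n_res
    if spec.kind == "helix":
        phi = np.full(n, HELIX_PHI_PSI[0])
        psi = np.full(n, HELIX_PHI_PSI[1])
    elif spec.kind == "strand":
        phi = np.full(n, STRAND_PHI_PSI[0])
        psi = np.full(n, STRAND_PHI_PSI[1])
    elif spec.kind in ("coil", "dipeptide"):
        if rama_table is not None:
            phi, psi = rama_table.sample_angles(seq, rng)
        else:
            phi = rng.uniform(-np.pi, np.pi, n)
            psi = rng.uniform(-np.pi, np.pi, n)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    state = backbone_from_dihedrals(seq, phi, psi)
    if spec.noise > 0:
        state.positions = state.positions + spec.noise * rng.standard_normal(
            state.positions.shape
        )
    return state


def make_toy_parameters(seed: int = 0, scale: float = 1.0):
    """Random, smooth, schema-valid ParameterSet (see potentials module)."""
    from .potentials import ParameterSet

    return ParameterSet.random(seed=seed, scale=scale)


@dataclass
class TwoBasinToy:
    """1-D double-well particle with a numerically exact Boltzmann reference.

    V(x) = barrier * (x^2 - 1)^2 + tilt * x.  The two basins sit near
    x = -1 and x = +1; ``tilt`` breaks the symmetry.  Partition-function
    quantities are computed by adaptive quadrature, which is exact for all
    practical purposes at these scales.
    """

    barrier: float = 2.0
    tilt: float = 0.0
    mass: float = 1.0

    def energy(self, x):
        return self.barrier * (np.asarray(x) ** 2 - 1.0) ** 2 + self.tilt * np.asarray(x)

    def force(self, x):
        return -(4.0 * self.barrier * np.asarray(x) * (np.asarray(x) ** 2 - 1.0) + self.tilt)

    def occupancies(self, T: float) -> tuple[float, float]:
        """Exact Boltzmann probability of (x < 0, x >= 0)."""
        from scipy.integrate import quad

        f = lambda x: np.exp(-self.energy(x) / T)
        left, _ = quad(f, -8.0, 0.0)
        right, _ = quad(f, 0.0, 8.0)
        z = left + right
        return left / z, right / z

    def mean_energy(self, T: float) -> float:
        from scipy.integrate import quad

        z, _ = quad(lambda x: np.exp(-self.energy(x) / T), -8.0, 8.0)
        ez, _ = quad(
            lambda x: self.energy(x) * np.exp(-self.energy(x) / T), -8.0, 8.0
        )
        return ez / z


def make_two_basin_toy(barrier: float = 2.0, tilt: float = 0.0) -> TwoBasinToy:
    return TwoBasinToy(barrier=barrier, tilt=tilt)
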