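"""Parameterized energy terms and their coordinate/parameter derivatives.

Terms
-----
* Oriented pair potential between side-chain beads (and between beads and
  the five backbone interaction sites H, O, N, Ca, C):

      V = kappa * ( V_radial(r12) + ang1(-n1.n12) ang2(n2.n12) V_angular(r12) )

  with all four curves cubic splines (see :mod:`cgfold.splines`); side-chain
  pairs use a 10 A cutoff, bead-backbone pairs 8 A.
* Environment (desolvation) term: per-residue curve of the smooth burial
  count N_i, summed over residues.
* Ramachandran term: periodic bicubic table per context class plus a single
  trainable scalar stabilizing the beta-sheet region.
* Backbone hydrogen bonding: distance/angle switching products between
  amide H donors and carbonyl O acceptors; only the magnitude is trainable.
* Steric repulsion among backbone N, Ca, Cbeta, C; fixed constants.
* Stiff bonded terms (bonds, angles, omega dihedral) keeping the three-atom
  backbone geometry near ideal; fixed, never trained.

Every term returns analytic coordinate gradients (validated against finite
differences in the test-suite) and exact parameter gradients (the spline
terms are linear in their coefficients).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import AMINO_ACIDS, BackboneState, DerivedFrame, BurialConfig
from .errors import DegenerateGeometryError
from .geometry import dihedral_grad, unit
from .splines import SplineCurve, smoothstep

# ---------------------------------------------------------------------------
# layout constants
# ---------------------------------------------------------------------------

SC_CUTOFF = 10.0
BB_CUTOFF = 8.0
SC_KNOTS = (16, 16, 15, 15)   # radial, angular, ang1, ang2  -> 62
BB_KNOTS = (14, 14, 13, 13)   # -> 54
ENV_KNOTS = 10
ENV_MAX = 12.0
BACKBONE_SITES = ("H", "O", "N", "CA", "C")

N_SC_PAIR_TYPES = 210         # 20 choose 2 + 20
N_BB_PAIR_TYPES = 100         # 5 sites x 20 residue types


def sc_pair_keys():
    keys = []
    for i, a in enumerate(AMINO_ACIDS):
        for b in AMINO_ACIDS[i:]:
            keys.append((a, b))
    return keys


def bb_pair_keys():
    return [(s, a) for s in BACKBONE_SITES for a in AMINO_ACIDS]


def canonical_sc_key(a: str, b: str):
    """Canonical unordered pair key and whether the roles were swapped."""
    if a <= b:
        return (a, b), False
    return (b, a), True


# ---------------------------------------------------------------------------
# pair potential
# ---------------------------------------------------------------------------


@dataclass
class PairPotentialParams:
    kappa: float
    radial: SplineCurve
    angular: SplineCurve
    ang1: SplineCurve
    ang2: SplineCurve
    cutoff: float

    @classmethod
    def zeros(cls, knots=SC_KNOTS, cutoff=SC_CUTOFF) -> "PairPotentialParams":
        kr, ka, k1, k2 = knots
        return cls(
            kappa=1.0,
            radial=SplineCurve.radial(np.zeros(kr), cutoff),
            angular=SplineCurve.radial(np.zeros(ka), cutoff),
            ang1=SplineCurve.open(np.zeros(k1), -1.0, 1.0),
            ang2=SplineCurve.open(np.zeros(k2), -1.0, 1.0),
            cutoff=cutoff,
        )

    @property
    def n_spline(self) -> int:
        return (
            self.radial.n_coef + self.angular.n_coef
            + self.ang1.n_coef + self.ang2.n_coef
        )

    @property
    def n_trainable(self) -> int:
        return 1 + self.n_spline  # kappa + splines

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [[self.kappa], self.radial.coef, self.angular.coef,
             self.ang1.coef, self.ang2.coef]
        )

    def unpack(self, v: np.ndarray) -> None:
        kr, ka = self.radial.n_coef, self.angular.n_coef
        k1 = self.ang1.n_coef
        self.kappa = float(v[0])
        o = 1
        self.radial.coef = np.asarray(v[o:o + kr]); o += kr
        self.angular.coef = np.asarray(v[o:o + ka]); o += ka
        self.ang1.coef = np.asarray(v[o:o + k1]); o += k1
        self.ang2.coef = np.asarray(v[o:])


def pair_energy_batch(params: PairPotentialParams, y1, n1, y2, n2):
    """Vectorized oriented pair energy for m interacting pairs.

    Returns (V (m,), grads dict with dy1/dn1/dy2/dn2 (m,3), dparam (m, P))
    where P = params.n_trainable, ordered [kappa, radial, angular, ang1,
    ang2].  Beyond the cutoff V and all gradients are identically zero.
    """
    y1 = np.atleast_2d(y1); y2 = np.atleast_2d(y2)
    n1 = np.atleast_2d(n1); n2 = np.atleast_2d(n2)
    d = y1 - y2
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-9):
        raise DegenerateGeometryError("coincident interaction sites")
    n12 = d / r[:, None]
    a1 = -np.sum(n1 * n12, axis=1)
    a2 = np.sum(n2 * n12, axis=1)

    vr, dvr = params.radial.evaluate(r)
    va, dva = params.angular.evaluate(r)
    A1, dA1 = params.ang1.evaluate(a1)
    A2, dA2 = params.ang2.evaluate(a2)
    kap = params.kappa

    bracket = vr + A1 * A2 * va
    V = kap * bracket

    # coordinate gradients
    dV_dr = kap * (dvr + A1 * A2 * dva)
    dV_da1 = kap * dA1 * A2 * va
    dV_da2 = kap * A1 * dA2 * va
    m = len(r)
    # d a1/d y1 = -(P n1)/r with P = I - n12 n12^T ; d a2/d y1 = (P n2)/r
    Pn1 = n1 - np.sum(n1 * n12, axis=1)[:, None] * n12
    Pn2 = n2 - np.sum(n2 * n12, axis=1)[:, None] * n12
    dy1 = (
        dV_dr[:, None] * n12
        + dV_da1[:, None] * (-Pn1 / r[:, None])
        + dV_da2[:, None] * (Pn2 / r[:, None])
    )
    dy2 = -dy1
    dn1 = dV_da1[:, None] * (-n12)
    dn2 = dV_da2[:, None] * n12

    # parameter gradients (exact: linear in spline coefficients)
    P = params.n_trainable
    dparam = np.zeros((m, P))
    dparam[:, 0] = bracket
    o = 1
    for curve, x, fac in (
        (params.radial, r, np.ones(m)),
        (params.angular, r, A1 * A2),
        (params.ang1, a1, A2 * va),
        (params.ang2, a2, A1 * va),
    ):
        k, w = curve.basis(x)
        rows = np.repeat(np.arange(m), 4)
        cols = k.ravel()
        vals = (kap * fac[:, None] * w).ravel()
        good = cols >= 0
        np.add.at(dparam, (rows[good], o + cols[good]), vals[good])
        o += curve.n_coef
    grads = {"dy1": dy1, "dn1": dn1, "dy2": dy2, "dn2": dn2}
    return V, grads, dparam


def eval_pair(params: PairPotentialParams, y1, n1, y2, n2):
    """Single-pair convenience wrapper around :func:`pair_energy_batch`."""
    V, g, dp = pair_energy_batch(
        params, y1[None], n1[None], y2[None], n2[None]
    )
    return float(V[0]), {k: v[0] for k, v in g.items()}, dp[0]


# ---------------------------------------------------------------------------
# environment potential
# ---------------------------------------------------------------------------


@dataclass
class EnvPotentialParams:
    curves: dict  # aa -> SplineCurve (kind "open" on [0, ENV_MAX])

    @classmethod
    def zeros(cls) -> "EnvPotentialParams":
        return cls({
            a: SplineCurve.open(np.zeros(ENV_KNOTS), 0.0, ENV_MAX)
            for a in AMINO_ACIDS
        })

    @property
    def n_trainable(self) -> int:
        return sum(c.n_coef for c in self.curves.values())


def eval_env(params: EnvPotentialParams, burial: np.ndarray, sequence):
    """Sum of per-residue environment-curve values at the burial counts.

    Returns (E, dE_dN (n,), basis list of (aa, idx, w) per residue).
    """
    E = 0.0
    n = len(sequence)
    dE_dN = np.zeros(n)
    basis = []
    for i, aa in enumerate(sequence.residues):
        c = params.curves[aa]
        f, df = c.evaluate(burial[i])
        E += float(f)
        dE_dN[i] = float(df)
        k, w = c.basis(burial[i])
        basis.append((aa, k[0], w[0]))
    return E, dE_dN, basis


# ---------------------------------------------------------------------------
# Ramachandran term
# ---------------------------------------------------------------------------


def _b3_scalar(s):
    a = np.abs(s)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m1] = (4 - 6 * a[m1] ** 2 + 3 * a[m1] ** 3) / 6
    out[m2] = (2 - a[m2]) ** 3 / 6
    return out


def _b3p_scalar(s):
    a = np.abs(s)
    sg = np.sign(s)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    out[m1] = sg[m1] * (-12 * a[m1] + 9 * a[m1] ** 2) / 6
    out[m2] = -sg[m2] * (2 - a[m2]) ** 2 / 2
    return out


BETA_CENTER = (np.deg2rad(-120.0), np.deg2rad(130.0))
BETA_WIDTH = np.deg2rad(40.0)


@dataclass
class RamaTable:
    """Periodic bicubic energy tables keyed by residue context.

    ``grids[ctx]`` holds B-spline coefficients on a uniform periodic
    (phi, psi) grid; the interpolant is C1 and exactly 2*pi-periodic in
    both angles.  ``sheet_bias`` is the single trainable scalar multiplying
    a smooth periodic bump over the beta-sheet region.
    """

    grids: dict            # ctx -> (ng, ng) array
    sheet_bias: float = 0.0
    _kb: float = field(default=1.0 / BETA_WIDTH**2, repr=False)

    def context_of(self, sequence, i: int) -> str:
        if i + 1 < len(sequence) and sequence.residues[i + 1] == "PRO":
            ctx = "prepro"
        elif sequence.residues[i] == "GLY":
            ctx = "glycine"
        else:
            ctx = "general"
        return ctx if ctx in self.grids else "general"

    def beta_bump(self, phi, psi):
        p0, s0 = BETA_CENTER
        g = np.exp(
            self._kb * (np.cos(phi - p0) - 1.0)
            + self._kb * (np.cos(psi - s0) - 1.0)
        )
        dgp = g * (-self._kb * np.sin(phi - p0))
        dgs = g * (-self._kb * np.sin(psi - s0))
        return g, dgp, dgs

    def evaluate(self, phi: float, psi: float, context: str = "general"):
        """Energy and (dE/dphi, dE/dpsi, dE/dbias) at wrapped angles."""
        grid = self.grids.get(context, self.grids["general"])
        ng = grid.shape[0]
        h = 2.0 * np.pi / ng
        up = (phi + np.pi) / h
        us = (psi + np.pi) / h
        jp = int(np.floor(up))
        js = int(np.floor(us))
        offs = np.arange(-1, 3)
        cp = jp + offs
        cs = js + offs
        wp_ = _b3_scalar(up - cp)
        wpd = _b3p_scalar(up - cp) / h
        ws_ = _b3_scalar(us - cs)
        wsd = _b3p_scalar(us - cs) / h
        patch = grid[np.ix_(cp % ng, cs % ng)]
        E = float(wp_ @ patch @ ws_)
        dEp = float(wpd @ patch @ ws_)
        dEs = float(wp_ @ patch @ wsd)
        g, dgp, dgs = self.beta_bump(phi, psi)
        E += self.sheet_bias * float(g)
        dEp += self.sheet_bias * float(dgp)
        dEs += self.sheet_bias * float(dgs)
        return E, dEp, dEs, float(g)

    def sample_angles(self, sequence, rng, temperature: float = 1.0):
        """Draw per-residue (phi, psi) from the table's Boltzmann weights."""
        ng = 72
        h = 2.0 * np.pi / ng
        centers = -np.pi + h * (np.arange(ng) + 0.5)
        n = len(sequence)
        phi = np.zeros(n)
        psi = np.zeros(n)
        cache = {}
        for i in range(n):
            ctx = self.context_of(sequence, i)
            if ctx not in cache:
                E = np.array(
                    [[self.evaluate(p, s, ctx)[0] for s in centers]
                     for p in centers]
                )
                w = np.exp(-(E - E.min()) / temperature).ravel()
                cache[ctx] = w / w.sum()
            idx = rng.choice(ng * ng, p=cache[ctx])
            phi[i] = centers[idx // ng] + rng.uniform(-h / 2, h / 2)
            psi[i] = centers[idx % ng] + rng.uniform(-h / 2, h / 2)
        return phi, psi


def _vonmises_bump(P, S, p0, s0, kappa):
    return np.exp(
        kappa * (np.cos(P - p0) - 1.0) + kappa * (np.cos(S - s0) - 1.0)
    )


def default_rama_table(ng: int = 24, sheet_bias: float = 0.0) -> RamaTable:
    """Bundled smooth Ramachandran table (synthetic, built programmatically).

    Energies are negative-log mixtures of von Mises bumps over the alpha,
    beta and left-handed-alpha basins; glycine gets a symmetrized map and
    pre-proline a beta-shifted one.  This is a stand-in statistical table
    for demonstrations and fixtures, not a PDB-derived library; the file
    format supports loading arbitrary context-keyed tables.
    """
    h = 2 * np.pi / ng
    grid = -np.pi + h * np.arange(ng)
    P, S = np.meshgrid(grid, grid, indexing="ij")
    d = np.deg2rad

    def nlog(mix):
        return -np.log(mix + 1e-3)

    general = nlog(
        1.0 * _vonmises_bump(P, S, d(-63), d(-43), 4.0)
        + 0.9 * _vonmises_bump(P, S, d(-120), d(130), 3.0)
        + 0.15 * _vonmises_bump(P, S, d(60), d(45), 5.0)
    )
    glycine = nlog(
        0.6 * _vonmises_bump(P, S, d(-80), d(70), 3.0)
        + 0.6 * _vonmises_bump(P, S, d(80), d(-70), 3.0)
        + 0.4 * _vonmises_bump(P, S, d(-100), d(150), 3.0)
        + 0.4 * _vonmises_bump(P, S, d(100), d(-150), 3.0)
    )
    prepro = nlog(
        1.0 * _vonmises_bump(P, S, d(-120), d(130), 3.0)
        + 0.5 * _vonmises_bump(P, S, d(-63), d(-43), 4.0)
    )
    grids = {"general": general, "glycine": glycine, "prepro": prepro}
    for g in grids.values():
        g -= g.min()
    return RamaTable(grids=grids, sheet_bias=sheet_bias)


def eval_rama(table: RamaTable, state: BackboneState):
    """Total Ramachandran energy with backbone gradients.

    Returns (E, grad (n,3,3), dE_dbias).
    """
    from .fixtures import measure_phi_psi  # angle measurement helper

    x = state.positions
    n = state.n_res
    E = 0.0
    grad = np.zeros((n, 3, 3))
    dbias = 0.0
    for i in range(n):
        if i == 0 or i + 1 == n:
            continue  # phi or psi undefined at chain ends
        phi, gphi = dihedral_grad(
            x[i - 1, core.C], x[i, core.N], x[i, core.CA], x[i, core.C]
        )
        psi, gpsi = dihedral_grad(
            x[i, core.N], x[i, core.CA], x[i, core.C], x[i + 1, core.N]
        )
        ctx = table.context_of(state.sequence, i)
        e, dEp, dEs, bump = table.evaluate(phi, psi, ctx)
        E += e
        dbias += bump
        for g, (ri, ai) in zip(
            gphi,
            ((i - 1, core.C), (i, core.N), (i, core.CA), (i, core.C)),
        ):
            grad[ri, ai] += dEp * g
        for g, (ri, ai) in zip(
            gpsi,
            ((i, core.N), (i, core.CA), (i, core.C), (i + 1, core.N)),
        ):
            grad[ri, ai] += dEs * g
    return E, grad, dbias


# ---------------------------------------------------------------------------
# hydrogen bonding
# ---------------------------------------------------------------------------


@dataclass
class HBondParams:
    magnitude: float = 0.0     # trainable; favorable when negative
    dist_on: float = 2.0       # A: score 1 below this H..O distance
    dist_off: float = 3.0      # A: score exactly 0 beyond
    cos_lo: float = 0.5        # angular switches rise from cos_lo to cos_hi
    cos_hi: float = 1.0
    min_separation: int = 2    # |i-j| >= 2 in sequence


def eval_hbond(params: HBondParams, state: BackboneState, frame: DerivedFrame):
    """Backbone-backbone hydrogen bonds between amide H and carbonyl O.

    Each (donor i, acceptor j) pair with |i-j| >= min_separation contributes
    magnitude * s_dist(r_HO) * s_ang(donor alignment) * s_ang(acceptor
    alignment); the product of switches is the pair's score in [0, 1].
    Returns (E, accumulator contributions, scores dict (i, j)->score,
    dE_dmagnitude).
    """
    n = state.n_res
    x = state.positions
    E = 0.0
    dmag = 0.0
    scores = {}
    bb = np.zeros((n, 3, 3))
    site = {"O": np.zeros((n, 3)), "H": np.zeros((n, 3))}
    for i in range(n):
        if not frame.has_H[i]:
            continue
        Hp = frame.H[i]
        Np = x[i, core.N]
        for j in range(n):
            if abs(i - j) < params.min_separation:
                continue
            Op = frame.O[j]
            Cp = x[j, core.C]
            dv = Op - Hp
            r = float(np.linalg.norm(dv))
            if r >= params.dist_off:
                continue
            uHO = dv / r
            uNH, JNH = unit(Hp - Np)
            uCO, JCO = unit(Op - Cp)
            cD = float(uNH @ uHO)
            cA = float(-uCO @ uHO)
            sd, dsd = smoothstep(r, params.dist_on, params.dist_off)
            sd, dsd = 1.0 - float(sd), -float(dsd)
            sD, dsD = smoothstep(cD, params.cos_lo, params.cos_hi)
            sA, dsA = smoothstep(cA, params.cos_lo, params.cos_hi)
            sD, dsD, sA, dsA = float(sD), float(dsD), float(sA), float(dsA)
            score = sd * sD * sA
            if score > 1e-12:
                scores[(i, j)] = score
            E += params.magnitude * score
            dmag += score
            mag = params.magnitude
            # gradients
            Jr = (np.eye(3) - np.outer(uHO, uHO)) / r
            # r depends on O_j (+uHO) and H_i (-uHO)
            gO = mag * dsd * sD * sA * uHO
            gH = -gO.copy()
            # cD = uNH . uHO
            gO = gO + mag * sd * dsD * sA * (Jr @ uNH)
            gH = gH + mag * sd * dsD * sA * (-(Jr @ uNH) + JNH @ uHO)
            gN = mag * sd * dsD * sA * (-(JNH @ uHO))
            # cA = -uCO . uHO
            gO = gO + mag * sd * sD * dsA * (-(Jr @ uCO) - JCO @ uHO)
            gH = gH + mag * sd * sD * dsA * (Jr @ uCO)
            gC = mag * sd * sD * dsA * (JCO @ uHO)
            site["O"][j] += gO
            site["H"][i] += gH
            bb[i, core.N] += gN
            bb[j, core.C] += gC
    return E, bb, site, scores, dmag



# ---------------------------------------------------------------------------
# sterics
# ---------------------------------------------------------------------------


@dataclass
class StericParams:
    radius: float = 3.2      # contact distance incl. switching width (A)
    strength: float = 10.0   # energy units at full overlap
    min_separation: int = 2  # residue separation


def eval_steric(
    state: BackboneState, frame: DerivedFrame,
    params: StericParams | None = None,
):
    """Smooth repulsion E = strength*(1 - r/radius)^3 among N, Ca, Cb, C.

    Pairs within the same or adjacent residues are excluded (bonded terms
    own that geometry).  Returns (E, backbone grad, CB site grad).
    """
    p = params or StericParams()
    n = state.n_res
    x = state.positions
    sites = []  # (res, kind, pos); kind: 0..2 backbone atom index, 3 = CB
    for i in range(n):
        for a in (core.N, core.CA, core.C):
            sites.append((i, a, x[i, a]))
        sites.append((i, 3, frame.CB[i]))
    E = 0.0
    bb = np.zeros((n, 3, 3))
    cb = np.zeros((n, 3))
    rc = p.radius
    for ii in range(len(sites)):
        i, ai, pi = sites[ii]
        for jj in range(ii + 1, len(sites)):
            j, aj, pj = sites[jj]
            if abs(i - j) < p.min_separation:
                continue
            d = pi - pj
            r = float(np.linalg.norm(d))
            if r >= rc:
                continue
            t = 1.0 - r / rc
            E += p.strength * t**3
            dEdr = -3.0 * p.strength * t**2 / rc
            g = dEdr * d / r
            if ai == 3:
                cb[i] += g
            else:
                bb[i, ai] += g
            if aj == 3:
                cb[j] -= g
            else:
                bb[j, aj] -= g
    return E, bb, cb


# ---------------------------------------------------------------------------
# bonded terms (fixed, not trainable)
# ---------------------------------------------------------------------------


@dataclass
class BondedParams:
    k_bond: float = 100.0    # energy / A^2
    k_angle: float = 50.0    # energy / rad^2
    k_omega: float = 20.0    # energy / rad^2


def _angle_grad(a, b, c):
    """Angle a-b-c and gradients w.r.t. the three points."""
    u = a - b
    v = c - b
    ru = np.linalg.norm(u)
    rv = np.linalg.norm(v)
    uh = u / ru
    vh = v / rv
    ct = float(np.clip(uh @ vh, -1.0, 1.0))
    st = np.sqrt(max(1.0 - ct * ct, 1e-12))
    th = np.arccos(ct)
    ga = -(vh - ct * uh) / (ru * st)
    gc = -(uh - ct * vh) / (rv * st)
    gb = -(ga + gc)
    return th, ga, gb, gc


def eval_bonded(state: BackboneState, params: BondedParams | None = None):
    """Stiff harmonic bonds/angles and omega dihedral restraint."""
    p = params or BondedParams()
    x = state.positions
    n = state.n_res
    E = 0.0
    grad = np.zeros((n, 3, 3))

    def bond(i1, a1, i2, a2, r0):
        nonlocal E
        d = x[i1, a1] - x[i2, a2]
        r = float(np.linalg.norm(d))
        E += p.k_bond * (r - r0) ** 2
        g = 2.0 * p.k_bond * (r - r0) * d / r
        grad[i1, a1] += g
        grad[i2, a2] -= g

    def angle(pts, th0):
        nonlocal E
        th, ga, gb, gc = _angle_grad(x[pts[0]], x[pts[1]], x[pts[2]])
        dth = th - np.deg2rad(th0)
        E += p.k_angle * dth**2
        for g, pt in zip((ga, gb, gc), pts):
            grad[pt] += 2.0 * p.k_angle * dth * g

    for i in range(n):
        bond(i, core.CA, i, core.N, core.BOND_N_CA)
        bond(i, core.C, i, core.CA, core.BOND_CA_C)
        if i + 1 < n:
            bond(i + 1, core.N, i, core.C, core.BOND_C_N)
        angle(((i, core.N), (i, core.CA), (i, core.C)), core.ANGLE_N_CA_C)
        if i + 1 < n:
            angle(((i, core.CA), (i, core.C), (i + 1, core.N)),
                  core.ANGLE_CA_C_N)
            angle(((i, core.C), (i + 1, core.N), (i + 1, core.CA)),
                  core.ANGLE_C_N_CA)
            om, gs = dihedral_grad(
                x[i, core.CA], x[i, core.C], x[i + 1, core.N],
                x[i + 1, core.CA],
            )
            dom = np.arctan2(np.sin(om - np.pi), np.cos(om - np.pi))
            E += p.k_omega * dom**2
            for g, pt in zip(gs, ((i, core.CA), (i, core.C),
                                  (i + 1, core.N), (i + 1, core.CA))):
                grad[pt] += 2.0 * p.k_omega * dom * g
    return E, grad


# ---------------------------------------------------------------------------
# the full trainable parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """All model parameters; the trainable ones flatten to the vector alpha.

    Alpha ordering (stable, documented, used by the parameter files and the
    trainer):

    1. side-chain pairs, keys sorted alphabetically as (a, b) with a <= b:
       [kappa, radial, angular, ang1, ang2] per pair (63 values);
    2. bead-backbone pairs, sites in order (H, O, N, CA, C), residue types
       alphabetical: same layout (55 values);
    3. environment curves, residue types alphabetical (10 values each);
    4. Ramachandran sheet bias (1);
    5. hydrogen-bond magnitude (1).

    Non-trainable constants (Rama grids, H-bond geometry, sterics, bonded
    spring constants, burial geometry) live alongside but are never touched
    by training.
    """

    sc_pairs: dict                    # (a, b) -> PairPotentialParams
    bb_pairs: dict                    # (site, a) -> PairPotentialParams
    env: EnvPotentialParams
    rama: RamaTable
    hbond: HBondParams
    steric: StericParams = field(default_factory=StericParams)
    bonded: BondedParams = field(default_factory=BondedParams)
    burial: BurialConfig = field(default_factory=BurialConfig)

    @classmethod
    def zeros(cls) -> "ParameterSet":
        return cls(
            sc_pairs={k: PairPotentialParams.zeros(SC_KNOTS, SC_CUTOFF)
                      for k in sc_pair_keys()},
            bb_pairs={k: PairPotentialParams.zeros(BB_KNOTS, BB_CUTOFF)
                      for k in bb_pair_keys()},
            env=EnvPotentialParams.zeros(),
            rama=RamaTable(
                grids={"general": np.zeros((24, 24))}, sheet_bias=0.0
            ),
            hbond=HBondParams(magnitude=0.0),
        )

    @classmethod
    def random(cls, seed: int = 0, scale: float = 1.0) -> "ParameterSet":
        """Smooth random trainable blocks (fixture/demo parameters)."""
        rng = np.random.default_rng(seed)

        def smooth(kn):
            c = rng.standard_normal(kn)
            k = np.array([0.25, 0.5, 0.25])
            return scale * np.convolve(c, k, mode="same")

        ps = cls.zeros()
        for pp in list(ps.sc_pairs.values()) + list(ps.bb_pairs.values()):
            pp.radial.coef = smooth(pp.radial.n_coef)
            pp.angular.coef = smooth(pp.angular.n_coef)
            pp.ang1.coef = smooth(pp.ang1.n_coef)
            pp.ang2.coef = smooth(pp.ang2.n_coef)
        for c in ps.env.curves.values():
            c.coef = smooth(c.n_coef)
        if scale > 0:
            ps.rama = default_rama_table(sheet_bias=-0.1 * scale)
        ps.hbond.magnitude = -2.0 * scale
        return ps

    @classmethod
    def demo(cls) -> "ParameterSet":
        """A physically-flavored demonstration parameter set.

        Not a trained force field: mildly attractive bead-bead wells, the
        bundled Ramachandran table, and hydrogen bonding strong enough to
        hold secondary structure in short simulations.
        """
        ps = cls.zeros()
        for pp in ps.sc_pairs.values():
            r = np.linspace(0, SC_CUTOFF, pp.radial.n_coef)
            pp.radial.coef = 2.0 * np.exp(-((r - 2.0) / 1.0) ** 2) - \
                0.5 * np.exp(-((r - 5.5) / 1.5) ** 2)
        ps.rama = default_rama_table(sheet_bias=-0.3)
        ps.hbond.magnitude = -3.0
        return ps

    # -- alpha vector ------------------------------------------------------

    def _blocks(self):
        for k in sorted(self.sc_pairs):
            yield ("sc", k)
        for k in bb_pair_keys():
            yield ("bb", k)
        for a in AMINO_ACIDS:
            yield ("env", a)
        yield ("rama_bias", None)
        yield ("hbond_mag", None)

    def block_sizes(self):
        sizes = {}
        for kind, key in self._blocks():
            if kind == "sc":
                sizes[(kind, key)] = self.sc_pairs[key].n_trainable
            elif kind == "bb":
                sizes[(kind, key)] = self.bb_pairs[key].n_trainable
            elif kind == "env":
                sizes[(kind, key)] = self.env.curves[key].n_coef
            else:
                sizes[(kind, key)] = 1
        return sizes

    def block_offsets(self):
        offs = {}
        o = 0
        for bk, size in self.block_sizes().items():
            offs[bk] = o
            o += size
        return offs, o

    @property
    def n_alpha(self) -> int:
        return self.block_offsets()[1]

    def to_vector(self) -> np.ndarray:
        parts = []
        for kind, key in self._blocks():
            if kind == "sc":
                parts.append(self.sc_pairs[key].pack())
            elif kind == "bb":
                parts.append(self.bb_pairs[key].pack())
            elif kind == "env":
                parts.append(self.env.curves[key].coef)
            elif kind == "rama_bias":
                parts.append(np.array([self.rama.sheet_bias]))
            else:
                parts.append(np.array([self.hbond.magnitude]))
        return np.concatenate(parts)

    def from_vector(self, v: np.ndarray) -> None:
        offs, total = self.block_offsets()
        if len(v) != total:
            from .errors import ParameterMismatchError

            raise ParameterMismatchError(
                f"alpha length {len(v)} != expected {total}"
            )
        sizes = self.block_sizes()
        for bk, o in offs.items():
            kind, key = bk
            chunk = v[o:o + sizes[bk]]
            if kind == "sc":
                self.sc_pairs[key].unpack(chunk)
            elif kind == "bb":
                self.bb_pairs[key].unpack(chunk)
            elif kind == "env":
                self.env.curves[key].coef = np.asarray(chunk, dtype=float)
            elif kind == "rama_bias":
                self.rama.sheet_bias = float(chunk[0])
            else:
                self.hbond.magnitude = float(chunk[0])


def count_parameters(pset: ParameterSet) -> dict:
    """Parameter bookkeeping by block (spline coefficients per the model
    definition; per-pair scale factors and the two scalars under
    ``scalars``)."""
    sc_spline = sum(p.n_spline for p in pset.sc_pairs.values())
    bb_spline = sum(p.n_spline for p in pset.bb_pairs.values())
    env = pset.env.n_trainable
    scalars = 2 + len(pset.sc_pairs) + len(pset.bb_pairs)
    return {
        "sc_pair_types": len(pset.sc_pairs),
        "sc_pair_params": sc_spline,
        "bb_pair_params": bb_spline,
        "env_params": env,
        "scalars": scalars,
    }


# ---------------------------------------------------------------------------
# composed backbone-level energy
# ---------------------------------------------------------------------------


def total_energy(
    state: BackboneState,
    frame: DerivedFrame,
    pset: ParameterSet,
    sidechain: "object | None" = None,
    include_env: bool = True,
):
    """Sum all energy terms; assemble coordinate and parameter gradients.

    ``sidechain`` is an optional object with attributes ``free_energy``,
    ``backbone_grad`` (n,3,3) and ``param_grad`` (n_alpha,) -- the converged
    belief-propagation result from :mod:`cgfold.sidechain`.  Returns
    (E, grad (n,3,3), param_grad (n_alpha,), terms dict).
    """
    from .core import burial_counts_with_grad, pullback_gradients

    n = state.n_res
    offs, n_alpha = pset.block_offsets()
    pgrad = np.zeros(n_alpha)
    terms = {}

    e_bond, g_bond = eval_bonded(state, pset.bonded)
    terms["bonded"] = e_bond

    e_st, g_st_bb, g_st_cb = eval_steric(state, frame, pset.steric)
    terms["steric"] = e_st

    e_rama, g_rama, dbias = eval_rama(pset.rama, state)
    terms["rama"] = e_rama
    pgrad[offs[("rama_bias", None)]] += dbias

    e_hb, g_hb_bb, hb_sites, _, dmag = eval_hbond(pset.hbond, state, frame)
    terms["hbond"] = e_hb
    pgrad[offs[("hbond_mag", None)]] += dmag

    if include_env:
        burial, dN_dCB, dN_dCA = burial_counts_with_grad(
            state, frame, pset.burial
        )
        frame.burial = burial
        e_env, dE_dN, env_basis = eval_env(pset.env, burial, state.sequence)
        terms["env"] = e_env
        g_env_cb = np.einsum("i,ijk->jk", dE_dN, dN_dCB)
        g_env_ca = dE_dN[:, None] * dN_dCA
        for i, (aa, k, w) in enumerate(env_basis):
            o = offs[("env", aa)]
            good = k >= 0
            np.add.at(pgrad, o + k[good], w[good])
    else:
        e_env = 0.0
        g_env_cb = np.zeros((n, 3))
        g_env_ca = np.zeros((n, 3))

    site_grads = {
        "O": hb_sites["O"],
        "H": hb_sites["H"],
        "CB": g_st_cb + g_env_cb,
    }
    grad = g_bond + g_st_bb + g_rama + g_hb_bb
    grad[:, core.CA] += g_env_ca
    grad += pullback_gradients(frame, site_grads)

    E = e_bond + e_st + e_rama + e_hb + e_env

    if sidechain is not None:
        E += sidechain.free_energy
        terms["sidechain"] = sidechain.free_energy
        grad = grad + sidechain.backbone_grad
        pgrad = pgrad + sidechain.param_grad

    return E, grad, pgrad, terms
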