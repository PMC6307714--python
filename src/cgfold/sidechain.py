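"""Discrete side-chain packing by belief propagation.

Each residue's side chain is a single oriented bead with up to six discrete
states (position + unit orientation in the residue's backbone frame, with a
prior weight from the rotamer library).  At every force evaluation the
joint Boltzmann distribution over all side-chain states is approximated by
sum-product belief propagation on the pairwise interaction graph; the Bethe
free energy of the converged beliefs is the side-chain contribution to the
total energy, and its derivatives (exact at the BP fixed point, where the
Bethe functional is stationary in the beliefs) give the forces pulled back
onto the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import BackboneState, DerivedFrame
from .geometry import unit
from .potentials import (
    ParameterSet,
    canonical_sc_key,
    pair_energy_batch,
)

def _lse(a, axis=None):
    """Minimal log-sum-exp (avoids scipy dispatch overhead on tiny arrays)."""
    m = np.max(a, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))
    return out.squeeze(axis) if axis is not None else float(out.ravel()[0])


__all__ = [
    "RotamerLibrary",
    "RotamerGraph",
    "Beliefs",
    "SidechainResult",
    "build_rotamer_graph",
    "run_bp",
    "sidechain_forces",
    "fixture_library",
]


# ---------------------------------------------------------------------------
# rotamer library
# ---------------------------------------------------------------------------


@dataclass
class RotamerLibrary:
    """Per-residue-type bead states in the residue-local backbone frame.

    ``states[aa]`` is a list of (local_position (3,), local_orientation
    unit (3,), prior_weight); weights are normalized to sum to 1.  At most
    six states per type are supported by the file format.
    """

    states: dict

    def __post_init__(self):
        for aa, lst in self.states.items():
            if not 1 <= len(lst) <= 6:
                raise ValueError(f"{aa}: need 1-6 rotamer states")
            tot = sum(w for _, _, w in lst)
            self.states[aa] = [
                (np.asarray(p, float), np.asarray(v, float) / np.linalg.norm(v),
                 w / tot)
                for p, v, w in lst
            ]

    def n_states(self, aa: str) -> int:
        return len(self.states[aa])

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "residues": {
                aa: [
                    {"pos": list(map(float, p)), "orient": list(map(float, v)),
                     "weight": float(w)}
                    for p, v, w in lst
                ]
                for aa, lst in self.states.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RotamerLibrary":
        from .errors import UnsupportedVersionError

        if d.get("version") != 1:
            raise UnsupportedVersionError(
                f"rotamer library version {d.get('version')!r} unsupported"
            )
        return cls({
            aa: [(s["pos"], s["orient"], s["weight"]) for s in lst]
            for aa, lst in d["residues"].items()
        })


# Rough per-type distance (A) from Cbeta to the bead (side-chain centroid).
_BEAD_EXTENT = {
    "ALA": 0.0, "GLY": 0.0, "SER": 1.0, "CYS": 1.2, "THR": 1.1,
    "VAL": 1.2, "PRO": 1.2, "ASP": 1.6, "ASN": 1.6, "ILE": 1.8,
    "LEU": 1.8, "MET": 2.2, "GLU": 2.2, "GLN": 2.2, "HIS": 2.2,
    "PHE": 2.4, "TYR": 2.9, "TRP": 2.7, "LYS": 2.9, "ARG": 3.5,
}
_CHI1_PRIORS = (0.5, 0.3, 0.2)  # trans, gauche-, gauche+ (fixture values)


def fixture_library() -> RotamerLibrary:
    """Idealized chi1-state library (synthetic stand-in, not PDB-derived).

    ALA and GLY have a single state at the (pseudo-)Cbeta; every other type
    gets three staggered chi1-like positions at tetrahedral angles about
    the Ca->Cbeta axis, with orientations along the Cbeta->bead direction.
    """
    # local-frame Cbeta direction (see core.place_virtual_sites)
    cb_dir = np.array([0.61830, 0.0, np.sqrt(1.0 - 0.61830**2)])
    cb_local = core.BOND_CA_CB * cb_dir
    # orthonormal vectors perpendicular to cb_dir
    e1 = np.cross(cb_dir, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(cb_dir, e1)
    tet = np.deg2rad(180.0 - 109.5)
    states = {}
    for aa in core.AMINO_ACIDS:
        ext = _BEAD_EXTENT[aa]
        if ext == 0.0:
            states[aa] = [(cb_local, cb_dir, 1.0)]
            continue
        lst = []
        for k, w in enumerate(_CHI1_PRIORS):
            az = 2.0 * np.pi * k / 3.0
            d = (
                np.cos(tet) * cb_dir
                + np.sin(tet) * (np.cos(az) * e1 + np.sin(az) * e2)
            )
            pos = cb_local + ext * d
            v = pos - cb_local
            lst.append((pos, v / np.linalg.norm(v), w))
        states[aa] = lst
    return RotamerLibrary(states)


# ---------------------------------------------------------------------------
# backbone interaction sites (positions + orientations + gradient scatter)
# ---------------------------------------------------------------------------


class BackboneSites:
    """The five backbone interaction sites H, O, N, Ca, C per residue.

    Orientations are unit vectors along a local bond: H along N->H, O and C
    along C->O, N along N->Ca, Ca along Ca->Cbeta.  ``scatter`` routes
    gradients w.r.t. a site's position/orientation into backbone-atom and
    derived-site accumulators.
    """

    def __init__(self, state: BackboneState, frame: DerivedFrame):
        self.state = state
        self.frame = frame
        n = state.n_res
        x = state.positions
        self.pos = {
            "H": frame.H, "O": frame.O, "N": x[:, core.N],
            "CA": x[:, core.CA], "C": x[:, core.C],
        }
        self.present = {
            s: (frame.has_H if s == "H" else np.ones(n, bool))
            for s in self.pos
        }
        self.orient = {s: np.zeros((n, 3)) for s in self.pos}
        self._Ju = {s: np.zeros((n, 3, 3)) for s in self.pos}
        for i in range(n):
            uNCa, J1 = unit(x[i, core.CA] - x[i, core.N])
            self.orient["N"][i] = uNCa
            self._Ju["N"][i] = J1
            uCaCb, J2 = unit(frame.CB[i] - x[i, core.CA])
            self.orient["CA"][i] = uCaCb
            self._Ju["CA"][i] = J2
            uCO, J3 = unit(frame.O[i] - x[i, core.C])
            self.orient["O"][i] = uCO
            self.orient["C"][i] = uCO
            self._Ju["O"][i] = J3
            self._Ju["C"][i] = J3
            if frame.has_H[i]:
                uNH, J4 = unit(frame.H[i] - x[i, core.N])
                self.orient["H"][i] = uNH
                self._Ju["H"][i] = J4

    def scatter(self, site: str, j: int, g_pos, g_orient, bb, site_grads):
        """Add d(site pos/orient) gradients to the accumulators."""
        # position gradient
        if site in ("N", "CA", "C"):
            bb[j, {"N": core.N, "CA": core.CA, "C": core.C}[site]] += g_pos
        else:
            site_grads[site][j] += g_pos
        # orientation = unit(Pb - Pa)
        g = self._Ju[site][j] @ g_orient
        if site == "N":          # u = unit(CA - N)
            bb[j, core.CA] += g
            bb[j, core.N] -= g
        elif site == "CA":       # u = unit(CB - CA)
            site_grads["CB"][j] += g
            bb[j, core.CA] -= g
        elif site in ("O", "C"):  # u = unit(O - C)
            site_grads["O"][j] += g
            bb[j, core.C] -= g
        elif site == "H":        # u = unit(H - N)
            site_grads["H"][j] += g
            bb[j, core.N] -= g


# ---------------------------------------------------------------------------
# rotamer graph
# ---------------------------------------------------------------------------


@dataclass
class RotamerGraph:
    """Factor graph of discrete side-chain states.

    Node energies hold bead-backbone interactions (plus, in "bead" burial
    mode, the state-dependent environment term); edges hold the oriented
    bead-bead pair tables.  Prior weights enter BP as -T log w and are kept
    separate from the physical energies.
    """

    state: BackboneState
    frame: DerivedFrame
    pset: ParameterSet
    pos: list          # per residue: (S_i, 3) global bead positions
    orient: list       # per residue: (S_i, 3) global orientations
    local_pos: list    # per residue: (S_i, 3) library-local positions
    local_orient: list
    log_prior: list    # per residue: (S_i,)
    node_energy: list  # per residue: (S_i,)
    edges: list        # (i, j, table (S_i, S_j)) with i < j
    env_mode: str = "cbeta"
    env_burial: list = None  # type: ignore[assignment]  # bead-mode N_i(s)

    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    def n_states(self, i: int) -> int:
        return len(self.pos[i])

    def neighbors(self, i: int):
        out = []
        for k, (a, b, _) in enumerate(self.edges):
            if a == i:
                out.append((b, k, True))
            elif b == i:
                out.append((a, k, False))
        return out


def _site_neighbors(sites, sname, i, pos_i, cutoff):
    """Indices j != i whose site lies within cutoff of any state of i."""
    present = sites.present[sname].copy()
    present[i] = False
    js = np.where(present)[0]
    if js.size == 0:
        return js
    d = np.linalg.norm(
        pos_i[:, None, :] - sites.pos[sname][js][None, :, :], axis=2
    )
    return js[np.any(d < cutoff, axis=0)]


def _bead_env(graph_pos_i, u_axis, CB, i, cfg):
    """Burial count of a bead against all other residues' Cbetas."""
    tot = 0.0
    for j in range(len(CB)):
        if j == i:
            continue
        d = CB[j] - graph_pos_i
        r = float(np.linalg.norm(d))
        rhat = d / r
        tot += float(cfg.radial_switch(r)) * float(
            cfg.angular_switch(float(u_axis @ rhat))
        )
    return tot


def build_rotamer_graph(
    state: BackboneState,
    frame: DerivedFrame,
    pset: ParameterSet,
    library: RotamerLibrary,
    env_mode: str = "cbeta",
) -> RotamerGraph:
    """Place library states in each residue's frame and tabulate energies.

    Edges connect exactly the residue pairs with any inter-state bead
    distance below the side-chain cutoff.  Bead-backbone interactions of
    each state with the five sites of every *other* residue enter the node
    energies.
    """
    n = state.n_res
    x = state.positions
    seq = state.sequence.residues
    sites = BackboneSites(state, frame)
    cutoff = next(iter(pset.sc_pairs.values())).cutoff
    bb_cutoff = next(iter(pset.bb_pairs.values())).cutoff

    pos, orient, lpos, lorient, log_prior = [], [], [], [], []
    for i in range(n):
        sts = library.states[seq[i]]
        P = np.array([s[0] for s in sts])
        V = np.array([s[1] for s in sts])
        W = np.array([s[2] for s in sts])
        R = frame.R[i]
        pos.append(x[i, core.CA] + P @ R.T)
        orient.append(V @ R.T)
        lpos.append(P)
        lorient.append(V)
        log_prior.append(np.log(W))

    node_energy = [np.zeros(len(pos[i])) for i in range(n)]
    env_burial = []
    # batch bead-backbone interactions by (site, residue-type) parameter key
    jobs = {}
    for i in range(n):
        S = len(pos[i])
        for sname in ("H", "O", "N", "CA", "C"):
            js = _site_neighbors(sites, sname, i, pos[i], bb_cutoff)
            if js.size == 0:
                continue
            m = len(js)
            jobs.setdefault((sname, seq[i]), []).append((i, js, S, m))
    for key, job_list in jobs.items():
        pp = pset.bb_pairs[key]
        sname = key[0]
        Y1 = np.concatenate([
            np.repeat(pos[i], m, axis=0) for (i, js, S, m) in job_list])
        N1 = np.concatenate([
            np.repeat(orient[i], m, axis=0) for (i, js, S, m) in job_list])
        Y2 = np.concatenate([
            np.tile(sites.pos[sname][js], (S, 1)) for (i, js, S, m) in job_list])
        N2 = np.concatenate([
            np.tile(sites.orient[sname][js], (S, 1)) for (i, js, S, m) in job_list])
        Vv, _, _ = pair_energy_batch(pp, Y1, N1, Y2, N2)
        o = 0
        for (i, js, S, m) in job_list:
            node_energy[i] += Vv[o:o + S * m].reshape(S, m).sum(axis=1)
            o += S * m
    for i in range(n):
        S = len(pos[i])
        E = node_energy[i]
        if env_mode == "bead":
            Ni = np.zeros(S)
            for s in range(S):
                u_axis, _ = unit(pos[i][s] - x[i, core.CA])
                Ni[s] = _bead_env(pos[i][s], u_axis, frame.CB, i, pset.burial)
            f, _ = pset.env.curves[seq[i]].evaluate(Ni)
            E += f
            env_burial.append(Ni)

    # edges: batch the state-pair tables by canonical pair-type key
    pair_list = []
    ejobs = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmin = np.min(
                np.linalg.norm(
                    pos[i][:, None, :] - pos[j][None, :, :], axis=2
                )
            )
            if dmin >= cutoff:
                continue
            key, swapped = canonical_sc_key(seq[i], seq[j])
            ejobs.setdefault(key, []).append((i, j, swapped))
            pair_list.append((i, j))
    tables = {}
    for key, job_list in ejobs.items():
        pp = pset.sc_pairs[key]
        A1, O1, A2, O2, spans = [], [], [], [], []
        for (i, j, swapped) in job_list:
            Si, Sj = len(pos[i]), len(pos[j])
            ii, jj = np.meshgrid(np.arange(Si), np.arange(Sj), indexing="ij")
            a, b = (j, i) if swapped else (i, j)
            sa = jj.ravel() if swapped else ii.ravel()
            sb = ii.ravel() if swapped else jj.ravel()
            A1.append(pos[a][sa]); O1.append(orient[a][sa])
            A2.append(pos[b][sb]); O2.append(orient[b][sb])
            spans.append((i, j, Si, Sj))
        Vv, _, _ = pair_energy_batch(
            pp, np.concatenate(A1), np.concatenate(O1),
            np.concatenate(A2), np.concatenate(O2),
        )
        o = 0
        for (i, j, Si, Sj) in spans:
            tables[(i, j)] = Vv[o:o + Si * Sj].reshape(Si, Sj)
            o += Si * Sj
    edges = [(i, j, tables[(i, j)]) for (i, j) in pair_list]

    return RotamerGraph(
        state=state, frame=frame, pset=pset, pos=pos, orient=orient,
        local_pos=lpos, local_orient=lorient, log_prior=log_prior,
        node_energy=node_energy, edges=edges, env_mode=env_mode,
        env_burial=env_burial if env_mode == "bead" else None,
    )


# ---------------------------------------------------------------------------
# belief propagation
# ---------------------------------------------------------------------------


@dataclass
class Beliefs:
    node_marginals: list
    edge_marginals: list   # aligned with graph.edges
    free_energy: float
    converged: bool
    iterations: int
    temperature: float


def run_bp(
    graph: RotamerGraph,
    temperature: float = 1.0,
    damping: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> Beliefs:
    """Damped synchronous sum-product to self-consistency.

    Returns beliefs and the Bethe free energy F = U_node + U_edge -
    T * S_Bethe evaluated at the converged (node, edge) marginals; on trees
    this equals -T log Z exactly.  Non-convergence is reported through
    ``converged`` rather than raised: callers (notably training) may use
    the partial result.
    """
    T = float(temperature)
    if T <= 0:
        raise ValueError("temperature must be positive")
    n = graph.n_nodes
    # effective log node weight: log w - E/T
    log_phi = [
        graph.log_prior[i] - graph.node_energy[i] / T for i in range(n)
    ]
    log_psi = [(-tab / T) for (_, _, tab) in graph.edges]

    # messages per directed edge: (edge_index, direction) -> log array;
    # direction 0 is i -> j, 1 is j -> i for edge k = (i, j)
    msgs = {}
    recv = [[] for _ in range(n)]  # node -> keys of messages it receives
    for k, (i, j, _) in enumerate(graph.edges):
        msgs[(k, 0)] = np.zeros(graph.n_states(j))
        msgs[(k, 1)] = np.zeros(graph.n_states(i))
        recv[j].append((k, 0))
        recv[i].append((k, 1))

    def totals():
        tot = [log_phi[i].copy() for i in range(n)]
        for i in range(n):
            for key in recv[i]:
                tot[i] += msgs[key]
        return tot

    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        tot = totals()
        delta = 0.0
        new = {}
        for k, (i, j, _) in enumerate(graph.edges):
            pre = tot[i] - msgs[(k, 1)]
            m = _lse(pre[:, None] + log_psi[k], axis=0)
            new[(k, 0)] = m - _lse(m)
            pre = tot[j] - msgs[(k, 0)]
            m = _lse(pre[None, :] + log_psi[k], axis=1)
            new[(k, 1)] = m - _lse(m)
        for key, m in new.items():
            old = msgs[key]
            # damp in log space (robust at low temperature, where
            # probability-space mixing can stall on saturated messages)
            mixed = damping * old + (1.0 - damping) * m
            mixed = mixed - _lse(mixed)
            delta = max(
                delta, float(np.max(np.abs(np.exp(mixed) - np.exp(old))))
            )
            msgs[key] = mixed
        if delta < tol:
            converged = True
            break

    tot = totals()
    node_marg = []
    for i in range(n):
        b = np.exp(tot[i] - _lse(tot[i]))
        node_marg.append(b / b.sum())
    edge_marg = []
    for k, (i, j, _) in enumerate(graph.edges):
        li = tot[i] - msgs[(k, 1)]
        lj = tot[j] - msgs[(k, 0)]
        lb = li[:, None] + lj[None, :] + log_psi[k]
        b = np.exp(lb - _lse(lb))
        edge_marg.append(b / b.sum())

    # Bethe free energy
    F = 0.0
    degree = np.zeros(n, dtype=int)
    for (i, j, _) in graph.edges:
        degree[i] += 1
        degree[j] += 1
    for i in range(n):
        b = node_marg[i]
        Eeff = graph.node_energy[i] - T * graph.log_prior[i]
        F += float(b @ Eeff)
        F -= T * (degree[i] - 1) * float(
            np.sum(b * np.log(np.maximum(b, 1e-300)))
        )
    for k, (i, j, tab) in enumerate(graph.edges):
        b = edge_marg[k]
        F += float(np.sum(b * tab))
        F += T * float(np.sum(b * np.log(np.maximum(b, 1e-300))))

    return Beliefs(
        node_marginals=node_marg, edge_marginals=edge_marg,
        free_energy=F, converged=converged, iterations=it, temperature=T,
    )


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------


@dataclass
class SidechainResult:
    free_energy: float
    backbone_grad: np.ndarray   # (n, 3, 3)
    param_grad: np.ndarray      # (n_alpha,)
    beliefs: Beliefs = None     # type: ignore[assignment]


def _bead_pullback(graph, i, g_pos, g_orient, local_p, local_v, bb):
    """Route bead position/orientation gradients to residue i's atoms."""
    dR = graph.frame.dR[i]  # (atom, in-xyz, row, col)
    bb[i, core.CA] += g_pos
    for a in range(3):
        # d(R p)/datom_a[k] = dR[a, k] @ p ; similarly for v
        contrib = np.einsum("kjc,c,j->k", dR[a], local_p, g_pos)
        contrib += np.einsum("kjc,c,j->k", dR[a], local_v, g_orient)
        bb[i, a] += contrib


def sidechain_forces(graph: RotamerGraph, beliefs: Beliefs) -> SidechainResult:
    """Expected energy gradients under the converged beliefs.

    Coordinate forces are expectations of per-state (node) and per-pair
    (edge) energy gradients under the node/edge marginals -- exact at the
    Bethe stationary point; parameter gradients are expectations of the
    spline basis functions.
    """
    state, frame, pset = graph.state, graph.frame, graph.pset
    n = state.n_res
    x = state.positions
    seq = state.sequence.residues
    sites = BackboneSites(state, frame)
    offs, n_alpha = pset.block_offsets()
    bb = np.zeros((n, 3, 3))
    site_grads = {
        "O": np.zeros((n, 3)), "H": np.zeros((n, 3)), "CB": np.zeros((n, 3))
    }
    pgrad = np.zeros(n_alpha)
    bb_cutoff = next(iter(pset.bb_pairs.values())).cutoff

    # node terms: bead-backbone pairs, batched by (site, residue-type) key
    njobs = {}
    for i in range(n):
        S = graph.n_states(i)
        for sname in ("H", "O", "N", "CA", "C"):
            js = _site_neighbors(sites, sname, i, graph.pos[i], bb_cutoff)
            if js.size == 0:
                continue
            njobs.setdefault((sname, seq[i]), []).append((i, js, S, len(js)))
    for key, job_list in njobs.items():
        pp = pset.bb_pairs[key]
        sname = key[0]
        Y1 = np.concatenate([
            np.repeat(graph.pos[i], m, axis=0) for (i, js, S, m) in job_list])
        N1 = np.concatenate([
            np.repeat(graph.orient[i], m, axis=0)
            for (i, js, S, m) in job_list])
        Y2 = np.concatenate([
            np.tile(sites.pos[sname][js], (S, 1))
            for (i, js, S, m) in job_list])
        N2 = np.concatenate([
            np.tile(sites.orient[sname][js], (S, 1))
            for (i, js, S, m) in job_list])
        w = np.concatenate([
            np.repeat(beliefs.node_marginals[i], m)
            for (i, js, S, m) in job_list])
        Vv, g, dp = pair_energy_batch(pp, Y1, N1, Y2, N2)
        o = offs[("bb", key)]
        pgrad[o:o + pp.n_trainable] += w @ dp
        wy2 = w[:, None] * g["dy2"]
        wn2 = w[:, None] * g["dn2"]
        wy1 = w[:, None] * g["dy1"]
        wn1 = w[:, None] * g["dn1"]
        c = 0
        for (i, js, S, m) in job_list:
            gy2 = wy2[c:c + S * m].reshape(S, m, 3).sum(axis=0)
            gn2 = wn2[c:c + S * m].reshape(S, m, 3).sum(axis=0)
            for jj, j in enumerate(js):
                sites.scatter(sname, j, gy2[jj], gn2[jj], bb, site_grads)
            gy1 = wy1[c:c + S * m].reshape(S, m, 3).sum(axis=1)
            gn1 = wn1[c:c + S * m].reshape(S, m, 3).sum(axis=1)
            for s in range(S):
                _bead_pullback(
                    graph, i, gy1[s], gn1[s],
                    graph.local_pos[i][s], graph.local_orient[i][s], bb,
                )
            c += S * m
    if graph.env_mode == "bead":
        for i in range(n):
            _bead_env_forces(
                graph, i, beliefs.node_marginals[i], bb, site_grads,
                pgrad, offs,
            )

    # edge terms, batched by canonical pair-type key; bead gradients are
    # accumulated per (residue, state) and pulled back once at the end
    acc_pos = [np.zeros((graph.n_states(i), 3)) for i in range(n)]
    acc_or = [np.zeros((graph.n_states(i), 3)) for i in range(n)]
    ejobs = {}
    for k, (i, j, tab) in enumerate(graph.edges):
        key, swapped = canonical_sc_key(seq[i], seq[j])
        ejobs.setdefault(key, []).append((k, i, j, swapped))
    for key, job_list in ejobs.items():
        pp = pset.sc_pairs[key]
        A1, O1, A2, O2, W, spans = [], [], [], [], [], []
        for (k, i, j, swapped) in job_list:
            Si, Sj = graph.n_states(i), graph.n_states(j)
            ii, jj = np.meshgrid(np.arange(Si), np.arange(Sj), indexing="ij")
            a, b = (j, i) if swapped else (i, j)
            sa = jj.ravel() if swapped else ii.ravel()
            sb = ii.ravel() if swapped else jj.ravel()
            A1.append(graph.pos[a][sa]); O1.append(graph.orient[a][sa])
            A2.append(graph.pos[b][sb]); O2.append(graph.orient[b][sb])
            W.append(beliefs.edge_marginals[k].ravel())
            spans.append((i, j, swapped, Si, Sj, ii.ravel(), jj.ravel()))
        Vv, g, dp = pair_energy_batch(
            pp, np.concatenate(A1), np.concatenate(O1),
            np.concatenate(A2), np.concatenate(O2),
        )
        w = np.concatenate(W)
        o = offs[("sc", key)]
        pgrad[o:o + pp.n_trainable] += w @ dp
        wy1 = w[:, None] * g["dy1"]
        wn1 = w[:, None] * g["dn1"]
        wy2 = w[:, None] * g["dy2"]
        wn2 = w[:, None] * g["dn2"]
        c = 0
        for (i, j, swapped, Si, Sj, si, sj) in spans:
            m = Si * Sj
            gi_pos, gi_or = (wy2, wn2) if swapped else (wy1, wn1)
            gj_pos, gj_or = (wy1, wn1) if swapped else (wy2, wn2)
            np.add.at(acc_pos[i], si, gi_pos[c:c + m])
            np.add.at(acc_or[i], si, gi_or[c:c + m])
            np.add.at(acc_pos[j], sj, gj_pos[c:c + m])
            np.add.at(acc_or[j], sj, gj_or[c:c + m])
            c += m
    for i in range(n):
        for s in range(graph.n_states(i)):
            _bead_pullback(
                graph, i, acc_pos[i][s], acc_or[i][s],
                graph.local_pos[i][s], graph.local_orient[i][s], bb,
            )

    bb += core.pullback_gradients(frame, site_grads)
    return SidechainResult(
        free_energy=beliefs.free_energy, backbone_grad=bb,
        param_grad=pgrad, beliefs=beliefs,
    )


def _bead_env_forces(graph, i, b_i, bb, site_grads, pgrad, offs):
    """Bead-mode environment term: gradients of v_env(N_i(s))."""
    state, frame, pset = graph.state, graph.frame, graph.pset
    cfg = pset.burial
    seq = state.sequence.residues
    curve = pset.env.curves[seq[i]]
    Ca = state.positions[i, core.CA]
    for s in range(graph.n_states(i)):
        w_s = b_i[s]
        if w_s < 1e-14:
            continue
        y = graph.pos[i][s]
        Ni = graph.env_burial[i][s]
        _, df = curve.evaluate(Ni)
        df = float(df)
        k, wgt = curve.basis(Ni)
        o = offs[("env", seq[i])]
        good = k[0] >= 0
        np.add.at(pgrad, o + k[0][good], w_s * wgt[0][good])
        u_axis, Ju = unit(y - Ca)
        g_y = np.zeros(3)
        g_ca = np.zeros(3)
        for j in range(state.n_res):
            if j == i:
                continue
            d = frame.CB[j] - y
            r = float(np.linalg.norm(d))
            rhat = d / r
            c = float(u_axis @ rhat)
            sr = float(cfg.radial_switch(r))
            sa = float(cfg.angular_switch(c))
            dsr = float(cfg.radial_switch_deriv(r))
            dsa = float(cfg.angular_switch_deriv(c))
            Jr = (np.eye(3) - np.outer(rhat, rhat)) / r
            dc_dCBj = Jr @ u_axis
            gCB = dsr * sa * rhat + sr * dsa * dc_dCBj
            site_grads["CB"][j] += w_s * df * gCB
            # y enters through -d and through u_axis
            dc_dy = -dc_dCBj + Ju @ rhat
            g_y += df * (-dsr * sa * rhat + sr * dsa * dc_dy)
            g_ca += df * (sr * dsa * (-(Ju @ rhat)))
        bb[i, core.CA] += w_s * g_ca
        _bead_pullback(
            graph, i, w_s * g_y, np.zeros(3),
            graph.local_pos[i][s], graph.local_orient[i][s], bb,
        )
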