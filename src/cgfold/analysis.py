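"""Trajectory observables: RMSD, radius of gyration, heat capacity,
hydrogen-bond counts, and RMSD-based clustering.

Conventions: Ca-RMSD is computed after optimal (Kabsch) superposition and,
by default, after excluding three residues at each terminus to discount
end fraying.  The heat capacity uses the fluctuation relation
Cp = var(E)/T^2 (unbiased variance), and the radius of gyration is
compared against the self-avoiding-walk reference Rg = 1.9 * Nres^0.6 A
for chemically denatured chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import BackboneState
from .errors import ShapeError

__all__ = [
    "kabsch",
    "ca_rmsd",
    "radius_of_gyration",
    "saw_reference",
    "heat_capacity",
    "hbond_count",
    "cluster_frames",
    "rmsd_histogram",
    "TrajectoryStats",
    "trajectory_stats",
]


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal rotation aligning centered Q onto centered P (SVD method).

    Returns (R, rmsd): ``R @ q`` superposes centered Q coordinates onto
    centered P.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = Pc - Qc @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return R, rmsd


def _ca_coords(x) -> np.ndarray:
    if isinstance(x, BackboneState):
        return x.positions[:, core.CA]
    x = np.asarray(x, float)
    if x.ndim == 3:
        return x[:, core.CA]
    return x


def ca_rmsd(A, B, exclude_termini: int = 3) -> float:
    """Best-fit Ca RMSD excluding ``exclude_termini`` residues at each end."""
    a = _ca_coords(A)
    b = _ca_coords(B)
    if a.shape != b.shape:
        raise ShapeError(f"residue count mismatch: {a.shape} vs {b.shape}")
    if exclude_termini < 0:
        raise ValueError("exclude_termini must be >= 0")
    n = len(a)
    if 2 * exclude_termini >= n:
        raise ValueError("exclusion removes the whole chain")
    sl = slice(exclude_termini, n - exclude_termini if exclude_termini else n)
    if np.array_equal(a[sl], b[sl]):
        return 0.0
    _, r = kabsch(a[sl], b[sl])
    return r


def radius_of_gyration(frame) -> float:
    """Root-mean-square Ca distance from the Ca centroid (A)."""
    ca = _ca_coords(frame)
    c = ca - ca.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(c**2, axis=1))))


def saw_reference(n_res: int) -> float:
    """Self-avoiding-walk Rg (A) for a chemically denatured chain."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    return 1.9 * n_res**0.6


def heat_capacity(energies, temperature: float) -> float:
    """Fluctuation-relation heat capacity Cp = var(E)/T^2 (unbiased)."""
    e = np.asarray(energies, float)
    if len(e) < 2:
        raise ValueError("need at least 2 energy samples")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(np.var(e, ddof=1) / temperature**2)


def hbond_count(state: BackboneState, pset=None, threshold: float = 0.5) -> int:
    """Number of donor/acceptor pairs with H-bond score >= threshold."""
    from . import potentials

    pset = pset or potentials.ParameterSet.zeros()
    frame = core.place_virtual_sites(state)
    _, _, _, scores, _ = potentials.eval_hbond(pset.hbond, state, frame)
    return int(sum(1 for s in scores.values() if s >= threshold))


def cluster_frames(frames, rmsd_cutoff: float = 3.0, exclude_termini: int = 3):
    """Greedy leader clustering on pairwise Ca-RMSD.

    A frame joins the first existing cluster whose leader is within
    ``rmsd_cutoff``; otherwise it founds a new cluster.  Clusters are
    returned largest first (ties by first-frame index); each cluster's
    centroid is the member minimizing mean RMSD to the rest of its cluster.
    Returns (clusters: list of member-index lists, centroids: list of
    frame indices).
    """
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    leaders = []
    members = []
    for fi, f in enumerate(frames):
        for li, leader in enumerate(leaders):
            if ca_rmsd(f, frames[leader], exclude_termini) < rmsd_cutoff:
                members[li].append(fi)
                break
        else:
            leaders.append(fi)
            members.append([fi])
    order = sorted(range(len(members)), key=lambda k: (-len(members[k]), members[k][0]))
    clusters = [members[k] for k in order]
    centroids = []
    for cl in clusters:
        if len(cl) == 1:
            centroids.append(cl[0])
            continue
        best, best_mean = cl[0], np.inf
        for a in cl:
            mean = np.mean([
                ca_rmsd(frames[a], frames[b], exclude_termini)
                for b in cl if b != a
            ])
            if mean < best_mean:
                best, best_mean = a, mean
        centroids.append(best)
    return clusters, centroids


def rmsd_histogram(
    trajectory, reference, discard_fraction: float = 1.0 / 3.0,
    bins: int = 30, range_max: float | None = None,
    exclude_termini: int = 3,
):
    """Histogram of Ca-RMSD-to-reference over the retained frames.

    The first ``discard_fraction`` of frames is dropped as equilibration.
    Returns (counts, bin_edges, rmsds).
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n = len(trajectory)
    start = int(np.floor(n * discard_fraction))
    kept = trajectory[start:]
    rmsds = np.array([ca_rmsd(f, reference, exclude_termini) for f in kept])
    hi = range_max if range_max is not None else max(float(rmsds.max()), 1e-6)
    counts, edges = np.histogram(rmsds, bins=bins, range=(0.0, hi))
    return counts, edges, rmsds


@dataclass
class TrajectoryStats:
    """Per-frame observables and per-run summaries of one trajectory."""

    energies: np.ndarray
    rg: np.ndarray
    hbonds: np.ndarray
    rmsd: np.ndarray | None
    cp: float
    clusters: list
    centroids: list

    def as_table(self) -> str:
        cols = ["frame", "energy", "rg", "hbonds"]
        if self.rmsd is not None:
            cols.append("rmsd")
        lines = ["\t".join(cols)]
        for i in range(len(self.energies)):
            row = [str(i), f"{self.energies[i]:.6f}", f"{self.rg[i]:.4f}",
                   str(int(self.hbonds[i]))]
            if self.rmsd is not None:
                row.append(f"{self.rmsd[i]:.4f}")
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def trajectory_stats(
    frames, energies, temperature: float, pset=None,
    reference=None, rmsd_cutoff: float = 3.0, exclude_termini: int = 3,
) -> TrajectoryStats:
    """Compute the standard per-frame and per-run observables."""
    energies = np.asarray(energies, float)
    rg = np.array([radius_of_gyration(f) for f in frames])
    hb = np.array([hbond_count(f, pset) for f in frames])
    rmsd = None
    if reference is not None:
        rmsd = np.array([
            ca_rmsd(f, reference, exclude_termini) for f in frames
        ])
    cp = heat_capacity(energies, temperature) if len(energies) > 1 else 0.0
    clusters, centroids = cluster_frames(
        list(frames), rmsd_cutoff, exclude_termini
    )
    return TrajectoryStats(
        energies=energies, rg=rg, hbonds=hb, rmsd=rmsd, cp=cp,
        clusters=clusters, centroids=centroids,
    )
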