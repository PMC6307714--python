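"""Contrastive-divergence training of the force-field parameters.

For each protein two short replica-exchange simulations are run from the
native structure: one restrained to stay within ~1 A best-fit Ca-RMSD of
the native (flat-bottom restraint) and one free.  Per retained frame the
parameter derivatives dV/dalpha are recorded, and each minibatch update
moves every trainable parameter by

    alpha <- alpha + (eps/M) * sum_a ( <dV/dalpha>_free - <dV/dalpha>_restrained ),

the contrastive pseudo-gradient ("model minus data"): the exact descent
direction of the data negative log-likelihood when the free simulation
equilibrates, and a useful direction even when it does not.  It lowers the
energy of the native-restrained ensemble relative to what the current
model prefers.  The step size decays
by a configured factor after a configured number of full passes through
the fixed minibatches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import core, dynamics
from .analysis import ca_rmsd, kabsch
from .core import BackboneState
from .errors import ParameterMismatchError
from .model import EnergyModel
from .potentials import ParameterSet

__all__ = [
    "Ensemble",
    "CDConfig",
    "RestraintSpec",
    "make_minibatches",
    "sample_free_ensemble",
    "sample_restrained_ensemble",
    "cd_delta",
    "cd_update_vector",
    "cd_update",
    "training_loop",
]


@dataclass
class Ensemble:
    """Sampled conformations with energies and per-frame dV/dalpha."""

    frames: list                 # list of (n,3,3) position arrays
    energies: np.ndarray
    dvda: np.ndarray             # (n_frames, n_alpha)
    provenance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mean_dvda(self) -> np.ndarray:
        return self.dvda.mean(axis=0)


@dataclass
class RestraintSpec:
    """Flat-bottom harmonic restraint on best-fit Ca-RMSD to a reference."""

    reference: np.ndarray        # (n, 3) Ca coordinates
    radius: float = 1.0          # A; zero energy/force inside
    spring: float = 50.0         # energy / A^2 beyond the bottom

    def energy_forces(self, state: BackboneState):
        """Restraint energy and forces on the Ca atoms.

        The gradient of the best-fit RMSD w.r.t. the mobile coordinates is
        (x'_i - R q'_i) / (N * RMSD) with primes denoting centered
        coordinates and R the optimal rotation (terms through R and the
        centroid vanish at the optimum).
        """
        ca = state.positions[:, core.CA]
        R, rmsd = kabsch(ca, self.reference)
        f = np.zeros_like(state.positions)
        if rmsd <= self.radius or rmsd < 1e-12:
            return 0.0, f
        e = 0.5 * self.spring * (rmsd - self.radius) ** 2
        pc = ca - ca.mean(axis=0)
        qc = self.reference - self.reference.mean(axis=0)
        diff = pc - qc @ R.T
        dE_dca = self.spring * (rmsd - self.radius) * diff / (len(ca) * rmsd)
        f[:, core.CA] = -dE_dca
        return e, f


@dataclass
class CDConfig:
    """Training hyperparameters (defaults follow the study protocol where
    one is stated; simulation sizes are meant to be scaled to the task)."""

    step_size: float = 0.1           # eps
    minibatch_size: int = 12         # M proteins per update
    sim_time: float = 5000.0         # time units of free-ensemble dynamics
    equil_fraction: float = 0.5      # discarded as equilibration
    restraint_radius: float = 1.0    # A
    restraint_spring: float = 50.0
    passes_before_decay: int = 2
    decay_factor: float = 0.25
    n_replicas: int = 8
    t_min: float = 0.9
    base_interval: float = 0.03      # ladder spacing at the reference size
    dt: float = 0.01
    friction: float = 1.0
    save_interval: int = 50          # MD steps between saved frames
    swap_period: int = 100
    seed: int = 0
    shuffle_minibatches: bool = False
    block_lr: dict = field(default_factory=dict)  # kind -> multiplier

    def __post_init__(self):
        if self.step_size <= 0 or self.minibatch_size < 1:
            raise ValueError("require eps > 0 and M >= 1")
        if not 0.0 <= self.equil_fraction < 1.0:
            raise ValueError("equil_fraction must be in [0, 1)")


def make_minibatches(n_items: int, m: int, rng=None):
    """Partition range(n_items) into ceil(n/m) fixed consecutive subsets."""
    idx = np.arange(n_items)
    if rng is not None:
        rng.shuffle(idx)
    return [idx[i:i + m].tolist() for i in range(0, n_items, m)]


def _sample_ensemble(
    protein: BackboneState,
    model: EnergyModel,
    config: CDConfig,
    rng: np.random.Generator,
    restraint: RestraintSpec | None,
    temperature: float = 1.0,
) -> Ensemble:
    """Replica-exchange sampling; frames recorded from the coldest replica."""
    ladder = dynamics.make_ladder(
        config.n_replicas, config.t_min, config.base_interval,
        protein.n_res, swap_period=config.swap_period,
    )
    temps = ladder.temperatures

    def provider(T):
        def force(state):
            res = model.evaluate(state, temperature=T)
            f = -res.grad
            if restraint is not None:
                _, fr = restraint.energy_forces(state)
                f = f + fr
            return f
        return force

    n_steps = max(1, int(round(config.sim_time / config.dt)))
    replicas = [protein.copy() for _ in temps]
    forces = [None] * len(temps)
    cfgs = [
        dynamics.ThermostatConfig(
            temperature=float(T), friction=config.friction, dt=config.dt
        )
        for T in temps
    ]
    providers = [provider(float(T)) for T in temps]

    frames, energies, dvda = [], [], []
    parity = 0
    for step in range(n_steps):
        for k in range(len(temps)):
            replicas[k], forces[k] = dynamics.langevin_step(
                replicas[k], providers[k], cfgs[k], rng, forces=forces[k]
            )
        if (step + 1) % config.swap_period == 0 and len(temps) > 1:
            es = np.array([
                model.energy(r, temperature=float(t))
                + (restraint.energy_forces(r)[0] if restraint else 0.0)
                for r, t in zip(replicas, temps)
            ])
            replicas, _, _ = dynamics.replica_exchange_step(
                replicas, es, temps, rng, parity=parity
            )
            parity ^= 1
            forces = [None] * len(temps)
        if (step + 1) % config.save_interval == 0:
            res = model.evaluate(replicas[0], temperature=temperature)
            frames.append(replicas[0].positions.copy())
            energies.append(res.energy)
            dvda.append(res.param_grad.copy())

    n_keep = len(frames) - int(np.floor(len(frames) * config.equil_fraction))
    frames = frames[len(frames) - n_keep:]
    energies = np.array(energies[-n_keep:]) if n_keep else np.zeros(0)
    dvda = (
        np.array(dvda[-n_keep:]) if n_keep
        else np.zeros((0, model.pset.n_alpha))
    )
    return Ensemble(
        frames=frames, energies=energies, dvda=dvda,
        provenance={
            "restrained": restraint is not None,
            "temperature": temperature,
            "n_res": protein.n_res,
        },
    )


def sample_free_ensemble(
    protein: BackboneState, model: EnergyModel, config: CDConfig,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    rng = rng or np.random.default_rng(config.seed)
    return _sample_ensemble(protein, model, config, rng, restraint=None)


def sample_restrained_ensemble(
    protein: BackboneState, model: EnergyModel, config: CDConfig,
    restraint: RestraintSpec | None = None,
    rng: np.random.Generator | None = None,
) -> Ensemble:
    rng = rng or np.random.default_rng(config.seed)
    if restraint is None:
        restraint = RestraintSpec(
            reference=protein.positions[:, core.CA].copy(),
            radius=config.restraint_radius,
            spring=config.restraint_spring,
        )
    return _sample_ensemble(protein, model, config, rng, restraint=restraint)


def cd_delta(batch, n_alpha: int) -> np.ndarray:
    """Sum over proteins of <dV/da>_free - <dV/da>_restrained."""
    delta = np.zeros(n_alpha)
    for restrained, free in batch:
        if restrained.dvda.shape[1] != n_alpha or free.dvda.shape[1] != n_alpha:
            raise ParameterMismatchError(
                "ensemble dV/dalpha dimension does not match the parameter set"
            )
        delta += free.mean_dvda() - restrained.mean_dvda()
    return delta


def cd_update_vector(
    alpha: np.ndarray, batch, eps: float, m: int,
    lr_scale: np.ndarray | None = None,
) -> np.ndarray:
    """Plain update rule on a flat parameter vector."""
    delta = cd_delta(batch, len(alpha))
    if lr_scale is not None:
        delta = delta * lr_scale
    return alpha + (eps / m) * delta


def _lr_scale(pset: ParameterSet, block_lr: dict) -> np.ndarray | None:
    if not block_lr:
        return None
    offs, n = pset.block_offsets()
    sizes = pset.block_sizes()
    scale = np.ones(n)
    for (kind, key), o in offs.items():
        scale[o:o + sizes[(kind, key)]] = block_lr.get(kind, 1.0)
    return scale


def cd_update(pset: ParameterSet, batch, config: CDConfig, eps=None):
    """One minibatch update; returns (new ParameterSet, diagnostics).

    The restraint itself has no trainable parameters, so the recorded
    dV/dalpha of restrained ensembles contains no restraint contribution by
    construction.  Non-trainable constants are untouched (the update flows
    through the alpha vector only).
    """
    eps = config.step_size if eps is None else eps
    alpha = pset.to_vector()
    new_alpha = cd_update_vector(
        alpha, batch, eps, config.minibatch_size,
        lr_scale=_lr_scale(pset, config.block_lr),
    )
    new = copy.deepcopy(pset)
    new.from_vector(new_alpha)
    delta = new_alpha - alpha
    offs, _ = pset.block_offsets()
    sizes = pset.block_sizes()
    norms = {}
    for kind in ("sc", "bb", "env", "rama_bias", "hbond_mag"):
        block = np.concatenate([
            delta[o:o + sizes[bk]] for bk, o in offs.items() if bk[0] == kind
        ])
        norms[kind] = float(np.linalg.norm(block))
    diag = {"eps": eps, "update_norms": norms}
    return new, diag


def training_loop(
    proteins: list,
    pset0: ParameterSet,
    config: CDConfig,
    n_passes: int = 1,
    model_factory=None,
    callback=None,
    start_step: int = 0,
):
    """Minibatched CD over a fixed partition of the training proteins.

    ``model_factory(pset) -> EnergyModel`` lets callers control the model
    configuration (the default full model is used otherwise).  Returns
    (final ParameterSet, history list of per-step dicts).
    """
    if len(proteins) == 0:
        raise ValueError("need at least one training protein")
    if model_factory is None:
        model_factory = EnergyModel
    batches = make_minibatches(
        len(proteins), config.minibatch_size,
        np.random.default_rng(config.seed)
        if config.shuffle_minibatches else None,
    )
    pset = copy.deepcopy(pset0)
    eps = config.step_size
    history = []
    step = 0
    for p in range(n_passes):
        if p > 0 and p % config.passes_before_decay == 0:
            eps *= config.decay_factor
        for bidx, batch_ids in enumerate(batches):
            if step < start_step:
                step += 1
                continue
            # per-step generator: resuming from a checkpoint at any step
            # reproduces the uninterrupted run exactly
            rng = np.random.default_rng([config.seed, step])
            model = model_factory(pset)
            batch = []
            rmsds = []
            for pid in batch_ids:
                prot = proteins[pid]
                r = sample_restrained_ensemble(prot, model, config, rng=rng)
                f = sample_free_ensemble(prot, model, config, rng=rng)
                batch.append((r, f))
                ref = prot.positions[:, core.CA]
                rmsds.extend(
                    ca_rmsd(fr[:, core.CA], ref, exclude_termini=0)
                    for fr in f.frames
                )
            pset, diag = cd_update(pset, batch, config, eps=eps)
            row = {
                "step": step, "pass": p, "minibatch": bidx, "eps": eps,
                "mean_rmsd": float(np.mean(rmsds)) if rmsds else np.nan,
                **{f"dnorm_{k}": v for k, v in diag["update_norms"].items()},
            }
            history.append(row)
            if callback is not None:
                callback(step, pset, row)
            step += 1
    return pset, history
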