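"""Sampling: Langevin (BAOAB) integration, pivot Monte Carlo, replica
exchange.

The integrator acts only on the backbone N/Ca/C coordinates; all derived
layers are rebuilt inside the force provider.  Pivot moves rotate a chain
segment rigidly about a backbone dihedral axis (preserving all bonded
geometry exactly) and are accepted by Metropolis; replica exchange swaps
configurations between neighboring temperatures, with the ladder spacing
scaling as 1/Nres so swap acceptance stays roughly size-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core
from .core import BackboneState
from .errors import IntegrationError
from .geometry import rotation_about_axis

# Display-unit conventions (used only for reporting, never in dynamics):
# one model energy unit ~ 0.6 kcal/mol and T = 1 corresponds to 300 K.
ENERGY_UNIT_KCAL = 0.6
T1_KELVIN = 300.0


@dataclass
class ThermostatConfig:
    temperature: float = 1.0
    friction: float = 1.0     # gamma, 1/time units
    dt: float = 0.01
    mass: float = 1.0         # uniform per atom
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0 or self.dt <= 0 or self.friction < 0:
            raise ValueError("require T >= 0, dt > 0, gamma >= 0")


def langevin_step(
    state: BackboneState,
    force_provider,
    config: ThermostatConfig,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
):
    """One BAOAB step; returns (new_state, forces_at_new_positions).

    ``force_provider(state) -> (n,3,3) forces``.  Passing the forces from
    the previous step avoids one evaluation per step.  At gamma = 0, T = 0
    this reduces to velocity Verlet; determinism is inherited from ``rng``.
    """
    dt, m, gam, T = config.dt, config.mass, config.friction, config.temperature
    if forces is None:
        forces = force_provider(state)
    if not np.all(np.isfinite(forces)):
        bad = int(np.argmax(~np.isfinite(forces.reshape(-1, 3)).all(axis=1)))
        raise IntegrationError(atom_index=bad)
    s = state.copy()
    p = s.momenta
    p += 0.5 * dt * forces                     # B
    s.positions += 0.5 * dt * p / m            # A
    if gam > 0:
        c1 = np.exp(-gam * dt)
        c2 = np.sqrt(m * T * (1.0 - c1 * c1))
        p *= c1
        p += c2 * rng.standard_normal(p.shape)  # O
    s.positions += 0.5 * dt * p / m            # A
    f_new = force_provider(s)
    if not np.all(np.isfinite(f_new)):
        bad = int(np.argmax(~np.isfinite(f_new.reshape(-1, 3)).all(axis=1)))
        raise IntegrationError(atom_index=bad)
    p += 0.5 * dt * f_new                      # B
    return s, f_new


def run_langevin(
    state: BackboneState,
    force_provider,
    config: ThermostatConfig,
    n_steps: int,
    rng: np.random.Generator | None = None,
    callback=None,
):
    """Integrate ``n_steps`` BAOAB steps; callback(step, state) if given."""
    rng = rng or np.random.default_rng(config.seed)
    f = force_provider(state)
    for step in range(n_steps):
        state, f = langevin_step(state, force_provider, config, rng, forces=f)
        if callback is not None:
            callback(step, state)
    return state


def pivot_move(
    state: BackboneState,
    rng: np.random.Generator,
    energy_provider,
    temperature: float,
    max_angle: float = np.pi,
    energy: float | None = None,
):
    """One pivot Monte Carlo move; returns (state', accepted, energy').

    Rotates the chain segment downstream of a randomly chosen phi or psi
    axis by a uniform angle, preserving every bonded internal coordinate
    exactly, and applies the Metropolis criterion at ``temperature``.
    ``energy_provider(state) -> float``; passing the current energy avoids
    recomputing it.
    """
    n = state.n_res
    if n < 2:
        raise ValueError("pivot moves need at least 2 residues")
    if energy is None:
        energy = energy_provider(state)
    # choose a dihedral: phi_i (axis N_i -> CA_i, rotates C_i onward) for
    # i in 1..n-1, or psi_i (axis CA_i -> C_i, rotates N_{i+1} onward) for
    # i in 0..n-2.
    use_phi = bool(rng.integers(2))
    if use_phi:
        i = int(rng.integers(1, n))
        origin = state.positions[i, core.N]
        axis = state.positions[i, core.CA] - origin
        first_flat = 3 * i + core.C
    else:
        i = int(rng.integers(0, n - 1))
        origin = state.positions[i, core.CA]
        axis = state.positions[i, core.C] - origin
        first_flat = 3 * (i + 1) + core.N
    angle = rng.uniform(-max_angle, max_angle)
    R = rotation_about_axis(axis, angle)
    trial = state.copy()
    flat = trial.positions.reshape(-1, 3)
    flat[first_flat:] = (flat[first_flat:] - origin) @ R.T + origin
    e_trial = energy_provider(trial)
    dE = e_trial - energy
    if dE <= 0 or rng.uniform() < np.exp(-dE / temperature):
        return trial, True, e_trial
    return state, False, energy


@dataclass
class ReplicaLadder:
    """Temperature ladder with 1/Nres interval scaling.

    T_k = T_min + k * base_interval * (nres_ref / Nres); the reference
    chain length anchors the normalization so that a protein of
    ``nres_ref`` residues gets intervals of exactly ``base_interval``.
    """

    temperatures: np.ndarray
    swap_period: int = 100
    seed: int = 0

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if np.any(np.diff(self.temperatures) <= 0) and len(self.temperatures) > 1:
            raise ValueError("temperatures must be strictly increasing")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)


def make_ladder(
    n_replicas: int,
    t_min: float,
    base_interval: float,
    n_res: int,
    nres_ref: int = 100,
    swap_period: int = 100,
    seed: int = 0,
) -> ReplicaLadder:
    if n_replicas < 1:
        raise ValueError("need at least one replica")
    step = base_interval * nres_ref / n_res
    temps = t_min + step * np.arange(n_replicas)
    return ReplicaLadder(temps, swap_period=swap_period, seed=seed)


def replica_exchange_step(
    configs: list,
    energies: np.ndarray,
    temperatures: np.ndarray,
    rng: np.random.Generator,
    parity: int = 0,
):
    """One sweep of neighbor swaps over pairs of the given parity.

    ``configs`` are swapped in place semantics-wise (a permuted list is
    returned); the configuration multiset is always a permutation of the
    input.  Acceptance: min(1, exp(dbeta * dE)).  Returns (configs,
    energies, accepted_mask).
    """
    configs = list(configs)
    energies = np.asarray(energies, dtype=float).copy()
    beta = 1.0 / np.asarray(temperatures, dtype=float)
    n = len(configs)
    accepted = np.zeros(n - 1, dtype=bool)
    for k in range(parity, n - 1, 2):
        dlnp = (beta[k] - beta[k + 1]) * (energies[k] - energies[k + 1])
        if dlnp >= 0 or rng.uniform() < np.exp(dlnp):
            configs[k], configs[k + 1] = configs[k + 1], configs[k]
            energies[k], energies[k + 1] = energies[k + 1], energies[k]
            accepted[k] = True
    return configs, energies, accepted
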