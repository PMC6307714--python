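"""Full-model energy/force evaluation (the inner loop of the simulator).

One evaluation performs, in order: deterministic virtual-site placement,
rotamer-graph construction, belief propagation to self-consistency, and
assembly of the total energy

    E = bonded + steric + Rama + H-bond + environment + F_sidechain

with its exact backbone gradient (forces) and parameter gradient, all
derived-coordinate contributions pulled back through the placement
Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import core, potentials, sidechain
from .core import BackboneState
from .errors import IntegrationError
from .potentials import ParameterSet
from .sidechain import RotamerLibrary, fixture_library


@dataclass
class BPConfig:
    damping: float = 0.5
    tol: float = 1e-8
    max_iter: int = 50


@dataclass
class EnergyResult:
    energy: float
    grad: np.ndarray        # (n, 3, 3) dE/dx
    param_grad: np.ndarray  # (n_alpha,)
    terms: dict
    beliefs: "sidechain.Beliefs | None"
    frame: "core.DerivedFrame"

    @property
    def forces(self) -> np.ndarray:
        return -self.grad


class EnergyModel:
    """Evaluates energy and forces of a parameter set on backbone states.

    ``env_mode`` selects where the burial count is measured: "cbeta"
    (default; N_i from the pseudo-Cbeta positions, environment term outside
    BP) or "bead" (state-dependent burial inside the node energies).
    ``include_sidechain=False`` drops the bead layer entirely (backbone-only
    model), mainly for tests and cheap demonstrations.
    """

    def __init__(
        self,
        pset: ParameterSet,
        library: RotamerLibrary | None = None,
        env_mode: str = "cbeta",
        bp: BPConfig | None = None,
        include_sidechain: bool = True,
    ):
        if env_mode not in ("cbeta", "bead"):
            raise ValueError(f"unknown env_mode {env_mode!r}")
        self.pset = pset
        self.library = library or fixture_library()
        self.env_mode = env_mode
        self.bp = bp or BPConfig()
        self.include_sidechain = include_sidechain

    def evaluate(
        self, state: BackboneState, temperature: float = 1.0
    ) -> EnergyResult:
        frame = core.place_virtual_sites(state)
        sc_result = None
        if self.include_sidechain:
            graph = sidechain.build_rotamer_graph(
                state, frame, self.pset, self.library, env_mode=self.env_mode
            )
            beliefs = sidechain.run_bp(
                graph, temperature=temperature, damping=self.bp.damping,
                tol=self.bp.tol, max_iter=self.bp.max_iter,
            )
            sc_result = sidechain.sidechain_forces(graph, beliefs)
        E, grad, pgrad, terms = potentials.total_energy(
            state, frame, self.pset, sidechain=sc_result,
            include_env=(self.env_mode == "cbeta"),
        )
        return EnergyResult(
            energy=E, grad=grad, param_grad=pgrad, terms=terms,
            beliefs=sc_result.beliefs if sc_result else None, frame=frame,
        )

    def energy(self, state: BackboneState, temperature: float = 1.0) -> float:
        return self.evaluate(state, temperature).energy

    def forces(
        self, state: BackboneState, temperature: float = 1.0
    ) -> np.ndarray:
        f = -self.evaluate(state, temperature).grad
        if not np.all(np.isfinite(f)):
            bad = int(np.argmax(~np.isfinite(f.reshape(-1, 3)).all(axis=1)))
            raise IntegrationError(atom_index=bad)
        return f
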