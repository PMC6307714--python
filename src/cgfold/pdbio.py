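"""PDB reading/writing for backbone states and trajectories.

Only N, CA and C records are consumed on input (O/H/CB are always
recomputed from the backbone); multi-MODEL files are treated as
trajectories.  Output optionally includes the derived O and CB sites for
visualization.
"""

from __future__ import annotations

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import core
from .core import BackboneState, Sequence
from .errors import MissingAtomError

__all__ = ["read_pdb", "write_pdb"]


def read_pdb(path) -> list[BackboneState]:
    """Read a (possibly multi-MODEL) PDB file into backbone states."""
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    states = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        mask = np.isin(arr.atom_name, ("N", "CA", "C")) & (
            ~arr.hetero if hasattr(arr, "hetero") else True
        )
        arr = arr[mask]
        res_ids = np.unique(arr.res_id)
        residues = []
        coords = {}
        for k, rid in enumerate(sorted(res_ids)):
            sel = arr[arr.res_id == rid]
            residues.append(str(sel.res_name[0]))
            for name in ("N", "CA", "C"):
                hit = sel[sel.atom_name == name]
                if len(hit) == 0:
                    raise MissingAtomError(residue=k + 1, atom=name)
                coords[(k + 1, name)] = hit.coord[0]
        seq = Sequence(residues)
        states.append(core.build_topology(seq, coords))
    return states


def _to_atom_array(state: BackboneState, include_derived: bool) -> struc.AtomArray:
    frame = core.place_virtual_sites(state) if include_derived else None
    atoms = []
    for i in range(state.n_res):
        for a, name in enumerate(core.ATOM_NAMES):
            atoms.append((i, name, state.positions[i, a]))
        if include_derived:
            atoms.append((i, "O", frame.O[i]))
            atoms.append((i, "CB", frame.CB[i]))
    arr = struc.AtomArray(len(atoms))
    for k, (i, name, xyz) in enumerate(atoms):
        arr.coord[k] = xyz
        arr.chain_id[k] = "A"
        arr.res_id[k] = i + 1
        arr.res_name[k] = state.sequence.residues[i]
        arr.atom_name[k] = name
        arr.element[k] = name[0]
    return arr


def write_pdb(path, states, include_derived: bool = False) -> None:
    """Write one state or a list of states (as MODELs) to a PDB file."""
    if isinstance(states, BackboneState):
        states = [states]
    arrays = [_to_atom_array(s, include_derived) for s in states]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))
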