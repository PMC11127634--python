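"""PDB and multi-model PDB input/output (wwPDB v3.3 columns, via biotite).

Chain ID maps to strand id, residue numbering is 1-based per strand, and a
residue containing the phosphorothioate sulfur atom is annotated ``PS`` on
read.  Multi-model files become a :class:`~thiohelix.core.Trajectory` with
one frame per MODEL.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .core import PS_SULFUR_NAME, Structure, Trajectory

__all__ = ["read_pdb", "write_pdb"]


def _to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = s.strand_ids.astype("U4")
    arr.res_id = s.res_indices
    arr.res_name = s.res_names.astype("U5")
    arr.atom_name = s.atom_names.astype("U6")
    arr.element = s.elements.astype("U2")
    arr.hetero = np.zeros(s.n_atoms, bool)
    return arr


def _from_atom_array(arr: bst.AtomArray) -> Structure:
    linkage = {}
    for chain, rid, name in zip(arr.chain_id, arr.res_id, arr.atom_name):
        key = (str(chain), int(rid))
        if name == PS_SULFUR_NAME:
            linkage[key] = "PS"
        else:
            linkage.setdefault(key, "PO")
    return Structure(
        np.array([str(a) for a in arr.atom_name], dtype=object),
        np.array([str(e).capitalize() for e in arr.element], dtype=object),
        np.asarray(arr.res_id, int),
        np.array([str(r) for r in arr.res_name], dtype=object),
        np.array([str(c) for c in arr.chain_id], dtype=object),
        np.asarray(arr.coord, float),
        linkage,
    )


def write_pdb(obj: Union[Structure, Trajectory], path) -> None:
    pdb = PDBFile()
    if isinstance(obj, Trajectory):
        stack = bst.stack([_to_atom_array(f) for f in obj.frames])
        pdb.set_structure(stack)
    else:
        pdb.set_structure(_to_atom_array(obj))
    pdb.write(str(path))


def read_pdb(path) -> Union[Structure, Trajectory]:
    """Read a PDB file; multi-model files return a Trajectory."""
    pdb = PDBFile.read(str(Path(path)))
    stack = pdb.get_structure(model=None)
    if stack.stack_depth() == 1:
        return _from_atom_array(stack[0])
    frames = [_from_atom_array(stack[i]) for i in range(stack.stack_depth())]
    return Trajectory(frames=frames)
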