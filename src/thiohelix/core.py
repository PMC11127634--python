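"""In-memory containers for nucleic-acid structures and conformational ensembles.

A :class:`Structure` is a flat table of atoms with (strand, residue, atom-name)
bookkeeping plus a per-residue linkage annotation distinguishing natural
phosphate (``PO``) from phosphorothioate (``PS``) 5′ linkages.  A
:class:`Trajectory` is an ordered list of same-topology structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

ResidueKey = Tuple[str, int]  # (strand_id, 1-based residue index)

#: atom name used for the phosphorothioate sulfur replacing a non-bridging
#: phosphate oxygen (the "SPT"-type site)
PS_SULFUR_NAME = "SP1"

_ELEMENT_FROM_NAME = {"P": "P", PS_SULFUR_NAME: "S"}


def element_from_atom_name(name: str) -> str:
    if name in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name]
    return name.lstrip("0123456789")[0]


@dataclass
class Structure:
    """Atom table with residue/strand bookkeeping; coordinates in Å."""

    atom_names: np.ndarray          # (n,) str
    elements: np.ndarray            # (n,) str
    res_indices: np.ndarray         # (n,) int, 1-based within each strand
    res_names: np.ndarray           # (n,) str, e.g. DA, DG, C, U
    strand_ids: np.ndarray          # (n,) str, chain identifiers
    coords: np.ndarray              # (n, 3) float Å
    linkage: Dict[ResidueKey, str] = field(default_factory=dict)  # "PO" | "PS"

    def __post_init__(self):
        n = len(self.atom_names)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.res_indices = np.asarray(self.res_indices, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype=object)
        self.strand_ids = np.asarray(self.strand_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.strand_ids, self.res_indices, self.atom_names))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (strand, residue, atom-name) keys")

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_keys(self) -> List[ResidueKey]:
        """Residue keys in file order (strand by strand, 5′→3′)."""
        seen: Dict[ResidueKey, None] = {}
        for s, i in zip(self.strand_ids, self.res_indices):
            seen.setdefault((s, int(i)), None)
        return list(seen)

    def strands(self) -> List[str]:
        out: Dict[str, None] = {}
        for s in self.strand_ids:
            out.setdefault(s, None)
        return list(out)

    def residue_atoms(self, key: ResidueKey) -> Dict[str, int]:
        """Map atom name → row index for one residue."""
        s, i = key
        mask = (self.strand_ids == s) & (self.res_indices == i)
        idx = np.nonzero(mask)[0]
        return {self.atom_names[j]: int(j) for j in idx}

    def residue_name(self, key: ResidueKey) -> str:
        s, i = key
        mask = (self.strand_ids == s) & (self.res_indices == i)
        j = np.nonzero(mask)[0]
        if len(j) == 0:
            raise KeyError(f"no residue {key}")
        return str(self.res_names[j[0]])

    def atom_coord(self, key: ResidueKey, name: str) -> np.ndarray:
        atoms = self.residue_atoms(key)
        if name not in atoms:
            raise KeyError(f"atom {name!r} not in residue {key}")
        return self.coords[atoms[name]]

    # -- selections --------------------------------------------------------
    def select(self, selection: str) -> np.ndarray:
        """Row indices for a named selection: 'P', 'heavy' or 'all'."""
        if selection == "all":
            return np.arange(self.n_atoms)
        if selection == "P":
            return np.nonzero(self.atom_names == "P")[0]
        if selection == "heavy":
            return np.nonzero(self.elements != "H")[0]
        raise ValueError(f"unknown selection {selection!r}")

    def copy(self) -> "Structure":
        return Structure(
            self.atom_names.copy(),
            self.elements.copy(),
            self.res_indices.copy(),
            self.res_names.copy(),
            self.strand_ids.copy(),
            self.coords.copy(),
            dict(self.linkage),
        )

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.atom_names, other.atom_names)
            and np.array_equal(self.res_indices, other.res_indices)
            and np.array_equal(self.strand_ids, other.strand_ids)
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.  ``frame_interval`` is metadata."""

    frames: List[Structure]
    frame_interval: float = 1.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for f in self.frames[1:]:
            if not ref.same_topology(f):
                raise ValueError("all frames must share one topology")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def topology(self) -> Structure:
        return self.frames[0]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.frames)

    def __getitem__(self, i) -> Structure:
        return self.frames[i]

    def coord_stack(self, selection: str = "all") -> np.ndarray:
        """(n_frames, n_sel, 3) coordinate array."""
        idx = self.topology.select(selection)
        return np.stack([f.coords[idx] for f in self.frames])


def concat_structures(parts: Sequence[Structure]) -> Structure:
    linkage: Dict[ResidueKey, str] = {}
    for p in parts:
        linkage.update(p.linkage)
    return Structure(
        np.concatenate([p.atom_names for p in parts]),
        np.concatenate([p.elements for p in parts]),
        np.concatenate([p.res_indices for p in parts]),
        np.concatenate([p.res_names for p in parts]),
        np.concatenate([p.strand_ids for p in parts]),
        np.concatenate([p.coords for p in parts]),
        linkage,
    )
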