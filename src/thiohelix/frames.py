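"""Base and base-pair reference frames.

Frames are assigned by least-squares superposition of idealized planar
base-ring templates onto the observed ring atoms, giving a right-handed
orthonormal triad plus origin per base.  Pair frames average the two base
frames after the strand-reversal flip, via the half rotation (the mid-frame
construction used throughout the helical-parameter algebra).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import bases
from ._geom import is_rotation, kabsch, matrix_to_rotvec, rotvec_to_matrix
from .core import ResidueKey, Structure

#: default Watson-Crick pairing criteria
C1_DISTANCE_CUTOFF = 12.0     # Å, C1'-C1'
Z_DOT_CUTOFF = -0.5           # z-axis alignment after strand flip
MIN_SAME_STRAND_SEPARATION = 4  # residues, excludes stacked neighbours


@dataclass(frozen=True)
class BaseFrame:
    """Orthonormal frame of one base: columns of ``axes`` are x, y, z."""

    origin: np.ndarray
    axes: np.ndarray
    residue: ResidueKey

    def __post_init__(self):
        if not is_rotation(self.axes, tol=1e-6):
            raise ValueError("axes must be a proper rotation matrix")


@dataclass(frozen=True)
class PairFrame:
    origin: np.ndarray
    axes: np.ndarray
    residues: Tuple[ResidueKey, ResidueKey]

    def __post_init__(self):
        if not is_rotation(self.axes, tol=1e-6):
            raise ValueError("axes must be a proper rotation matrix")


def assign_base_frame(structure: Structure, residue: ResidueKey) -> BaseFrame:
    """Fit the residue's idealized ring template; returns its base frame.

    The frame is the rigid transform (R, t) minimizing the RMSD between the
    template ring atoms and the observed ones, so a base lying exactly at
    template coordinates has identity axes and zero origin.
    """
    letter = bases.base_letter(structure.residue_name(residue))
    ring = bases.ring_atom_names(letter)
    template = bases.BASE_TEMPLATES[letter]
    atom_map = structure.residue_atoms(residue)
    missing = [a for a in ring if a not in atom_map]
    if missing:
        raise ValueError(f"residue {residue} lacks ring atoms {missing}")
    obs = np.array([structure.coords[atom_map[a]] for a in ring])
    tmpl = np.array([template[a] for a in ring])
    if np.linalg.matrix_rank(obs - obs.mean(axis=0), tol=1e-6) < 2:
        raise ValueError(f"degenerate (collinear) ring atoms in {residue}")
    R, t, _ = kabsch(tmpl, obs)
    return BaseFrame(origin=t, axes=R, residue=residue)


def pair_frame(f1: BaseFrame, f2: BaseFrame) -> PairFrame:
    """Mid-frame of a Watson-Crick pair.

    The second frame is flipped (x and z axes negated, the strand-reversal
    convention), then the two frames are averaged through the half rotation;
    the origin is the midpoint of the two origins.
    """
    r2 = f2.axes @ bases.FLIP
    if f1.axes[:, 2] @ r2[:, 2] < 0.0:
        raise ValueError("frames not pairable: z axes anti-aligned after flip")
    rel = matrix_to_rotvec(f1.axes.T @ r2)
    mid = f1.axes @ rotvec_to_matrix(0.5 * rel)
    origin = 0.5 * (f1.origin + f2.origin)
    return PairFrame(origin=origin, axes=mid, residues=(f1.residue, f2.residue))


def _complementary(structure: Structure, k1: ResidueKey, k2: ResidueKey) -> bool:
    b1 = bases.base_letter(structure.residue_name(k1))
    b2 = bases.base_letter(structure.residue_name(k2))
    return b2 in {bases.WC_COMPLEMENT_DNA.get(b1), bases.WC_COMPLEMENT_RNA.get(b1)}


def detect_pairing(
    structure: Structure,
    c1_cutoff: float = C1_DISTANCE_CUTOFF,
    z_dot_cutoff: float = Z_DOT_CUTOFF,
) -> List[Tuple[ResidueKey, ResidueKey]]:
    """Watson-Crick pairs by complementarity + distance + frame anti-alignment.

    Candidates must be sequence-complementary, have C1'-C1' within
    ``c1_cutoff`` and anti-aligned z axes after the strand flip.  Same-strand
    candidates (hairpins) must be separated by at least
    ``MIN_SAME_STRAND_SEPARATION`` residues.  A greedy match on ascending
    C1'-C1' distance assigns at most one partner per residue; unpaired
    residues (bulges, loops) simply receive none.
    """
    keys = structure.residue_keys()
    frames = {}
    c1 = {}
    for k in keys:
        atoms = structure.residue_atoms(k)
        if "C1'" not in atoms:
            continue
        try:
            frames[k] = assign_base_frame(structure, k)
        except ValueError:
            continue
        c1[k] = structure.coords[atoms["C1'"]]

    candidates = []
    usable = [k for k in keys if k in frames]
    for i, k1 in enumerate(usable):
        for k2 in usable[i + 1:]:
            if k1[0] == k2[0] and abs(k1[1] - k2[1]) < MIN_SAME_STRAND_SEPARATION:
                continue
            if not _complementary(structure, k1, k2):
                continue
            d = float(np.linalg.norm(c1[k1] - c1[k2]))
            if d > c1_cutoff:
                continue
            z1 = frames[k1].axes[:, 2]
            z2f = (frames[k2].axes @ bases.FLIP)[:, 2]
            # after flipping the candidate partner, paired z axes align;
            # equivalently the raw z axes are anti-aligned
            if z1 @ (-z2f) > z_dot_cutoff:
                continue
            # rank by base-frame origin distance: true partners share the
            # pair centre, whereas register-shifted contacts that pass the
            # C1' gate sit a full step away
            rank = float(np.linalg.norm(frames[k1].origin - frames[k2].origin))
            candidates.append((rank, k1, k2))

    candidates.sort(key=lambda c: c[0])
    taken = set()
    pairs: List[Tuple[ResidueKey, ResidueKey]] = []
    for _, k1, k2 in candidates:
        if k1 in taken or k2 in taken:
            continue
        taken.add(k1)
        taken.add(k2)
        pairs.append((k1, k2))
    order = {k: i for i, k in enumerate(keys)}
    pairs.sort(key=lambda p: min(order[p[0]], order[p[1]]))
    # orient each pair so the first member is the earlier residue
    return [(a, b) if order[a] < order[b] else (b, a) for a, b in pairs]


def pair_frames_for(
    structure: Structure,
    pairing: Optional[List[Tuple[ResidueKey, ResidueKey]]] = None,
) -> List[PairFrame]:
    """Pair frames for all detected (or given) Watson-Crick pairs, in order."""
    if pairing is None:
        pairing = detect_pairing(structure)
    out = []
    for k1, k2 in pairing:
        f1 = assign_base_frame(structure, k1)
        f2 = assign_base_frame(structure, k2)
        out.append(pair_frame(f1, f2))
    return out
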