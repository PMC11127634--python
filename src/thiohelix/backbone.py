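"""Backbone and glycosidic torsions, BI/BII and α/γ substates, sugar puckers.

Torsion conventions: IUPAC-signed angles in (−180, 180].  The backbone
torsions follow the standard nucleic-acid definitions::

    alpha   O3'(i-1) - P - O5' - C5'
    beta    P - O5' - C5' - C4'
    gamma   O5' - C5' - C4' - C3'
    delta   C5' - C4' - C3' - O3'
    epsilon C4' - C3' - O3' - P(i+1)
    zeta    C3' - O3' - P(i+1) - O5'(i+1)
    chi     O4' - C1' - N9 - C4  (purines) / O4' - C1' - N1 - C2 (pyrimidines)

Sugar pseudorotation uses the Altona–Sundaralingam relation on the five
endocyclic torsions; conformer names partition the phase circle into ten
36-degree sectors.  The BI/BII rule is the literal sign rule (both ε and ζ
negative → BI, both positive → BII); the common ε−ζ difference criterion is
available as a variant for cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import bases
from ._geom import dihedral_deg
from .core import ResidueKey, Structure

__all__ = [
    "dihedral", "TorsionRecord", "backbone_torsions", "classify_BI_BII",
    "alpha_gamma_state", "Pucker", "sugar_pucker", "sugar_pucker_from_structure",
    "torsion_table", "PUCKER_NAMES",
]

TORSION_NAMES = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "chi"]

#: the ten canonical conformers, one per 36-degree sector of P starting at
#: the north sector centred on 18 degrees
PUCKER_NAMES = [
    "C3'-endo", "C4'-exo", "O4'-endo", "C1'-exo", "C2'-endo",
    "C3'-exo", "C4'-endo", "O4'-exo", "C1'-endo", "C2'-exo",
]


def dihedral(p1, p2, p3, p4) -> float:
    """IUPAC-signed torsion of four points, degrees in (−180, 180]."""
    return dihedral_deg(p1, p2, p3, p4)


@dataclass
class TorsionRecord:
    """Per-nucleotide torsions; missing torsions are None with a flag."""

    residue: ResidueKey
    angles: Dict[str, Optional[float]] = field(default_factory=dict)
    undefined: List[str] = field(default_factory=list)

    def __getattr__(self, name):
        if name in TORSION_NAMES:
            return self.angles.get(name)
        raise AttributeError(name)


def _coord(structure: Structure, atoms: Dict[str, int], name: str):
    return structure.coords[atoms[name]] if name in atoms else None


def backbone_torsions(structure: Structure) -> List[TorsionRecord]:
    """All seven torsions for every residue, chain-aware.

    Missing atoms (chain termini, incomplete residues) flag the affected
    torsion as undefined instead of failing.  The phosphorothioate sulfur
    replaces a non-bridging oxygen that appears in no torsion quadruple, so
    PS residues are handled identically to natural ones.
    """
    keys = structure.residue_keys()
    atom_maps = {k: structure.residue_atoms(k) for k in keys}
    by_strand: Dict[str, Dict[int, ResidueKey]] = {}
    for s, i in keys:
        by_strand.setdefault(s, {})[i] = (s, i)

    records = []
    for key in keys:
        s, i = key
        me = atom_maps[key]
        prev = by_strand[s].get(i - 1)
        nxt = by_strand[s].get(i + 1)
        g = lambda name: _coord(structure, me, name)
        g_prev = (lambda name: _coord(structure, atom_maps[prev], name)) if prev else (lambda name: None)
        g_next = (lambda name: _coord(structure, atom_maps[nxt], name)) if nxt else (lambda name: None)

        quads = {
            "alpha": (g_prev("O3'"), g("P"), g("O5'"), g("C5'")),
            "beta": (g("P"), g("O5'"), g("C5'"), g("C4'")),
            "gamma": (g("O5'"), g("C5'"), g("C4'"), g("C3'")),
            "delta": (g("C5'"), g("C4'"), g("C3'"), g("O3'")),
            "epsilon": (g("C4'"), g("C3'"), g("O3'"), g_next("P")),
            "zeta": (g("C3'"), g("O3'"), g_next("P"), g_next("O5'")),
        }
        try:
            letter = bases.base_letter(structure.residue_name(key))
            n_name = bases.GLYCOSIDIC_N[letter]
            c_name = bases.CHI_RING_ATOM[letter]
            quads["chi"] = (g("O4'"), g("C1'"), g(n_name), g(c_name))
        except (ValueError, KeyError):
            quads["chi"] = (None,) * 4

        rec = TorsionRecord(residue=key)
        for name, pts in quads.items():
            if any(p is None for p in pts):
                rec.angles[name] = None
                rec.undefined.append(name)
            else:
                rec.angles[name] = dihedral(*pts)
        records.append(rec)
    return records


def classify_BI_BII(eps: float, zeta: float) -> str:
    """BI if both ε and ζ are negative, BII if both positive.

    Zeros and mixed signs are reported as ``unclassified``; this is the
    literal sign rule, with the gap handled explicitly.
    """
    if eps is None or zeta is None:
        raise ValueError("epsilon and zeta must both be defined")
    if eps < 0.0 and zeta < 0.0:
        return "BI"
    if eps > 0.0 and zeta > 0.0:
        return "BII"
    return "unclassified"


def classify_BI_BII_difference(eps: float, zeta: float) -> str:
    """ε−ζ < 0 variant of the BI/BII criterion (cross-check rule)."""
    if eps is None or zeta is None:
        raise ValueError("epsilon and zeta must both be defined")
    d = (eps - zeta + 180.0) % 360.0 - 180.0
    return "BI" if d < 0 else "BII"


def _gauche_bin(angle: float) -> str:
    a = angle % 360.0
    if 0.0 <= a < 120.0:
        return "g+"
    if 120.0 <= a < 240.0:
        return "t"
    return "g-"


def alpha_gamma_state(alpha: float, gamma: float) -> str:
    """Joint α/γ rotamer state, e.g. the canonical "g-/g+"."""
    if alpha is None or gamma is None:
        raise ValueError("alpha and gamma must both be defined")
    return f"{_gauche_bin(alpha)}/{_gauche_bin(gamma)}"


@dataclass(frozen=True)
class Pucker:
    """Sugar pseudorotation state."""

    phase: float            # P, degrees in [0, 360)
    amplitude: float        # nu_max, degrees >= 0
    name: Optional[str]     # canonical conformer, None if amplitude ~ 0

    @property
    def defined(self) -> bool:
        return self.name is not None


def pucker_name(phase: float) -> str:
    sector = int((phase % 360.0) // 36.0)
    return PUCKER_NAMES[sector]


def sugar_pucker(nu0, nu1, nu2, nu3, nu4) -> Pucker:
    """Pseudorotation phase and amplitude from the five ring torsions.

    Altona–Sundaralingam: tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin36°+sin72°)),
    quadrant-corrected by the sign of ν2; νmax = ν2 / cos P.
    """
    nus = np.array([nu0, nu1, nu2, nu3, nu4], float)
    if np.all(np.abs(nus) < 0.5):
        return Pucker(phase=float("nan"), amplitude=0.0, name=None)
    s36, s72 = np.sin(np.deg2rad(36.0)), np.sin(np.deg2rad(72.0))
    num = (nu4 + nu1) - (nu3 + nu0)
    den = 2.0 * nu2 * (s36 + s72)
    p = np.degrees(np.arctan2(num, den)) % 360.0
    amp = nu2 / np.cos(np.deg2rad(p))
    return Pucker(phase=float(p), amplitude=float(amp), name=pucker_name(p))


_NU_QUADS = [
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
]


def sugar_pucker_from_structure(structure: Structure,
                                residue: ResidueKey) -> Pucker:
    atoms = structure.residue_atoms(residue)
    needed = {"C1'", "C2'", "C3'", "C4'", "O4'"}
    if not needed <= set(atoms):
        raise ValueError(f"residue {residue} lacks sugar ring atoms")
    nus = [dihedral(*(structure.coords[atoms[a]] for a in quad))
           for quad in _NU_QUADS]
    return sugar_pucker(*nus)


def torsion_table(structure: Structure) -> pd.DataFrame:
    """One row per residue: torsions, BI/BII, α/γ state, pucker."""
    rows = []
    for rec in backbone_torsions(structure):
        row = {"strand": rec.residue[0], "residue": rec.residue[1]}
        row.update({n: rec.angles.get(n) for n in TORSION_NAMES})
        e, z = rec.angles.get("epsilon"), rec.angles.get("zeta")
        row["bi_bii"] = classify_BI_BII(e, z) if e is not None and z is not None else None
        a, gm = rec.angles.get("alpha"), rec.angles.get("gamma")
        row["alpha_gamma"] = (alpha_gamma_state(a, gm)
                              if a is not None and gm is not None else None)
        try:
            pk = sugar_pucker_from_structure(structure, rec.residue)
            row["pucker_P"] = pk.phase
            row["pucker_amplitude"] = pk.amplitude
            row["pucker_name"] = pk.name
        except ValueError:
            row["pucker_P"] = np.nan
            row["pucker_amplitude"] = np.nan
            row["pucker_name"] = None
        rows.append(row)
    return pd.DataFrame(rows)
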