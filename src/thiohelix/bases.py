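"""Idealized planar base templates in base-frame coordinates.

Each template maps atom name → coordinates (Å) of the base in its *own*
reference frame.  The frame convention is chosen so that for a Watson–Crick
pair whose pair frame is (R, o):

* the strand-1 base sits at ``R @ T + o``;
* the strand-2 (complementary) base sits at ``R @ F @ T' + o`` with
  ``F = diag(-1, 1, -1)`` (the strand-reversal flip about the y axis).

Flipping a strand-2 base frame's x and z axes therefore recovers the pair
frame exactly.  The geometries are idealized (regular fused rings, planar);
only self-consistency matters, because the same templates are used both to
build structures and to assign frames by least-squares superposition.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np

# strand-reversal flip: rotation by 180 deg about y
FLIP = np.diag([-1.0, 1.0, -1.0])

_HEX_BOND = 1.39          # six-ring bond length
_C1_N_BOND = 1.47         # glycosidic bond
_C1_X = 5.35              # |x| of C1' in the pair frame (C1'-C1' = 10.7 Å)
_C1_Y = -2.5              # y of the C1'-C1' line in the pair frame
_LAMBDA = 54.5            # glycosidic bond angle vs the C1'-C1' line (deg)
_EXO_BOND = 1.35          # exocyclic substituent bond length

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T", "U"}

RING_ATOMS: Dict[str, List[str]] = {
    "purine": ["N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9"],
    "pyrimidine": ["N1", "C2", "N3", "C4", "C5", "C6"],
}

#: exocyclic heavy atoms per base: name → host ring atom
_EXOCYCLIC = {
    "A": {"N6": "C6"},
    "G": {"O6": "C6", "N2": "C2"},
    "C": {"O2": "C2", "N4": "C4"},
    "T": {"O2": "C2", "O4": "C4", "C7": "C5"},
    "U": {"O2": "C2", "O4": "C4"},
}

GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1", "U": "N1"}
#: the base atom defining chi together with the glycosidic N
CHI_RING_ATOM = {"A": "C4", "G": "C4", "C": "C2", "T": "C2", "U": "C2"}

WC_COMPLEMENT_DNA = {"A": "T", "T": "A", "G": "C", "C": "G"}
WC_COMPLEMENT_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _hexagon() -> Dict[str, np.ndarray]:
    """Regular six-ring, atoms N1..C6; N1 points toward -y."""
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    ang = np.deg2rad(-90 + 60 * np.arange(6))
    return {
        n: _HEX_BOND * np.array([np.cos(a), np.sin(a), 0.0])
        for n, a in zip(names, ang)
    }


def _purine_local() -> Dict[str, np.ndarray]:
    """Fused 6+5 purine ring system in a local build frame."""
    atoms = _hexagon()
    c4, c5 = atoms["C4"], atoms["C5"]
    s = np.linalg.norm(c5 - c4)
    apothem = s / (2 * np.tan(np.pi / 5))
    mid = 0.5 * (c4 + c5)
    out = mid / np.linalg.norm(mid)      # away from the hexagon centre
    pc = mid + apothem * out             # pentagon centre
    r5 = s / (2 * np.sin(np.pi / 5))     # pentagon circumradius
    a4 = np.arctan2(c4[1] - pc[1], c4[0] - pc[0])
    a5 = np.arctan2(c5[1] - pc[1], c5[0] - pc[0])
    # walk the pentagon from C5 away from C4: C5 -> N7 -> C8 -> N9 -> C4
    step = (a5 - a4 + np.pi) % (2 * np.pi) - np.pi  # signed 72 deg step
    for k, name in enumerate(["N7", "C8", "N9"], start=1):
        a = a5 + k * step
        atoms[name] = pc + r5 * np.array([np.cos(a), np.sin(a), 0.0])
    # glycosidic C1' radially out of the pentagon through N9
    n9 = atoms["N9"]
    atoms["C1'"] = n9 + _C1_N_BOND * (n9 - pc) / np.linalg.norm(n9 - pc)
    atoms["_pentagon_centre"] = pc
    return atoms


def _pyrimidine_local() -> Dict[str, np.ndarray]:
    atoms = _hexagon()
    n1 = atoms["N1"]
    atoms["C1'"] = n1 + _C1_N_BOND * n1 / np.linalg.norm(n1)
    return atoms


def _planar_map(atoms: Dict[str, np.ndarray], c1_from: np.ndarray,
                n_from: np.ndarray, c1_to: np.ndarray,
                n_to: np.ndarray, mirror: bool) -> Dict[str, np.ndarray]:
    """In-plane rigid map taking (C1', N) to target positions.

    ``mirror`` reflects the local template about its C1'→N axis first, which
    selects on which side of the glycosidic bond the ring extends.
    """
    coords = {k: v.copy() for k, v in atoms.items() if not k.startswith("_")}
    if mirror:
        axis = (n_from - c1_from) / np.linalg.norm(n_from - c1_from)
        for k, v in coords.items():
            rel = v - c1_from
            par = (rel @ axis) * axis
            coords[k] = c1_from + 2 * par - rel
            coords[k][2] = 0.0
    v_from = n_from - c1_from
    v_to = n_to - c1_to
    th = np.arctan2(v_to[1], v_to[0]) - np.arctan2(v_from[1], v_from[0])
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    return {k: R @ (v - c1_from) + c1_to for k, v in coords.items()}


def _add_exocyclic(base: str, coords: Dict[str, np.ndarray],
                   centre: np.ndarray) -> None:
    for name, host in _EXOCYCLIC[base].items():
        h = coords[host]
        d = (h - centre) / np.linalg.norm(h - centre)
        coords[name] = h + _EXO_BOND * d


def _build_templates() -> Dict[str, Dict[str, np.ndarray]]:
    lam = np.deg2rad(_LAMBDA)
    c1_r = np.array([_C1_X, _C1_Y, 0.0])
    c1_y = np.array([-_C1_X, _C1_Y, 0.0])
    n_r = c1_r + _C1_N_BOND * np.array([-np.cos(lam), np.sin(lam), 0.0])
    n_y = c1_y + _C1_N_BOND * np.array([np.cos(lam), np.sin(lam), 0.0])

    templates: Dict[str, Dict[str, np.ndarray]] = {}

    pur = _purine_local()
    for base in PURINES:
        # mirror flag orients the Watson-Crick edge (N1 side) toward the
        # partner across x = 0
        coords = _planar_map(pur, pur["C1'"], pur["N9"], c1_r, n_r, False)
        hexc = np.mean([coords[a] for a in ["N1", "C2", "N3", "C4", "C5", "C6"]], axis=0)
        _add_exocyclic(base, coords, hexc)
        templates[base] = coords

    pyr = _pyrimidine_local()
    for base in PYRIMIDINES:
        coords = _planar_map(pyr, pyr["C1'"], pyr["N1"], c1_y, n_y, False)
        hexc = np.mean([coords[a] for a in RING_ATOMS["pyrimidine"]], axis=0)
        _add_exocyclic(base, coords, hexc)
        # express in the pyrimidine's own base frame (pair frame times FLIP)
        templates[base] = {k: FLIP @ v for k, v in coords.items()}

    return templates


#: atom name → base-frame coordinates, per one-letter base code
BASE_TEMPLATES: Dict[str, Dict[str, np.ndarray]] = _build_templates()


def ring_atom_names(base: str) -> List[str]:
    return RING_ATOMS["purine" if base in PURINES else "pyrimidine"]


def base_letter(res_name: str) -> str:
    """One-letter base code from a residue name (DA, DG, ... or A, G, ...)."""
    b = res_name[-1]
    if b not in PURINES | PYRIMIDINES:
        raise ValueError(f"unknown residue name {res_name!r}")
    return b


def residue_name(base: str, chemistry: str) -> str:
    return ("D" + base) if chemistry == "DNA" else base
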