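"""Ideal A-/B-form duplex construction with phosphorothioate annotation.

The builder is a fiber model: every base pair is placed from uniform
per-step parameters, and each nucleotide's heavy atoms are instantiated
from a per-form internal-coordinate template (idealized planar base, sugar
ring closed numerically at the form's target pseudorotation phase, backbone
torsions at classical fiber values).  Because the same base templates drive
both construction and frame assignment, re-analyzing a built duplex returns
the form's reference step parameters to numerical precision.

The B form is the canonical straight 36 deg / 3.38 Å helix.  The A form is
generated helically — inclined, x-displaced base pairs around a common axis
with h-twist 32.7 deg and h-rise 2.81 Å — so that the analyzed
helical-axis parameters land in the A-form diagnostic region (xdisp below
−3 Å, inclination above 10 deg, h-rise below 3 Å) while the step-frame
rise stays above 3 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from . import bases
from ._geom import dihedral_deg, kabsch, place_atom
from .core import PS_SULFUR_NAME, ResidueKey, Structure, concat_structures
from .frames import PairFrame
from .helical import StepParams, rebuild_from_steps, step_parameters

__all__ = ["SequenceSpec", "FiberForm", "A_FORM", "B_FORM", "build_duplex"]


# ---------------------------------------------------------------------------
# sequence bookkeeping
# ---------------------------------------------------------------------------

def _complement(base: str, target_chemistry: str) -> str:
    """Watson-Crick partner of ``base``, spelled in the target alphabet."""
    partner = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}.get(base)
    if partner is None:
        raise ValueError(f"unknown base {base!r}")
    if partner == "T" and target_chemistry == "RNA":
        partner = "U"
    return partner


def reverse_complement(strand: str, target_chemistry: str) -> str:
    return "".join(_complement(b, target_chemistry) for b in reversed(strand))


@dataclass(frozen=True)
class SequenceSpec:
    """Duplex sequence with phosphorothioate site annotation.

    ``ps_sites`` holds ``(strand_id, residue_index)`` pairs marking a PS
    linkage 5′ of that residue; strand ids are "A" (strand 1) and "B"
    (strand 2), residue indices 1-based along each strand 5′→3′.
    """

    strand1: str
    strand1_type: str = "DNA"
    strand2_type: str = "DNA"
    strand2: Optional[str] = None
    ps_sites: FrozenSet[Tuple[str, int]] = frozenset()

    def __post_init__(self):
        for t in (self.strand1_type, self.strand2_type):
            if t not in ("DNA", "RNA"):
                raise ValueError(f"strand type must be DNA or RNA, got {t!r}")
        expected = reverse_complement(self.strand1, self.strand2_type)
        if self.strand2 is None:
            object.__setattr__(self, "strand2", expected)
        elif self.strand2 != expected:
            raise ValueError(
                f"strand2 {self.strand2!r} is not the reverse complement "
                f"of strand1 (expected {expected!r})")
        object.__setattr__(self, "ps_sites", frozenset(self.ps_sites))
        n = len(self.strand1)
        for strand_id, idx in self.ps_sites:
            if strand_id not in ("A", "B"):
                raise ValueError(f"unknown strand id {strand_id!r}")
            if not 1 <= idx <= n:
                raise ValueError(f"PS site index {idx} out of range")
            if idx == 1:
                raise ValueError(
                    f"PS site ({strand_id}, 1): 5' terminal residue has no "
                    "phosphate")

    @property
    def n_pairs(self) -> int:
        return len(self.strand1)

    @classmethod
    def with_ps_before_every(cls, strand1: str, base: str,
                             strand1_type: str = "DNA",
                             strand2_type: str = "DNA") -> "SequenceSpec":
        """PS linkage 5′ of every occurrence of ``base``, on both strands."""
        spec = cls(strand1, strand1_type, strand2_type)
        sites = set()
        for sid, strand in (("A", spec.strand1), ("B", spec.strand2)):
            for i, b in enumerate(strand, start=1):
                if b == base and i > 1:
                    sites.add((sid, i))
        return cls(strand1, strand1_type, strand2_type, spec.strand2,
                   frozenset(sites))


# ---------------------------------------------------------------------------
# fiber forms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberForm:
    """Reference geometry of an idealized helical form.

    ``step`` holds the six uniform base-pair step parameters; ``torsions``
    the per-residue backbone/glycosidic targets (classical fiber values);
    ``pucker_phase``/``pucker_amplitude`` the sugar pseudorotation target.
    """

    name: str
    step: StepParams
    torsions: Dict[str, float]
    pucker_phase: float
    pucker_amplitude: float
    helical: Optional[Dict[str, float]] = None

    def pair_frames(self, n_pairs: int) -> List[PairFrame]:
        start = PairFrame(np.zeros(3), np.eye(3), (("A", 1), ("B", n_pairs)))
        frames = rebuild_from_steps(start, [self.step] * (n_pairs - 1))
        return [
            PairFrame(f.origin, f.axes, (("A", i + 1), ("B", n_pairs - i)))
            for i, f in enumerate(frames)
        ]


_B_TORSIONS = {"alpha": -41.0, "beta": 136.0, "gamma": 36.0, "delta": 139.0,
               "epsilon": -133.0, "zeta": -157.0, "chi": -102.0}
_A_TORSIONS = {"alpha": -68.0, "beta": 178.0, "gamma": 54.0, "delta": 82.0,
               "epsilon": -153.0, "zeta": -71.0, "chi": -158.0}

B_FORM = FiberForm(
    name="B",
    step=StepParams(shift=0.0, slide=0.0, rise=3.38,
                    tilt=0.0, roll=0.0, twist=36.0),
    torsions=_B_TORSIONS,
    pucker_phase=155.0,      # C2'-endo
    pucker_amplitude=38.0,
)

_A_HELICAL = {"h_twist": 32.7, "h_rise": 2.81, "xdisp": -4.17, "incl": 19.1}


def _a_form_step() -> StepParams:
    """Uniform step parameters equivalent to the helical A-form placement."""
    hz = Rotation.from_euler("z", _A_HELICAL["h_twist"], degrees=True).as_matrix()
    tilt_x = Rotation.from_euler("x", _A_HELICAL["incl"], degrees=True).as_matrix()
    disp = np.array([_A_HELICAL["xdisp"], 0.0, 0.0])
    frames = []
    for i in range(2):
        rz = np.linalg.matrix_power(hz, i)
        origin = rz @ disp + np.array([0.0, 0.0, i * _A_HELICAL["h_rise"]])
        frames.append(PairFrame(origin, rz @ tilt_x, (("A", i + 1), ("B", 2 - i))))
    return step_parameters(frames[0], frames[1])


A_FORM = FiberForm(
    name="A",
    step=_a_form_step(),
    torsions=_A_TORSIONS,
    pucker_phase=18.0,       # C3'-endo
    pucker_amplitude=38.0,
    helical=dict(_A_HELICAL),
)

FORMS = {"A": A_FORM, "B": B_FORM}


# ---------------------------------------------------------------------------
# sugar ring closure
# ---------------------------------------------------------------------------

_RING_ATOMS = ["C1'", "C2'", "C3'", "C4'", "O4'"]
_RING_BONDS = [1.526, 1.525, 1.527, 1.446, 1.414]   # x0-x1, ..., x4-x0


def pseudorotation_torsions(phase: float, amplitude: float) -> np.ndarray:
    """Endocyclic torsions ν0..ν4 from pseudorotation phase/amplitude."""
    j = np.arange(5)
    return amplitude * np.cos(np.deg2rad(phase + 144.0 * (j - 2)))


def _ring_torsions(x: np.ndarray) -> np.ndarray:
    # ν_j is the torsion about the bond x_j — x_{j+1}... using the standard
    # furanose indexing: ν0 = C4'-O4'-C1'-C2' etc.
    quads = [(3, 4, 0, 1), (4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0)]
    return np.array([dihedral_deg(x[a], x[b], x[c], x[d]) for a, b, c, d in quads])


@lru_cache(maxsize=32)
def closed_sugar_ring(phase: float, amplitude: float) -> Tuple[Tuple[float, ...], ...]:
    """Five furanose ring atoms realizing the target pseudorotation state.

    Solved by weighted least squares over bond lengths (hard) and the five
    Altona–Sundaralingam torsions (soft); cached per (phase, amplitude).
    Returns coordinates in atom order C1', C2', C3', C4', O4'.
    """
    nu_t = pseudorotation_torsions(phase, amplitude)
    r0 = 1.49 / (2 * np.sin(np.pi / 5))
    ang = np.deg2rad(90 + 72 * np.arange(5))
    x0 = np.column_stack([
        r0 * np.cos(ang),
        r0 * np.sin(ang),
        0.25 * np.cos(np.deg2rad(phase + 144.0 * (np.arange(5) - 2))),
    ]).ravel()

    def residuals(v):
        x = v.reshape(5, 3)
        res = []
        for j in range(5):
            d = np.linalg.norm(x[(j + 1) % 5] - x[j]) - _RING_BONDS[j]
            res.append(10.0 * d)
        nu = _ring_torsions(x)
        dnu = (nu - nu_t + 180.0) % 360.0 - 180.0
        res.extend(0.2 * dnu)
        return np.array(res)

    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    x = sol.x.reshape(5, 3)
    x -= x.mean(axis=0)
    return tuple(tuple(row) for row in x)


# ---------------------------------------------------------------------------
# nucleotide templates
# ---------------------------------------------------------------------------

_C2_BRANCH = +1.0


def _offset_for_angle(a1: float, a2: float, a12: float) -> float:
    """Torsion offset between two substituents of one centre (degrees)."""
    a1, a2, a12 = np.deg2rad([a1, a2, a12])
    c = (np.cos(a12) - np.cos(a1) * np.cos(a2)) / (np.sin(a1) * np.sin(a2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _measured_phase(ring: Dict[str, np.ndarray]) -> float:
    x = np.array([ring[a] for a in _RING_ATOMS])
    nu = _ring_torsions(x)
    s36, s72 = np.sin(np.deg2rad(36.0)), np.sin(np.deg2rad(72.0))
    p = np.degrees(np.arctan2((nu[4] + nu[1]) - (nu[3] + nu[0]),
                              2.0 * nu[2] * (s36 + s72)))
    return p % 360.0


# glycosidic anchor shared by all base templates: every base places its
# glycosidic nitrogen and C1' at the same base-frame coordinates, so one
# sugar/backbone unit per form serves purines and pyrimidines alike
def _glycosidic_anchor():
    g = bases.BASE_TEMPLATES["G"]
    return g["C4"], g["N9"], g["C1'"]


def _sugar_backbone(form: FiberForm, chemistry: str,
                    chi: float, gamma: float, beta: float) -> Dict[str, np.ndarray]:
    """Sugar + backbone atoms in base-frame coordinates for given torsions."""
    tor = form.torsions
    cx, n, c1 = _glycosidic_anchor()
    coords: Dict[str, np.ndarray] = {}

    ring = np.array(closed_sugar_ring(form.pucker_phase, form.pucker_amplitude))
    ring_map = dict(zip(_RING_ATOMS, ring))
    ang_c1 = _angle(ring_map["O4'"], ring_map["C1'"], ring_map["C2'"])

    o4 = place_atom(cx, n, c1, np.linalg.norm(ring_map["O4'"] - ring_map["C1'"]),
                    108.2, chi)
    delta_t = _offset_for_angle(108.2, 114.0, ang_c1)
    # the branch sign selects the C1' epimer (which side of the glycosidic
    # bond the C2' arm leaves); fixed by backbone chain closure of built
    # duplexes to the beta-D configuration
    c2 = place_atom(cx, n, c1,
                    np.linalg.norm(ring_map["C2'"] - ring_map["C1'"]),
                    114.0, chi + _C2_BRANCH * delta_t)
    R, t, _ = kabsch(
        np.array([ring_map["C1'"], ring_map["O4'"], ring_map["C2'"]]),
        np.array([c1, o4, c2]))
    for a in ("O4'", "C2'", "C3'", "C4'"):
        coords[a] = R @ np.asarray(ring_map[a]) + t

    c2p, c3p, c4p, o4p = (coords[a] for a in ("C2'", "C3'", "C4'", "O4'"))
    ring_normal = np.cross(c2p - c1, o4p - c1)
    base_side = np.sign((n - c1) @ ring_normal)

    # C5' on the same ring face as the base (beta face)
    t_ring = dihedral_deg(c2p, c3p, c4p, o4p)
    for sign in (+1.0, -1.0):
        c5 = place_atom(c2p, c3p, c4p, 1.510, 115.0, t_ring + sign * 119.0)
        if np.sign((c5 - c4p) @ ring_normal) == base_side:
            break
    coords["C5'"] = c5
    coords["O3'"] = place_atom(c5, c4p, c3p, 1.423, 110.6, tor["delta"])
    coords["O5'"] = place_atom(c3p, c4p, c5, 1.440, 110.2, gamma)
    p = place_atom(c4p, c5, coords["O5'"], 1.593, 120.9, beta)
    coords["P"] = p
    coords["OP1"] = place_atom(c5, coords["O5'"], p, 1.485, 108.1,
                               tor["alpha"] + 115.0)
    coords["OP2"] = place_atom(c5, coords["O5'"], p, 1.485, 108.1,
                               tor["alpha"] - 115.0)

    if chemistry == "RNA":
        t2 = dihedral_deg(c4p, c3p, c2p, c1)
        for sign in (+1.0, -1.0):
            o2 = place_atom(c4p, c3p, c2p, 1.413, 110.0, t2 + sign * 120.0)
            if np.sign((o2 - c2p) @ ring_normal) == -base_side:
                break
        coords["O2'"] = o2
    return coords


@lru_cache(maxsize=8)
def _calibrated_torsions(form_name: str) -> Tuple[float, float, float]:
    """(χ, γ, β) refined so consecutive residues form a closed backbone.

    A rigid-residue fiber with the classical torsion targets leaves an
    O3'(i)—P(i+1) gap; the glycosidic and two exocyclic torsions are the
    free parameters that move the phosphate relative to the helix, so they
    are refined (starting from the classical values) until the O3'—P
    linkage has bond length 1.607 Å, a sensible C3'-O3'-P angle and ε near
    its target.
    """
    form = FORMS[form_name]
    tor = form.torsions
    frames = form.pair_frames(2)

    def closure(v):
        chi, gamma, beta = v
        bb = _sugar_backbone(form, "DNA", chi, gamma, beta)
        r1 = {a: frames[0].axes @ x + frames[0].origin for a, x in bb.items()}
        r2 = {a: frames[1].axes @ x + frames[1].origin for a, x in bb.items()}
        gap = np.linalg.norm(r2["P"] - r1["O3'"]) - 1.607
        ang = _angle(r1["C3'"], r1["O3'"], r2["P"]) - 119.7
        eps = dihedral_deg(r1["C4'"], r1["C3'"], r1["O3'"], r2["P"]) - tor["epsilon"]
        eps = (eps + 180.0) % 360.0 - 180.0
        zeta = dihedral_deg(r1["C3'"], r1["O3'"], r2["P"], r2["O5'"]) - tor["zeta"]
        zeta = (zeta + 180.0) % 360.0 - 180.0
        return [20.0 * gap, 0.05 * ang, 0.03 * eps, 0.03 * zeta]

    x0 = np.array([tor["chi"], tor["gamma"], tor["beta"]])
    sol = least_squares(closure, x0, diff_step=1e-6, xtol=1e-12, ftol=1e-12)
    return tuple(float(x) for x in sol.x)


@lru_cache(maxsize=64)
def nucleotide_template(base: str, chemistry: str,
                        form_name: str) -> Dict[str, np.ndarray]:
    """Full heavy-atom nucleotide in base-frame coordinates.

    Base atoms come from the planar templates; the sugar ring is closed at
    the form's pseudorotation target and attached through the glycosidic
    bond; exocyclic backbone atoms are placed at the form's torsion
    targets, with χ/γ/β refined for backbone chain closure.
    """
    form = FORMS[form_name]
    coords = {k: np.asarray(v, float).copy()
              for k, v in bases.BASE_TEMPLATES[base].items()}
    chi, gamma, beta = _calibrated_torsions(form_name)
    coords.update(_sugar_backbone(form, chemistry, chi, gamma, beta))
    return coords


def _angle(p1, p2, p3) -> float:
    from ._geom import angle_deg
    return angle_deg(p1, p2, p3)


# ---------------------------------------------------------------------------
# duplex assembly
# ---------------------------------------------------------------------------

_NO_5P = ("P", "OP1", "OP2")


def _residue_structure(letter: str, chemistry: str, form: FiberForm,
                       axes: np.ndarray, origin: np.ndarray, strand: str,
                       index: int, n_res: int, ps: bool) -> Structure:
    tmpl = nucleotide_template(letter, chemistry, form.name)
    names = [a for a in tmpl if a not in _NO_5P or index > 1]
    coords = np.array([axes @ tmpl[a] + origin for a in names])
    res_name = bases.residue_name(letter, chemistry)
    elements = []
    out_names = []
    for a, xyz in zip(names, coords):
        out_names.append(a)
        elements.append(a[0] if a[0] in "PONC" else a[0])
    s = Structure(
        np.array(out_names, dtype=object),
        np.array(elements, dtype=object),
        np.full(len(names), index),
        np.array([res_name] * len(names), dtype=object),
        np.array([strand] * len(names), dtype=object),
        coords,
        {(strand, index): "PS" if ps else "PO"},
    )
    if ps:
        s = _substitute_sulfur(s, (strand, index))
    return s


def _substitute_sulfur(res: Structure, key: ResidueKey) -> Structure:
    """Replace the OP1 non-bridging oxygen with the PS sulfur (bond 1.99 Å)."""
    atoms = res.residue_atoms(key)
    if "OP1" not in atoms or "P" not in atoms:
        raise ValueError(f"PS site {key} has no 5' phosphate")
    i_o, i_p = atoms["OP1"], atoms["P"]
    d = res.coords[i_o] - res.coords[i_p]
    res.coords[i_o] = res.coords[i_p] + 1.99 * d / np.linalg.norm(d)
    res.atom_names[i_o] = PS_SULFUR_NAME
    res.elements[i_o] = "S"
    return res


def build_duplex(seq: SequenceSpec, form: FiberForm) -> Structure:
    """Construct an ideal duplex for the sequence in the given fiber form.

    Strand "A" runs 5′→3′ with pair 1 at the start; strand "B" is its
    reverse complement.  PS sites carry the sulfur substitution and a
    ``PS`` linkage annotation.
    """
    n = seq.n_pairs
    if n < 2:
        raise ValueError("need at least 2 base pairs")
    frames = form.pair_frames(n)
    parts = []
    for i, fr in enumerate(frames, start=1):
        b1 = seq.strand1[i - 1]
        parts.append(_residue_structure(
            b1, seq.strand1_type, form, fr.axes, fr.origin, "A", i, n,
            ("A", i) in seq.ps_sites))
    for i, fr in enumerate(frames, start=1):
        j = n - i + 1                      # strand-2 residue paired with i
        b2 = seq.strand2[j - 1]
        axes2 = fr.axes @ bases.FLIP
        parts.append(_residue_structure(
            b2, seq.strand2_type, form, axes2, fr.origin, "B", j, n,
            ("B", j) in seq.ps_sites))
    order = sorted(range(n, 2 * n), key=lambda k: parts[k].res_indices[0])
    parts = parts[:n] + [parts[k] for k in order]
    return concat_structures(parts)


def duplex_pairing(seq: SequenceSpec) -> List[Tuple[ResidueKey, ResidueKey]]:
    n = seq.n_pairs
    return [(("A", i), ("B", n - i + 1)) for i in range(1, n + 1)]
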