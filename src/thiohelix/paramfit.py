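"""MM parameter derivation for the phosphorothioate backbone moiety.

Implements the desk-side half of a PS force-field parameterization:

* RESP charge fitting (least squares to an electrostatic-potential grid
  with the hyperbolic restraint, net-charge constrained);
* bond/angle force constants from a quantum-style Hessian — bonds via the
  interatomic sub-block eigenvalue projection, angles via the
  internal-coordinate compliance projection ``k = 1/(gᵀ H⁺ g)``;
* Fourier-series fitting of a torsion potential-energy scan;
* a small MM energy/force evaluator used to produce base energies and for
  recovery tests;
* the published PS parameter values packaged as fixtures (this work
  vs. the independently derived comparison set vs. the natural phosphate
  reference), and a comparison report between sets.

Units: kcal/mol energies, Å lengths, degrees for equilibrium angles and
phases, force constants kcal·mol⁻¹·Å⁻² (bonds) and kcal·mol⁻¹·rad⁻²
(angles), charges in elementary charge units.  The electrostatic grid
potential is in e/Å units, so model potentials are plain Σ qᵢ/rᵢ.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

COULOMB_CONSTANT = 332.0636   # kcal·mol⁻¹·Å·e⁻²

#: conventional RESP hyperbolic restraint constants (the tooling the
#: published values came from does not print its weights; these are the
#: standard single-stage defaults)
RESP_DEFAULT_A = 0.0005
RESP_DEFAULT_B = 0.1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeSet:
    molecule: str
    charges: Dict[str, float]             # atom name -> charge (e)
    net_charge: float

    def __post_init__(self):
        total = sum(self.charges.values())
        if abs(total - self.net_charge) > 1e-10:
            raise ValueError(
                f"charges sum to {total}, expected {self.net_charge}")

    def __getitem__(self, atom: str) -> float:
        return self.charges[atom]


@dataclass(frozen=True)
class BondParam:
    k: float          # kcal/mol/Å^2,  E = k (r - r_eq)^2
    r_eq: float       # Å

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("bond force constant must be positive")


@dataclass(frozen=True)
class AngleParam:
    k: float          # kcal/mol/rad^2,  E = k (θ - θ_eq)^2
    theta_eq: float   # degrees

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("angle force constant must be positive")
        if not 0.0 < self.theta_eq < 180.0:
            raise ValueError("theta_eq must be in (0, 180)")


@dataclass(frozen=True)
class DihedralTerm:
    n: int            # multiplicity
    k: float          # barrier height kcal/mol, >= 0
    phase: float      # degrees, 0 or 180

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("dihedral barrier must be >= 0")
        if self.phase not in (0.0, 180.0):
            raise ValueError("phase restricted to 0 or 180 degrees")


@dataclass(frozen=True)
class LJParam:
    epsilon: float    # kcal/mol well depth
    rmin_half: float  # Å


@dataclass
class TorsionScan:
    """Relative energies on a regular torsion grid (baseline-shifted to 0)."""

    angles: np.ndarray     # degrees
    energies: np.ndarray   # kcal/mol

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float)
        self.energies = np.asarray(self.energies, float)
        if self.angles.shape != self.energies.shape or self.angles.ndim != 1:
            raise ValueError("angles and energies must be matching 1-D arrays")
        d = np.diff(self.angles)
        if len(d) and not np.allclose(d, d[0], atol=1e-9):
            raise ValueError("angles must lie on a regular grid")
        self.energies = self.energies - self.energies.min()

    @property
    def pace(self) -> float:
        return float(self.angles[1] - self.angles[0])


@dataclass
class ESPGrid:
    points: np.ndarray       # (m, 3) Å
    potentials: np.ndarray   # (m,) e/Å units

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        self.potentials = np.asarray(self.potentials, float)
        if self.points.shape[0] != self.potentials.shape[0]:
            raise ValueError("points and potentials must match")


@dataclass
class HessianData:
    matrix: np.ndarray       # (3N, 3N) kcal/mol/Å^2
    coords: np.ndarray       # (N, 3) Å

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        self.coords = np.asarray(self.coords, float)
        n = self.coords.shape[0]
        if self.matrix.shape != (3 * n, 3 * n):
            raise ValueError("Hessian must be 3N x 3N")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-6):
            raise ValueError("Hessian must be symmetric within 1e-6")


@dataclass
class ParameterSet:
    """Charges + bonded terms + packaged Lennard-Jones constants."""

    label: str
    provenance: str                              # this_work | comparison | natural_reference
    charges: ChargeSet
    atom_types: Dict[str, str]                   # atom name -> type
    bonds: Dict[Tuple[str, str], BondParam] = field(default_factory=dict)
    angles: Dict[Tuple[str, str, str], AngleParam] = field(default_factory=dict)
    dihedrals: Dict[Tuple[str, str, str, str], List[DihedralTerm]] = field(default_factory=dict)
    lj: Dict[str, LJParam] = field(default_factory=dict)
    notes: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.bonds = {_canon_bond(k): v for k, v in self.bonds.items()}
        self.angles = {_canon_angle(k): v for k, v in self.angles.items()}
        self.dihedrals = {_canon_dihedral(k): v for k, v in self.dihedrals.items()}

    def bond(self, t1: str, t2: str) -> BondParam:
        return self.bonds[_canon_bond((t1, t2))]

    def angle(self, t1: str, t2: str, t3: str) -> AngleParam:
        return self.angles[_canon_angle((t1, t2, t3))]

    def numeric_fields(self):
        """Flat (path, value) list of every numeric entry, for comparisons."""
        out = []
        for a, q in sorted(self.charges.charges.items()):
            out.append((("charge", a), q))
        for k, b in sorted(self.bonds.items()):
            out.append((("bond", *k, "k"), b.k))
            out.append((("bond", *k, "r_eq"), b.r_eq))
        for k, a in sorted(self.angles.items()):
            out.append((("angle", *k, "k"), a.k))
            out.append((("angle", *k, "theta_eq"), a.theta_eq))
        for k, terms in sorted(self.dihedrals.items()):
            for t in terms:
                out.append((("dihedral", *k, t.n, "k"), t.k))
                out.append((("dihedral", *k, t.n, "phase"), t.phase))
        for t, p in sorted(self.lj.items()):
            out.append((("lj", t, "epsilon"), p.epsilon))
            out.append((("lj", t, "rmin_half"), p.rmin_half))
        return out


def _canon_bond(k):
    return tuple(sorted(k))


def _canon_angle(k):
    a, b, c = k
    return (a, b, c) if a <= c else (c, b, a)


def _canon_dihedral(k):
    return k if k <= k[::-1] else k[::-1]


# ---------------------------------------------------------------------------
# RESP charge fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RespResult:
    charges: ChargeSet
    rrms: float               # relative RMS of the potential fit
    iterations: int


def resp_fit(grid: ESPGrid, atom_coords: np.ndarray,
             atom_names: Sequence[str], net_charge: float,
             restraint_a: float = RESP_DEFAULT_A,
             restraint_b: float = RESP_DEFAULT_B,
             molecule: str = "DMPT", max_iter: int = 200,
             tol: float = 1e-12) -> RespResult:
    """Restrained electrostatic-potential charge fit.

    Minimizes ``Σ_k (V_k − Σ_i q_i/r_ik)² + a Σ_i (√(q_i²+b²) − b)``
    subject to ``Σ q_i = net_charge``, by the standard iteratively
    re-linearized solve of the KKT system.  With ``restraint_a = 0`` this
    is an exact constrained least squares.
    """
    coords = np.asarray(atom_coords, float)
    n = coords.shape[0]
    if grid.points.shape[0] <= n:
        raise ValueError("need more grid points than atoms")
    if restraint_a < 0:
        raise ValueError("restraint a must be >= 0")
    diff = grid.points[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.min(r) < 1e-6:
        raise ValueError("grid point coincides with an atom")
    if n > 1:
        dmin = min(np.linalg.norm(coords[i] - coords[j])
                   for i in range(n) for j in range(i + 1, n))
        if dmin < 1e-6:
            raise ValueError("coincident atoms: singular design")
    A = 1.0 / r
    AtA = A.T @ A
    Atv = A.T @ grid.potentials

    q = np.full(n, net_charge / n)
    for it in range(1, max_iter + 1):
        B = 2.0 * AtA
        if restraint_a > 0:
            B = B + np.diag(restraint_a / np.sqrt(q**2 + restraint_b**2))
        kkt = np.zeros((n + 1, n + 1))
        kkt[:n, :n] = B
        kkt[:n, n] = 1.0
        kkt[n, :n] = 1.0
        rhs = np.concatenate([2.0 * Atv, [net_charge]])
        sol = np.linalg.solve(kkt, rhs)
        q_new = sol[:n]
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    else:
        raise RuntimeError(f"RESP did not converge in {max_iter} iterations")
    # enforce the constraint exactly against round-off
    q = q + (net_charge - q.sum()) / n
    resid = A @ q - grid.potentials
    denom = np.linalg.norm(grid.potentials)
    rrms = float(np.linalg.norm(resid) / denom) if denom > 0 else 0.0
    charges = ChargeSet(molecule=molecule,
                        charges={a: float(c) for a, c in zip(atom_names, q)},
                        net_charge=float(net_charge))
    return RespResult(charges=charges, rrms=rrms, iterations=it)


# ---------------------------------------------------------------------------
# Hessian-based bond/angle parameters
# ---------------------------------------------------------------------------

def _bond_gradient(coords: np.ndarray, i: int, j: int) -> np.ndarray:
    u = coords[j] - coords[i]
    u = u / np.linalg.norm(u)
    g = np.zeros(coords.size)
    g[3 * i:3 * i + 3] = -u
    g[3 * j:3 * j + 3] = u
    return g


def hessian_bond(h: HessianData, i: int, j: int,
                 method: str = "compliance") -> BondParam:
    """Bond force constant from a quantum-style Hessian.

    The default projects the inverse Hessian onto the stretch coordinate,
    ``k = 1/(2 gᵀH⁺g)`` — exact for decoupled harmonic terms at the
    minimum.  ``method="seminario"`` eigen-decomposes the 3×3 interatomic
    sub-block ``−∂²E/∂x_i∂x_j`` and projects onto the bond direction
    (the classical construction; picks up small bend contamination in
    polyatomics).  The equilibrium length is read from the geometry.
    """
    u = h.coords[j] - h.coords[i]
    r_eq = float(np.linalg.norm(u))
    u = u / r_eq
    if method == "compliance":
        g = _bond_gradient(h.coords, i, j)
        hinv = np.linalg.pinv(h.matrix, rcond=1e-8)
        c = float(g @ hinv @ g)
        if c <= 0 or c > 1e6:
            raise ValueError(f"atoms {i},{j} appear non-bonded")
        return BondParam(k=1.0 / (2.0 * c), r_eq=r_eq)
    if method != "seminario":
        raise ValueError(f"unknown method {method!r}")
    sub = -h.matrix[3 * i:3 * i + 3, 3 * j:3 * j + 3]
    w, v = np.linalg.eig(0.5 * (sub + sub.T))
    # the sub-block of E = k (r - r_eq)^2 is 2k uu^T, hence the factor 1/2
    k = 0.5 * float(sum(lam * abs(u @ vec) for lam, vec in zip(w.real, v.T.real)))
    if k < 1e-6:
        raise ValueError(f"atoms {i},{j} appear non-bonded (k ≈ 0)")
    return BondParam(k=k, r_eq=r_eq)


def _angle_gradient(coords: np.ndarray, i: int, j: int, k: int) -> np.ndarray:
    """Wilson B-matrix row of the angle i-j-k (central j), radians/Å."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    ru, rv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / ru, v / rv
    cos_t = np.clip(uh @ vh, -1.0, 1.0)
    sin_t = np.sqrt(max(1.0 - cos_t**2, 1e-12))
    gi = (cos_t * uh - vh) / (ru * sin_t)
    gk = (cos_t * vh - uh) / (rv * sin_t)
    g = np.zeros(coords.size)
    g[3 * i:3 * i + 3] = gi
    g[3 * k:3 * k + 3] = gk
    g[3 * j:3 * j + 3] = -(gi + gk)
    return g


def hessian_angle(h: HessianData, i: int, j: int, k: int,
                  method: str = "compliance") -> AngleParam:
    """Angle force constant from the Hessian.

    The default route projects the inverse Hessian onto the angle's
    internal coordinate, ``k = 1 / (gᵀ H⁺ g)`` with ``g`` the Wilson
    B-row — exact for a decoupled harmonic force field at its minimum.
    ``method="seminario"`` uses the classical interatomic sub-block
    perpendicular projections instead (approximate away from 90° angles;
    kept as a cross-check).
    """
    from ._geom import angle_deg
    theta_eq = angle_deg(h.coords[i], h.coords[j], h.coords[k])
    if method == "compliance":
        g = _angle_gradient(h.coords, i, j, k)
        hinv = np.linalg.pinv(h.matrix, rcond=1e-8)
        c = float(g @ hinv @ g)
        if c <= 0:
            raise ValueError("non-positive compliance: atoms not coupled")
        kk = 1.0 / (2.0 * c)  # E = k (θ-θ0)^2 → d²E/dθ² = 2k = 1/compliance
        return AngleParam(k=kk, theta_eq=theta_eq)
    if method == "seminario":
        u = h.coords[i] - h.coords[j]
        v = h.coords[k] - h.coords[j]
        ru, rv = np.linalg.norm(u), np.linalg.norm(v)
        nrm = np.cross(u, v)
        nrm = nrm / np.linalg.norm(nrm)
        pa_i = np.cross(nrm, u / ru)
        pa_k = np.cross(v / rv, nrm)

        def proj(a, b, direction):
            sub = -h.matrix[3 * a:3 * a + 3, 3 * b:3 * b + 3]
            w, vec = np.linalg.eig(0.5 * (sub + sub.T))
            return float(sum(abs(lam) * abs(direction @ e)
                             for lam, e in zip(w.real, vec.T.real)))

        k1 = proj(i, j, pa_i)
        k2 = proj(k, j, pa_k)
        if k1 < 1e-9 or k2 < 1e-9:
            raise ValueError("near-zero eigen-projection: atoms not bonded")
        kk = 1.0 / (1.0 / (ru**2 * k1) + 1.0 / (rv**2 * k2))
        return AngleParam(k=kk, theta_eq=theta_eq)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# dihedral PES fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralFitResult:
    terms: List[DihedralTerm]
    rmse: float

    def energy(self, angles_deg) -> np.ndarray:
        phi = np.deg2rad(np.asarray(angles_deg, float))
        e = np.zeros_like(phi)
        for t in self.terms:
            e = e + t.k * (1.0 + np.cos(t.n * phi - np.deg2rad(t.phase)))
        return e


def fit_dihedral(scan: TorsionScan,
                 base_energy: Optional[np.ndarray] = None,
                 multiplicities: Iterable[int] = (1, 2, 3)) -> DihedralFitResult:
    """Least-squares Fourier fit of the residual torsion profile.

    The target ``scan − base_energy`` is fitted to
    ``Σ_n K_n (1 + cos(nφ − δ_n))`` with phases restricted to {0°, 180°},
    which keeps the problem linear: signed cosine coefficients are fitted
    and the sign absorbed into the phase.
    """
    mults = sorted(set(int(m) for m in multiplicities))
    if any(m < 1 for m in mults):
        raise ValueError("multiplicities must be positive")
    n_pts = len(scan.angles)
    if 360.0 % scan.pace > 1e-9 and (360.0 % scan.pace) < scan.pace - 1e-9:
        raise ValueError("grid pace must divide 360 degrees")
    if n_pts <= 2 * max(mults):
        raise ValueError("grid too coarse for requested multiplicities")
    target = scan.energies.copy()
    if base_energy is not None:
        base = np.asarray(base_energy, float)
        if base.shape != target.shape:
            raise ValueError("base_energy must match the scan grid")
        target = target - base
    phi = np.deg2rad(scan.angles)
    design = np.column_stack([np.cos(m * phi) for m in mults] +
                             [np.ones_like(phi)])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    terms = []
    for m, c in zip(mults, coef[:-1]):
        k = abs(float(c))
        phase = 0.0 if c >= 0 else 180.0
        terms.append(DihedralTerm(n=m, k=k, phase=phase))
    rmse = float(np.sqrt(np.mean((design @ coef - target) ** 2)))
    return DihedralFitResult(terms=terms, rmse=rmse)


# ---------------------------------------------------------------------------
# MM energy / force evaluator
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """Minimal molecular fragment: names, types, bonds, coordinates."""

    atom_names: List[str]
    atom_types: List[str]
    bonds: List[Tuple[int, int]]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.bonds = [tuple(sorted(b)) for b in self.bonds]

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def angles(self) -> List[Tuple[int, int, int]]:
        adj = {i: set() for i in range(self.n_atoms)}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        out = []
        for j in range(self.n_atoms):
            for a, c in itertools.combinations(sorted(adj[j]), 2):
                out.append((a, j, c))
        return out

    def dihedrals(self) -> List[Tuple[int, int, int, int]]:
        adj = {i: set() for i in range(self.n_atoms)}
        for a, b in self.bonds:
            adj[a].add(b)
            adj[b].add(a)
        out = []
        for b, c in self.bonds:
            for a in sorted(adj[b] - {c}):
                for d in sorted(adj[c] - {b}):
                    if a != d:
                        out.append((a, b, c, d))
        return out

def _bond_distance_matrix(n: int, bonds) -> np.ndarray:
    d = np.full((n, n), 10**6)
    np.fill_diagonal(d, 0)
    for a, b in bonds:
        d[a, b] = d[b, a] = 1
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def nonbonded_pairs(fragment: Fragment) -> List[Tuple[int, int]]:
    d = _bond_distance_matrix(fragment.n_atoms, fragment.bonds)
    return [(i, j) for i in range(fragment.n_atoms)
            for j in range(i + 1, fragment.n_atoms) if d[i, j] >= 3]


def mm_energy(fragment: Fragment, params: ParameterSet,
              coords: Optional[np.ndarray] = None,
              with_forces: bool = False):
    """Energy components (and optionally forces) of one conformation.

    Standard functional forms: harmonic bonds/angles, cosine dihedral
    series, Coulomb ``C q_i q_j / r`` with C = 332.0636, 12-6
    Lennard-Jones on 1-4-and-beyond pairs (unscaled).
    """
    x = np.asarray(coords if coords is not None else fragment.coords, float)
    t = fragment.atom_types
    comp = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0,
            "coulomb": 0.0, "lj": 0.0}
    forces = np.zeros_like(x)

    for i, j in fragment.bonds:
        key = _canon_bond((t[i], t[j]))
        if key not in params.bonds:
            raise KeyError(f"missing bond parameter {key}")
        p = params.bonds[key]
        d = x[j] - x[i]
        r = np.linalg.norm(d)
        comp["bond"] += p.k * (r - p.r_eq)**2
        if with_forces:
            f = 2.0 * p.k * (r - p.r_eq) * d / r
            forces[i] += f
            forces[j] -= f

    for i, j, k in fragment.angles():
        key = _canon_angle((t[i], t[j], t[k]))
        if key not in params.angles:
            raise KeyError(f"missing angle parameter {key}")
        p = params.angles[key]
        from ._geom import angle_deg
        th = math.radians(angle_deg(x[i], x[j], x[k]))
        th0 = math.radians(p.theta_eq)
        comp["angle"] += p.k * (th - th0)**2
        if with_forces:
            g = _angle_gradient(x, i, j, k).reshape(-1, 3)
            forces -= 2.0 * p.k * (th - th0) * g

    for quad in fragment.dihedrals():
        key = _canon_dihedral(tuple(t[a] for a in quad))
        terms = params.dihedrals.get(key)
        if terms is None:
            raise KeyError(f"missing dihedral parameter {key}")
        i, j, k, l = quad
        from ._geom import dihedral_deg
        phi = math.radians(dihedral_deg(x[i], x[j], x[k], x[l]))
        for term in terms:
            d0 = math.radians(term.phase)
            comp["dihedral"] += term.k * (1.0 + math.cos(term.n * phi - d0))
            if with_forces:
                dV = -term.k * term.n * math.sin(term.n * phi - d0)
                g = _dihedral_gradient(x, i, j, k, l).reshape(-1, 3)
                forces -= dV * g

    q = [params.charges.charges[a] for a in fragment.atom_names]
    for i, j in nonbonded_pairs(fragment):
        d = x[j] - x[i]
        r = np.linalg.norm(d)
        e_c = COULOMB_CONSTANT * q[i] * q[j] / r
        comp["coulomb"] += e_c
        lj_i, lj_j = params.lj[t[i]], params.lj[t[j]]
        eps = math.sqrt(lj_i.epsilon * lj_j.epsilon)
        rmin = lj_i.rmin_half + lj_j.rmin_half
        s6 = (rmin / r)**6
        comp["lj"] += eps * (s6 * s6 - 2.0 * s6)
        if with_forces:
            de = -e_c / r + eps * (-12.0 * s6 * s6 / r + 12.0 * s6 / r)
            f = de * d / r
            forces[i] += f
            forces[j] -= f

    comp["total"] = sum(v for k_, v in comp.items() if k_ != "total")
    if with_forces:
        return comp, forces
    return comp


def _dihedral_gradient(x: np.ndarray, i: int, j: int, k: int, l: int) -> np.ndarray:
    """∂φ/∂x for the torsion i-j-k-l (radians per Å)."""
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    # signs follow the IUPAC torsion convention used by dihedral_deg
    gi = nb2 / (n1 @ n1) * n1
    gl = -nb2 / (n2 @ n2) * n2
    s = (b1 @ b2) / (nb2**2)
    u = (b3 @ b2) / (nb2**2)
    gj = -(1.0 + s) * gi + u * gl
    gk = s * gi - (1.0 + u) * gl
    g = np.zeros_like(x)
    g[i], g[j], g[k], g[l] = gi, gj, gk, gl
    return g
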