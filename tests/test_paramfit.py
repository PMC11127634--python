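"""RESP charges, Hessian-derived bonded terms, dihedral PES fitting, MM energy."""

import numpy as np
import pytest

from thiohelix.paramfit import (AngleParam, BondParam, ChargeSet, DihedralTerm,
                                ESPGrid, Fragment, HessianData, LJParam,
                                ParameterSet, TorsionScan, fit_dihedral,
                                hessian_angle, hessian_bond, mm_energy,
                                resp_fit)
from thiohelix.ps_parameters import dmpt_fragment, load_published_ps_parameters


def _sphere_grid(rng, n, radii=(2.0, 4.0), centre=(0.0, 0.0, 0.0)):
    pts = rng.normal(0, 1, (n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= rng.uniform(*radii, n)[:, None]
    return pts + np.asarray(centre)


def _forward_potential(points, coords, charges):
    r = np.linalg.norm(points[:, None, :] - coords[None, :, :], axis=2)
    return (charges / r).sum(axis=1)


class TestRespFit:
    def test_single_atom_charge_recovered_exactly(self, rng):
        pts = _sphere_grid(rng, 80)
        coords = np.zeros((1, 3))
        grid = ESPGrid(pts, _forward_potential(pts, coords, np.array([0.93])))
        res = resp_fit(grid, coords, ["P"], 0.93, restraint_a=0.0)
        assert res.charges["P"] == pytest.approx(0.9300, abs=1e-8)

    def test_multi_atom_recovery_and_exact_conservation(self, rng):
        coords = rng.normal(0, 1.2, (5, 3))
        q_true = np.array([0.93, -0.7, -0.78, 0.3, -0.75])
        pts = _sphere_grid(rng, 300, radii=(3.0, 6.0))
        grid = ESPGrid(pts, _forward_potential(pts, coords, q_true))
        res = resp_fit(grid, coords, list("ABCDE"), q_true.sum(),
                       restraint_a=0.0)
        got = np.array([res.charges[a] for a in "ABCDE"])
        assert np.allclose(got, q_true, atol=1e-6)
        assert sum(res.charges.charges.values()) == pytest.approx(
            q_true.sum(), abs=1e-12)

    def test_strong_restraint_drives_symmetric_charges_to_zero(self, rng):
        coords = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        pts = _sphere_grid(rng, 200, radii=(3.0, 5.0))
        grid = ESPGrid(pts, _forward_potential(pts, coords,
                                               np.array([0.4, -0.4])))
        res = resp_fit(grid, coords, ["A", "B"], 0.0, restraint_a=1e6)
        assert abs(res.charges["A"]) < 1e-3
        assert abs(res.charges["B"]) < 1e-3

    def test_too_few_grid_points_rejected(self, rng):
        grid = ESPGrid(np.ones((2, 3)), np.ones(2))
        with pytest.raises(ValueError):
            resp_fit(grid, np.zeros((3, 3)) + np.arange(3)[:, None],
                     list("ABC"), 0.0)


def _diatomic_hessian(k, r0):
    u = np.array([1.0, 0.0, 0.0])
    blk = 2 * k * np.outer(u, u)
    h = np.block([[blk, -blk], [-blk, blk]])
    coords = np.array([[0.0, 0, 0], [r0, 0, 0]])
    return HessianData(h, coords)


def _fd_hessian(fragment, params, h=1e-4):
    x0 = fragment.coords.flatten()
    n = x0.size
    H = np.zeros((n, n))

    def e(v):
        return mm_energy(fragment, params, v.reshape(-1, 3))["total"]

    for a in range(n):
        for b in range(a, n):
            xs = [x0.copy() for _ in range(4)]
            xs[0][a] += h; xs[0][b] += h
            xs[1][a] += h; xs[1][b] -= h
            xs[2][a] -= h; xs[2][b] += h
            xs[3][a] -= h; xs[3][b] -= h
            H[a, b] = H[b, a] = (e(xs[0]) - e(xs[1]) - e(xs[2]) + e(xs[3])) / (4 * h * h)
    return HessianData(H, fragment.coords)


def _triatomic(k_bond=300.0, k_angle=80.0, r0=1.5, theta0=104.5):
    ps = ParameterSet(
        label="triatomic", provenance="this_work",
        charges=ChargeSet("tri", {"A1": 0.0, "A2": 0.0, "A3": 0.0}, 0.0),
        atom_types={"A1": "X", "A2": "Y", "A3": "X"},
        bonds={("X", "Y"): BondParam(k_bond, r0)},
        angles={("X", "Y", "X"): AngleParam(k_angle, theta0)},
    )
    th = np.deg2rad(theta0)
    coords = np.array([[r0, 0, 0], [0, 0, 0],
                       [r0 * np.cos(th), r0 * np.sin(th), 0]])
    frag = Fragment(["A1", "A2", "A3"], ["X", "Y", "X"],
                    [(0, 1), (1, 2)], coords)
    return frag, ps


class TestHessianParameters:
    def test_analytic_diatomic_bond_recovery(self):
        for method in ("compliance", "seminario"):
            bp = hessian_bond(_diatomic_hessian(500.0, 2.0), 0, 1,
                              method=method)
            assert bp.k == pytest.approx(500.0, abs=1e-6)
            assert bp.r_eq == pytest.approx(2.0, abs=1e-12)

    def test_equilibria_read_from_geometry(self):
        frag, ps = _triatomic()
        hd = _fd_hessian(frag, ps)
        assert hessian_bond(hd, 0, 1).r_eq == pytest.approx(1.5, abs=1e-12)
        assert hessian_angle(hd, 0, 1, 2).theta_eq == pytest.approx(
            104.5, abs=1e-9)

    def test_finite_difference_triatomic_recovery_within_one_percent(self):
        frag, ps = _triatomic(k_bond=300.0, k_angle=80.0)
        hd = _fd_hessian(frag, ps)
        assert hessian_bond(hd, 0, 1).k == pytest.approx(300.0, rel=0.01)
        assert hessian_bond(hd, 1, 2).k == pytest.approx(300.0, rel=0.01)
        assert hessian_angle(hd, 0, 1, 2).k == pytest.approx(80.0, rel=0.01)

    def test_non_interacting_pair_rejected(self):
        # two atoms with no coupling at all: empty interatomic sub-block
        hd = HessianData(np.zeros((6, 6)), np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        with pytest.raises(ValueError):
            hessian_bond(hd, 0, 1, method="seminario")


class TestFitDihedral:
    def test_noiseless_recovery_on_15_degree_grid(self):
        angles = np.arange(0.0, 360.0, 15.0)
        phi = np.deg2rad(angles)
        energies = (1.2 * (1 + np.cos(phi)) + 0.5 * (1 + np.cos(2 * phi))
                    + 1.8 * (1 + np.cos(3 * phi)))
        fit = fit_dihedral(TorsionScan(angles, energies))
        by_n = {t.n: t for t in fit.terms}
        assert by_n[1].k == pytest.approx(1.2, abs=1e-8)
        assert by_n[2].k == pytest.approx(0.5, abs=1e-8)
        assert by_n[3].k == pytest.approx(1.8, abs=1e-8)
        assert all(t.phase == 0.0 for t in fit.terms)
        assert fit.rmse < 1e-10

    def test_negative_coefficient_becomes_180_phase(self):
        angles = np.arange(0.0, 360.0, 15.0)
        phi = np.deg2rad(angles)
        energies = 0.9 * (1 + np.cos(2 * phi - np.pi))
        fit = fit_dihedral(TorsionScan(angles, energies))
        by_n = {t.n: t for t in fit.terms}
        assert by_n[2].k == pytest.approx(0.9, abs=1e-8)
        assert by_n[2].phase == 180.0

    def test_constant_pes_gives_zero_barriers(self):
        angles = np.arange(0.0, 360.0, 15.0)
        fit = fit_dihedral(TorsionScan(angles, np.full(24, 2.5)))
        assert all(t.k == pytest.approx(0.0, abs=1e-10) for t in fit.terms)

    def test_noise_robustness_over_seeded_replicates(self):
        angles = np.arange(0.0, 360.0, 15.0)
        phi = np.deg2rad(angles)
        clean = (1.2 * (1 + np.cos(phi)) + 0.5 * (1 + np.cos(2 * phi))
                 + 1.8 * (1 + np.cos(3 * phi)))
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean + rng.normal(0, 0.05, clean.shape)
            fit = fit_dihedral(TorsionScan(angles, noisy))
            assert fit.rmse <= 0.1

    def test_base_energy_subtracted_before_fitting(self):
        angles = np.arange(0.0, 360.0, 15.0)
        phi = np.deg2rad(angles)
        target = 0.7 * (1 + np.cos(3 * phi))
        base = 2.0 * (1 + np.cos(phi))
        fit = fit_dihedral(TorsionScan(angles, target + base), base_energy=base)
        by_n = {t.n: t for t in fit.terms}
        assert by_n[3].k == pytest.approx(0.7, abs=1e-8)
        assert by_n[1].k == pytest.approx(0.0, abs=1e-8)

    def test_coarse_grid_rejected(self):
        angles = np.arange(0.0, 360.0, 60.0)
        with pytest.raises(ValueError, match="coarse"):
            fit_dihedral(TorsionScan(angles, np.zeros(6)),
                         multiplicities=(1, 2, 3))


class TestMMEnergy:
    def test_bond_at_equilibrium_is_zero(self):
        frag, ps = _triatomic()
        comp = mm_energy(frag, ps)
        assert comp["bond"] == pytest.approx(0.0, abs=1e-18)
        assert comp["angle"] == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        eps, rmin_half = 0.25, 1.9
        ps = ParameterSet(
            label="pair", provenance="this_work",
            charges=ChargeSet("pair", {f"A{i}": 0.0 for i in range(4)}, 0.0),
            atom_types={f"A{i}": "X" for i in range(4)},
            bonds={("X", "X"): BondParam(300.0, 1.5)},
            angles={("X", "X", "X"): AngleParam(50.0, 120.0)},
            dihedrals={("X", "X", "X", "X"): [DihedralTerm(3, 0.0, 0.0)]},
            lj={"X": LJParam(eps, rmin_half)},
        )
        # linear 4-atom chain whose 1-4 pair sits at the LJ minimum
        rmin = 2 * rmin_half
        coords = np.array([[0.0, 0, 0], [1.5, 0.6, 0], [rmin - 1.5, -0.6, 0],
                           [rmin, 0.0, 0]])
        frag = Fragment([f"A{i}" for i in range(4)],
                        ["X"] * 4, [(0, 1), (1, 2), (2, 3)], coords)
        comp = mm_energy(frag, ps)
        assert comp["lj"] == pytest.approx(-eps, abs=1e-12)

    def test_coulomb_unit_charges_at_one_angstrom(self):
        ps = ParameterSet(
            label="qq", provenance="this_work",
            charges=ChargeSet("qq", {"A0": 1.0, "A1": 0.0, "A2": 0.0,
                                     "A3": 1.0}, 2.0),
            atom_types={f"A{i}": "X" for i in range(4)},
            bonds={("X", "X"): BondParam(300.0, 1.0)},
            angles={("X", "X", "X"): AngleParam(50.0, 90.0)},
            dihedrals={("X", "X", "X", "X"): [DihedralTerm(1, 0.0, 0.0)]},
            lj={"X": LJParam(0.0, 1.0)},
        )
        coords = np.array([[0.0, 0, 0], [0, 1, 0], [1, 1, 0], [1, 0, 0]])
        frag = Fragment([f"A{i}" for i in range(4)], ["X"] * 4,
                        [(0, 1), (1, 2), (2, 3)], coords)
        comp = mm_energy(frag, ps)
        assert comp["coulomb"] == pytest.approx(332.0636, abs=1e-10)

    def test_missing_parameter_raises(self):
        frag, ps = _triatomic()
        ps.angles = {}
        with pytest.raises(KeyError, match="angle"):
            mm_energy(frag, ps)

    def test_forces_match_central_finite_differences(self):
        frag = dmpt_fragment()
        params = load_published_ps_parameters("this_work")
        comp, forces = mm_energy(frag, params, with_forces=True)
        h = 1e-5
        x0 = frag.coords
        for i in (0, 1, 4, 7):            # P, S, an oxygen, a hydrogen
            for c in range(3):
                xp, xm = x0.copy(), x0.copy()
                xp[i, c] += h
                xm[i, c] -= h
                fd = -(mm_energy(frag, params, xp)["total"]
                       - mm_energy(frag, params, xm)["total"]) / (2 * h)
                assert forces[i, c] == pytest.approx(fd, abs=1e-4)
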