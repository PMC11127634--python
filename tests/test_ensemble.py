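"""Trajectory statistics: superposition, RMSD/RMSF, clustering, bimodality."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from thiohelix.core import Structure, Trajectory
from thiohelix.ensemble import (DistSummary, distribution_summary,
                                gromos_cluster, interstrand_p_distances,
                                pairwise_rmsd_matrix, rmsd_series, rmsf,
                                superpose)
from thiohelix.fiber import B_FORM, SequenceSpec, build_duplex, duplex_pairing


def _transformed(s, seed=0, shift=(3.0, -1.0, 2.0)):
    out = s.copy()
    R = Rotation.random(random_state=seed).as_matrix()
    out.coords = s.coords @ R.T + np.asarray(shift)
    return out


def _jittered(s, sigma, rng):
    out = s.copy()
    out.coords = s.coords + rng.normal(0, sigma, s.coords.shape)
    return out


def _brute_force_rmsd(mobile, target):
    """Direct numeric minimization over rotation vector + translation."""
    def cost(v):
        R = Rotation.from_rotvec(v[:3]).as_matrix()
        d = mobile @ R.T + v[3:] - target
        return np.sqrt((d**2).sum() / len(mobile))
    best = min(
        (minimize(cost, np.concatenate([rv, [0, 0, 0]]), method="Nelder-Mead",
                  options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
         for rv in ([0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5],
                    [2.2, 2.2, 0])),
        key=lambda r: r.fun)
    return best.fun


class TestSuperpose:
    def test_identical_structures_rmsd_zero(self, gc_duplex):
        _, _, r = superpose(gc_duplex, gc_duplex)
        assert r < 1e-12

    def test_rigid_copy_recovers_transform(self, gc_duplex):
        moved = _transformed(gc_duplex, seed=5)
        R, t, r = superpose(gc_duplex, moved)
        assert r < 1e-9
        back = gc_duplex.coords @ R.T + t
        assert np.abs(back - moved.coords).max() < 1e-8

    def test_rmsd_matches_numeric_minimization(self, rng, gc_duplex):
        noisy = _jittered(gc_duplex, 0.4, rng)
        _, _, r = superpose(gc_duplex, noisy, selection="P")
        idx = gc_duplex.select("P")
        oracle = _brute_force_rmsd(gc_duplex.coords[idx], noisy.coords[idx])
        assert r == pytest.approx(oracle, abs=1e-6)

    def test_mismatched_selections_raise(self, gc_duplex):
        short = build_duplex(SequenceSpec("GC"), B_FORM)
        with pytest.raises(ValueError):
            superpose(short, gc_duplex, "P")


class TestRmsdSeries:
    def test_rigidly_moved_frames_give_zero(self, gc_duplex):
        traj = Trajectory([_transformed(gc_duplex, seed=k) for k in range(4)])
        assert np.abs(rmsd_series(traj, gc_duplex, "P")).max() < 1e-9

    def test_isotropic_noise_mean_rmsd(self, rng, gc_duplex):
        sigma = 0.3
        traj = Trajectory([_jittered(gc_duplex, sigma, rng)
                           for _ in range(40)])
        r = rmsd_series(traj, gc_duplex, "heavy")
        # sqrt(3) sigma, slightly reduced by the 6-dof superposition fit
        n = len(gc_duplex.select("heavy"))
        expect = sigma * np.sqrt(3.0) * np.sqrt(1.0 - 2.0 / n)
        assert r.mean() == pytest.approx(expect, rel=0.05)


class TestRmsf:
    def test_static_trajectory_is_zero(self, gc_duplex):
        traj = Trajectory([gc_duplex.copy() for _ in range(5)])
        assert rmsf(traj)["rmsf"].max() < 1e-12

    def test_alternating_displacement_closed_form(self, gc_duplex):
        d = 0.7
        lo, hi = gc_duplex.copy(), gc_duplex.copy()
        hi.coords = hi.coords.copy()
        idx = gc_duplex.residue_atoms(("A", 3))["P"]
        lo.coords[idx, 0] -= d
        hi.coords[idx, 0] += d
        traj = Trajectory([lo, hi, lo, hi])
        out = rmsf(traj, selection="P", fit=False)
        row = out[(out.strand == "A") & (out.residue == 3)]
        assert row.rmsf.iloc[0] == pytest.approx(d, abs=1e-12)

    def test_gaussian_noise_matches_sqrt3_sigma(self, rng, gc_duplex):
        sigma = 0.25
        traj = Trajectory([_jittered(gc_duplex, sigma, rng)
                           for _ in range(5000)])
        out = rmsf(traj, selection="P", fit=False)
        assert np.allclose(out.rmsf, sigma * np.sqrt(3), rtol=0.05)

    def test_invariant_under_frame_reversal(self, rng, gc_duplex):
        frames = [_jittered(gc_duplex, 0.2, rng) for _ in range(10)]
        a = rmsf(Trajectory(frames))["rmsf"]
        b = rmsf(Trajectory(frames[::-1]))["rmsf"]
        assert np.allclose(a, b, atol=1e-12)


class TestInterstrandPDistances:
    def test_simple_two_atom_distance(self):
        s = Structure(
            np.array(["P", "P"], dtype=object),
            np.array(["P", "P"], dtype=object),
            np.array([2, 2]), np.array(["DG", "DC"], dtype=object),
            np.array(["A", "B"], dtype=object),
            np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        out = interstrand_p_distances(s, [(("A", 2), ("B", 2))])
        assert out["mean"].iloc[0] == pytest.approx(5.0)

    def test_fiber_symmetry_of_interior_pairs(self, gc_duplex, gc_spec):
        out = interstrand_p_distances(gc_duplex, duplex_pairing(gc_spec))
        interior = out[out.defined].iloc[1:-1]
        assert interior["mean"].max() - interior["mean"].min() < 0.1

    def test_terminal_pairs_flagged_undefined(self, gc_duplex, gc_spec):
        out = interstrand_p_distances(gc_duplex, duplex_pairing(gc_spec))
        # each terminal pair contains one 5'-OH residue without P
        assert not out.iloc[0].defined
        assert not out.iloc[-1].defined


def _two_basin_trajectory(n_per_basin=20, separation=8.0, seed=0):
    """Two well-separated conformational basins with small internal noise."""
    s = build_duplex(SequenceSpec("GCGC"), B_FORM)
    rng = np.random.default_rng(seed)
    frames = []
    for basin in (0.0, separation):
        for _ in range(n_per_basin):
            f = s.copy()
            f.coords = s.coords + rng.normal(0, 0.05, s.coords.shape)
            # displace one strand: an internal deformation that global
            # superposition cannot remove
            f.coords[f.strand_ids == "A"] += np.array([basin, 0.0, 0.0])
            frames.append(f)
    return Trajectory(frames)


def _gromos_oracle(m, cutoff):
    """Exhaustive neighbour-count clustering on a distance matrix."""
    n = m.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        idx = sorted(remaining)
        counts = [(sum(m[i, j] <= cutoff for j in idx), -i) for i in idx]
        best = max(range(len(idx)), key=lambda k: counts[k])
        centre = idx[best]
        members = {j for j in idx if m[centre, j] <= cutoff}
        clusters.append((centre, members))
        remaining -= members
    return clusters


class TestGromosClustering:
    def test_huge_cutoff_single_cluster(self):
        traj = _two_basin_trajectory(5)
        res = gromos_cluster(traj, cutoff_nm=100.0)
        assert res.n_clusters == 1
        assert res.sizes == [traj.n_frames]

    def test_tiny_cutoff_all_singletons(self):
        traj = _two_basin_trajectory(5)
        res = gromos_cluster(traj, cutoff_nm=1e-6)
        assert res.n_clusters == traj.n_frames
        assert all(s == 1 for s in res.sizes)

    def test_two_basin_recovery_matches_exhaustive_oracle(self):
        traj = _two_basin_trajectory(20)
        res = gromos_cluster(traj, cutoff_nm=0.2)
        assert res.n_clusters == 2
        assert sorted(res.sizes) == [20, 20]
        m = pairwise_rmsd_matrix(traj, "heavy")
        oracle = _gromos_oracle(m, 0.2 * 10.0)
        assert len(oracle) == 2
        got = {frozenset(np.nonzero(res.assignments == c + 1)[0])
               for c in range(res.n_clusters)}
        want = {frozenset(members) for _, members in oracle}
        assert got == want

    def test_partition_properties(self):
        traj = _two_basin_trajectory(8, seed=3)
        res = gromos_cluster(traj, cutoff_nm=0.15)
        assert (res.assignments >= 1).all()
        assert sum(res.sizes) == traj.n_frames
        assert res.sizes == sorted(res.sizes, reverse=True)
        rerun = gromos_cluster(traj, cutoff_nm=0.15)
        assert np.array_equal(res.assignments, rerun.assignments)


class TestDistributionSummary:
    def test_constant_series(self):
        s = distribution_summary(np.full(100, 36.0))
        assert s.sd == 0.0
        assert not s.bimodal

    def test_single_gaussian_not_bimodal(self):
        rng = np.random.default_rng(123)
        x = rng.normal(36.0, 1.5, 5000)
        s = distribution_summary(x)
        assert not s.bimodal

    def test_twist_mixture_flagged_bimodal(self):
        # the high/low twist-state scenario: 30.5 and 36.5 deg components
        rng = np.random.default_rng(456)
        x = np.concatenate([rng.normal(30.5, 1.5, 2500),
                            rng.normal(36.5, 1.5, 2500)])
        s = distribution_summary(x)
        assert s.bimodal
        lo, hi = s.component_means
        assert lo == pytest.approx(30.5, abs=0.5)
        assert hi == pytest.approx(36.5, abs=0.5)

    def test_small_samples_never_bimodal(self):
        s = distribution_summary(np.r_[np.zeros(20), np.ones(20)])
        assert not s.bimodal
        assert s.note is not None

    def test_histogram_counts_sum_to_sample_size(self, rng):
        x = rng.normal(0, 1, 777)
        s = distribution_summary(x, bins=31)
        assert s.counts.sum() == 777

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            distribution_summary([])
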