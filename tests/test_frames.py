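"""Base-frame assignment, pair-frame averaging and pair detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation, Slerp

from thiohelix import bases
from thiohelix.core import Structure, concat_structures
from thiohelix.fiber import B_FORM, SequenceSpec, build_duplex, duplex_pairing
from thiohelix.frames import (BaseFrame, assign_base_frame, detect_pairing,
                              pair_frame)


def _base_structure(letter, coords_map, strand="A", index=1):
    names = list(coords_map)
    res_name = "D" + letter if letter != "U" else "U"
    return Structure(
        np.array(names, dtype=object),
        np.array([n[0] for n in names], dtype=object),
        np.full(len(names), index),
        np.array([res_name] * len(names), dtype=object),
        np.array([strand] * len(names), dtype=object),
        np.array([coords_map[n] for n in names]),
    )


def _template_structure(letter, R=np.eye(3), t=np.zeros(3), jitter=None, rng=None):
    tmpl = bases.BASE_TEMPLATES[letter]
    coords = {a: R @ x + t for a, x in tmpl.items()}
    if jitter is not None:
        coords = {a: x + rng.normal(0, jitter, 3) for a, x in coords.items()}
    return _base_structure(letter, coords)


class TestAssignBaseFrame:
    def test_template_placement_gives_identity_frame(self):
        s = _template_structure("G")
        f = assign_base_frame(s, ("A", 1))
        assert np.allclose(f.axes, np.eye(3), atol=1e-9)
        assert np.allclose(f.origin, 0.0, atol=1e-9)

    def test_recovers_known_rigid_transform(self):
        R = Rotation.from_euler("zyx", [40, -25, 100], degrees=True).as_matrix()
        t = np.array([3.0, -1.0, 7.5])
        f = assign_base_frame(_template_structure("C", R, t), ("A", 1))
        assert np.allclose(f.axes, R, atol=1e-9)
        assert np.allclose(f.origin, t, atol=1e-9)

    def test_noise_bounded_rotation_and_exact_orthonormality(self, rng):
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        s = _template_structure("A", R, np.zeros(3), jitter=0.05, rng=rng)
        f = assign_base_frame(s, ("A", 1))
        dev = Rotation.from_matrix(f.axes.T @ R).magnitude()
        assert dev < 0.05
        assert np.allclose(f.axes.T @ f.axes, np.eye(3), atol=1e-12)

    def test_equivariance_under_rigid_motion(self, rng, gc_duplex):
        key = ("A", 3)
        f0 = assign_base_frame(gc_duplex, key)
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([5.0, 1.0, -4.0])
        moved = gc_duplex.copy()
        moved.coords = gc_duplex.coords @ R.T + t
        f1 = assign_base_frame(moved, key)
        assert np.allclose(f1.axes, R @ f0.axes, atol=1e-9)
        assert np.allclose(f1.origin, R @ f0.origin + t, atol=1e-9)

    def test_missing_ring_atoms_raise(self, gc_duplex):
        broken = gc_duplex.copy()
        mask = ~((broken.strand_ids == "A") & (broken.res_indices == 1)
                 & (broken.atom_names == "N9"))
        broken = Structure(broken.atom_names[mask], broken.elements[mask],
                           broken.res_indices[mask], broken.res_names[mask],
                           broken.strand_ids[mask], broken.coords[mask])
        with pytest.raises(ValueError, match="ring atoms"):
            assign_base_frame(broken, ("A", 1))


class TestPairFrame:
    def test_flip_image_pair_returns_first_frame(self):
        R = Rotation.from_euler("zxz", [30, 10, -20], degrees=True).as_matrix()
        o = np.array([1.0, 2.0, 3.0])
        f1 = BaseFrame(o, R, ("A", 1))
        f2 = BaseFrame(o, R @ bases.FLIP, ("B", 1))
        pf = pair_frame(f1, f2)
        assert np.allclose(pf.axes, R, atol=1e-12)
        assert np.allclose(pf.origin, o, atol=1e-12)

    def test_mid_frame_matches_slerp_oracle(self):
        r1 = Rotation.from_euler("xyz", [5, 10, 15], degrees=True)
        rel = Rotation.from_rotvec([0.2, -0.1, 0.3])
        r2_flipped = r1 * rel
        slerp = Slerp([0, 1], Rotation.concatenate([r1, r2_flipped]))
        mid = slerp(0.5).as_matrix()
        f1 = BaseFrame(np.zeros(3), r1.as_matrix(), ("A", 1))
        f2 = BaseFrame(np.array([0, 0, 1.0]),
                       r2_flipped.as_matrix() @ bases.FLIP, ("B", 1))
        pf = pair_frame(f1, f2)
        assert np.allclose(pf.axes, mid, atol=1e-10)
        assert np.allclose(pf.origin, [0, 0, 0.5], atol=1e-12)

    def test_propeller_twist_cancels(self):
        # frames rotated +/- p/2 about the shared y axis average to identity
        p = 24.0
        ry = lambda a: Rotation.from_euler("y", a, degrees=True).as_matrix()
        f1 = BaseFrame(np.zeros(3), ry(p / 2), ("A", 1))
        f2 = BaseFrame(np.zeros(3), ry(-p / 2) @ bases.FLIP, ("B", 1))
        pf = pair_frame(f1, f2)
        assert np.allclose(pf.axes, np.eye(3), atol=1e-12)

    def test_antialigned_frames_rejected(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3), ("A", 1))
        # partner with z pointing the same way as f1 before the flip
        f2 = BaseFrame(np.zeros(3), np.diag([-1.0, 1.0, -1.0]) @ bases.FLIP,
                       ("B", 1))
        with pytest.raises(ValueError, match="not pairable"):
            pair_frame(f1, f2)


class TestDetectPairing:
    def test_duplex_fully_paired(self, gc_duplex, gc_spec):
        assert detect_pairing(gc_duplex) == duplex_pairing(gc_spec)

    def test_hybrid_fully_paired(self, hybrid_duplex, hybrid_spec):
        assert detect_pairing(hybrid_duplex) == duplex_pairing(hybrid_spec)

    def test_single_strand_has_no_pairs(self, gc_duplex):
        mask = gc_duplex.strand_ids == "A"
        single = Structure(
            gc_duplex.atom_names[mask], gc_duplex.elements[mask],
            gc_duplex.res_indices[mask], gc_duplex.res_names[mask],
            gc_duplex.strand_ids[mask], gc_duplex.coords[mask])
        assert detect_pairing(single) == []

    def test_hairpin_stem_pairs_loop_and_bulge_unpaired(self):
        # stem + single-nucleotide bulge + 4-nt loop, folded onto one strand
        stem = build_duplex(SequenceSpec("GCGCG"), B_FORM)
        n = 5
        names, elems, res, rnames, strands, coords = [], [], [], [], [], []
        offset = {}
        new_index = {}
        counter = 0
        for i in range(1, n + 1):          # 5' stem arm
            counter += 1
            new_index[("A", i)] = counter
        counter += 1                        # bulge after the first arm
        bulge_idx = counter
        for i in range(4):                  # loop
            counter += 1
        loop_last = counter
        for i in range(n, 0, -1):           # 3' stem arm (strand B reversed)
            counter += 1
            new_index[("B", i)] = counter
        for a in range(stem.n_atoms):
            key = (stem.strand_ids[a], int(stem.res_indices[a]))
            names.append(stem.atom_names[a])
            elems.append(stem.elements[a])
            res.append(new_index[key])
            rnames.append(stem.res_names[a])
            strands.append("A")
            coords.append(stem.coords[a])
        # bulge + loop residues: far-away bases, no partners
        from thiohelix import bases as _b
        far = np.array([60.0, 0.0, 0.0])
        for k, letter in enumerate(["A", "T", "T", "A", "G"]):
            idx = bulge_idx if k == 0 else bulge_idx + k
            for atom, xyz in _b.BASE_TEMPLATES[letter].items():
                names.append(atom)
                elems.append(atom[0])
                res.append(idx)
                rnames.append("D" + letter)
                strands.append("A")
                coords.append(xyz + far + np.array([0, 0, 6.0 * k]))
        hairpin = Structure(
            np.array(names, dtype=object), np.array(elems, dtype=object),
            np.array(res, int), np.array(rnames, dtype=object),
            np.array(strands, dtype=object), np.array(coords))
        pairs = detect_pairing(hairpin)
        paired = {r for p in pairs for r in p}
        assert len(pairs) == n
        for k in range(bulge_idx, loop_last + 1):
            assert ("A", k) not in paired
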