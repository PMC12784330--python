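"""Molecule extraction, cluster building, Kabsch superposition and the
packing-similarity overlay, including the polytype signature."""
import itertools

import numpy as np
import pytest

from crystherm.packing import (
    Cluster,
    MoleculeInstance,
    build_cluster,
    extract_molecules,
    kabsch_superpose,
    overlay,
)
from crystherm.structures import CrystalStructure, Site, UnitCell
from crystherm.synthetic import PolytypeSpec, make_polytype_pair


def _water_like(cell=10.0, offset=(0.0, 0.0, 0.0)):
    """One bent 3-atom molecule in a P1 cubic cell."""
    ox, oy, oz = offset
    sites = [
        Site("O", ((0.0 + ox) / cell, (0.0 + oy) / cell, (0.0 + oz) / cell)),
        Site("H", ((0.96 + ox) / cell, (0.0 + oy) / cell, (0.0 + oz) / cell)),
        Site("H", ((-0.24 + ox) / cell, (0.93 + oy) / cell, (0.0 + oz) / cell)),
    ]
    return CrystalStructure(UnitCell(cell, cell, cell), sites)


def _rotate_cluster(cluster: Cluster, rot: np.ndarray, shift: np.ndarray) -> Cluster:
    mols = [MoleculeInstance(m.elements, m.coords @ rot.T + shift, m.origin)
            for m in cluster.molecules]
    return Cluster(mols, cluster.structure_name)


def _rotation(axis, angle_deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


class TestExtractMolecules:
    def test_single_molecule_in_p1(self):
        mols = extract_molecules(_water_like())
        assert len(mols) == 1
        assert mols[0].elements == ("O", "H", "H")

    def test_boundary_crossing_molecule_reassembled(self):
        whole = extract_molecules(_water_like())[0]
        ref = np.linalg.norm(whole.coords[0] - whole.coords[1])
        split = extract_molecules(_water_like(offset=(9.9, 9.8, 0.05)))
        assert len(split) == 1
        d = np.linalg.norm(split[0].coords[0] - split[0].coords[1])
        assert d == pytest.approx(ref, abs=1e-9)
        # all intramolecular distances preserved, not just one bond
        def dists(m):
            return sorted(np.linalg.norm(a - b)
                          for a, b in itertools.combinations(m.coords, 2))
        np.testing.assert_allclose(dists(split[0]), dists(whole), atol=1e-9)

    def test_two_congruent_molecules_per_cell(self):
        cell = 10.0
        sites = []
        for off in ((0.0, 0.0, 0.0), (5.0, 5.0, 5.0)):
            for s in _water_like(offset=off).sites:
                sites.append(s)
        mols = extract_molecules(CrystalStructure(UnitCell(cell, cell, cell), sites))
        assert len(mols) == 2
        assert mols[0].elements == mols[1].elements

    def test_covalent_network_rejected(self):
        # simple cubic of carbons 1.5 A apart: one infinite bonded component
        n, spacing = 3, 1.5
        cell = n * spacing
        sites = [Site("C", (i / n, j / n, k / n))
                 for i in range(n) for j in range(n) for k in range(n)]
        with pytest.raises(ValueError, match="network"):
            extract_molecules(CrystalStructure(UnitCell(cell, cell, cell), sites))


class TestBuildCluster:
    def test_single_molecule_cluster(self):
        cl = build_cluster(_water_like(), 1)
        assert cl.n == 1
        assert cl.central.origin[1] == (0, 0, 0)

    def test_simple_cubic_first_shell(self):
        """N = 7 on a simple-cubic arrangement: the central molecule plus six
        equidistant first-shell neighbours, matching brute-force enumeration."""
        cl = build_cluster(_water_like(), 7)
        center = cl.central.centroid
        dists = [np.linalg.norm(m.centroid - center) for m in cl.molecules]
        np.testing.assert_allclose(dists[1:], 10.0, atol=1e-9)
        # brute force over a big block of translations
        brute = sorted(
            np.linalg.norm(10.0 * np.array(t))
            for t in itertools.product(range(-4, 5), repeat=3)
        )[:7]
        np.testing.assert_allclose(sorted(dists), brute, atol=1e-9)
        # deterministic tie-break: re-built cluster is identical
        cl2 = build_cluster(_water_like(), 7)
        assert [m.origin for m in cl.molecules] == [m.origin for m in cl2.molecules]

    def test_neighbour_distances_nondecreasing(self, polytype_pair):
        cl = build_cluster(polytype_pair[0], 20)
        center = cl.central.centroid
        d = [np.linalg.norm(m.centroid - center) for m in cl.molecules]
        assert all(x <= y + 1e-9 for x, y in zip(d, d[1:]))

    def test_unreachable_size_rejected(self):
        with pytest.raises(ValueError):
            build_cluster(_water_like(), 10**6)


class TestKabsch:
    def test_identity(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.1]])
        rot, trans, rmsd = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_90_degree_rotation(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.3, 0.2, 1.1]])
        r90 = _rotation([0, 0, 1], 90.0)
        rot, _, rmsd = kabsch_superpose(pts, pts @ r90.T)
        assert rmsd < 1e-10
        np.testing.assert_allclose(rot, r90, atol=1e-10)

    def test_matches_quaternion_method_oracle(self, rng):
        """Optimal RMSD agrees with Horn's quaternion method to 1e-10."""
        for _ in range(5):
            a = rng.normal(size=(10, 3))
            b = (a @ _rotation(rng.normal(size=3), 37.0).T
                 + rng.normal(size=3) + 0.05 * rng.normal(size=(10, 3)))
            _, _, rmsd = kabsch_superpose(a, b)

            # Horn: largest eigenvalue of the 4x4 key matrix
            ac = a - a.mean(0)
            bc = b - b.mean(0)
            m = ac.T @ bc
            sxx, sxy, sxz = m[0]
            syx, syy, syz = m[1]
            szx, szy, szz = m[2]
            key = np.array([
                [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
                [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
                [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
                [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
            ])
            lam = np.linalg.eigvalsh(key)[-1]
            e0 = (ac**2).sum() + (bc**2).sum()
            rmsd_horn = np.sqrt(max(e0 - 2 * lam, 0.0) / a.shape[0])
            assert rmsd == pytest.approx(rmsd_horn, abs=1e-10)

    def test_proper_rotation_enforced(self, rng):
        a = rng.normal(size=(8, 3))
        rot, _, _ = kabsch_superpose(a, -a)  # inverted copy
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(line, line)


class TestOverlay:
    def test_self_overlay_is_perfect(self, polytype_pair):
        cl = build_cluster(polytype_pair[0], 12)
        res = overlay(cl, cl)
        assert res.n_matched == 12
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_motion_invariance(self, polytype_pair):
        cl = build_cluster(polytype_pair[0], 12)
        moved = _rotate_cluster(cl, _rotation([1, 2, 3], 33.0), np.array([5.0, -2, 7]))
        res = overlay(cl, moved)
        assert res.n_matched == 12
        assert res.rmsd < 1e-6

    def test_inverted_copy_matched_only_with_inversion_allowed(self, polytype_pair):
        cl = build_cluster(polytype_pair[0], 8)
        inv = Cluster([MoleculeInstance(m.elements, -m.coords, m.origin)
                       for m in cl.molecules])
        res = overlay(cl, inv, allow_inversion=True)
        assert res.n_matched == 8
        assert res.inverted
        assert res.rmsd < 1e-8

    def test_polytype_signature(self, polytype_pair):
        """Clusters confined to the shared layers overlay perfectly; clusters
        spanning the re-oriented layer lose exactly its molecules."""
        s_a, s_b = polytype_pair
        cl15 = overlay(build_cluster(s_a, 15), build_cluster(s_b, 15))
        assert cl15.n_matched == 15
        assert cl15.rmsd < 1e-8

        ca30, cb30 = build_cluster(s_a, 30), build_cluster(s_b, 30)
        res30 = overlay(ca30, cb30)
        assert res30.n_matched < 30
        assert res30.rmsd < 1e-8
        # unmatched molecules sit in the flipped layer (z near -gap_flip)
        matched_a = {i for i, _ in res30.correspondence}
        unmatched_z = [ca30.molecules[i].centroid[2] for i in range(30)
                       if i not in matched_a]
        flipped_layer_z = -PolytypeSpec().gap_flip
        assert unmatched_z
        for z in unmatched_z:
            assert z == pytest.approx(flipped_layer_z, abs=1.5)

    def test_symmetry_of_matched_count(self, polytype_pair):
        s_a, s_b = polytype_pair
        ca, cb = build_cluster(s_a, 20), build_cluster(s_b, 20)
        assert overlay(ca, cb).n_matched == overlay(cb, ca).n_matched

    def test_matches_exhaustive_enumeration_on_reduction(self, polytype_pair):
        """n_matched on a 12-molecule reduction equals the maximum over an
        exhaustive all-pairs-seeded assignment search."""
        s_a, s_b = polytype_pair
        ca, cb = build_cluster(s_a, 12), build_cluster(s_b, 12)
        res = overlay(ca, cb, allow_inversion=False)

        from scipy.optimize import linear_sum_assignment

        coords_a = [m.heavy()[1] for m in ca.molecules]
        coords_b = [m.heavy()[1] for m in cb.molecules]
        best = 0
        for i in range(12):
            for j in range(12):
                rot, trans, _ = kabsch_superpose(coords_a[i], coords_b[j])
                moved = [c @ rot.T + trans for c in coords_a]
                cost = np.array([[np.sqrt(np.mean(np.sum((ma - mb) ** 2, -1)))
                                  for mb in coords_b] for ma in moved])
                rows, cols = linear_sum_assignment(cost)
                best = max(best, int(np.sum(cost[rows, cols] < 0.5)))
        assert res.n_matched == best

    def test_topology_mismatch_rejected(self, polytype_pair):
        cl = build_cluster(polytype_pair[0], 4)
        water = build_cluster(_water_like(), 4)
        with pytest.raises(ValueError, match="topology"):
            overlay(cl, water)
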