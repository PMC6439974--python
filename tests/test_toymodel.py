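"""Geometry, energy terms, moves, and RMSD of the coarse-grained model."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from bars.toymodel import (
    BOND_LENGTH,
    TOY_SCHEMA,
    Conformation,
    ToyProtein,
    build_coords,
    kabsch_rmsd,
    perturb,
    radius_of_gyration,
    term_energies,
    total_energy,
)
from bars.weights import WeightVector


def make_protein(n=8, ss="C", pairs=(), hydrophobic=None):
    labels = tuple((ss * n)[:n])
    if hydrophobic is None:
        hydrophobic = (False,) * n
    return ToyProtein(n, labels, tuple(hydrophobic), frozenset(pairs))


def random_conformation(n, rng):
    prot = make_protein(n)
    angles = rng.uniform(60, 150, n - 2)
    torsions = rng.uniform(-180 + 1e-6, 180, n - 3)
    return Conformation(prot, angles, torsions)


class TestGeometry:
    def test_planar_zigzag_closed_form(self):
        # all 90 degree bond angles, torsion 0: a planar "U"; the chain
        # returns to x=0, so d(0,3) equals one bond length
        xyz = build_coords(np.array([90.0, 90.0]), np.array([0.0]))
        assert xyz.shape == (4, 3)
        np.testing.assert_allclose(xyz[:, 2], 0.0, atol=1e-12)
        d03 = np.linalg.norm(xyz[3] - xyz[0])
        assert d03 == pytest.approx(BOND_LENGTH, abs=1e-9)

    def test_extended_chain_torsion_180(self):
        # 180-degree torsions with near-straight angles give a planar,
        # monotonically extending zigzag
        n = 10
        xyz = build_coords(np.full(n - 2, 150.0), np.full(n - 3, 180.0))
        assert np.all(np.diff(xyz[:, 0]) > 0)
        np.testing.assert_allclose(xyz[:, 2], 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bond_length_invariant(self, seed):
        rng = np.random.default_rng(seed)
        conf = random_conformation(12, rng)
        d = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        np.testing.assert_allclose(d, BOND_LENGTH, atol=1e-9)

    def test_coords_deterministic_in_internal_coords(self):
        rng = np.random.default_rng(3)
        prot = make_protein(9)
        angles = rng.uniform(60, 150, 7)
        torsions = rng.uniform(-179, 180, 6)
        a = Conformation(prot, angles, torsions)
        b = Conformation(prot, angles.copy(), torsions.copy())
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_angle_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_coords(np.array([0.0, 90.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            build_coords(np.array([90.0, 180.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            build_coords(np.array([90.0, 90.0]), np.array([-180.0]))


class TestEnergyTerms:
    def test_no_close_pairs_means_no_clash(self):
        n = 10
        prot = make_protein(n)
        conf = Conformation(
            prot, np.full(n - 2, 150.0), np.full(n - 3, 180.0)
        )
        tv = term_energies(conf)
        assert tv.values[TOY_SCHEMA.index("clash")] == 0.0

    def test_extended_chain_has_no_contacts(self):
        n = 12
        prot = make_protein(n, pairs={(0, 11), (1, 9)})
        conf = Conformation(
            prot, np.full(n - 2, 150.0), np.full(n - 3, 180.0)
        )
        tv = term_energies(conf)
        assert tv.values[TOY_SCHEMA.index("contact")] == 0.0

    def test_terms_match_brute_force_oracle(self, helix):
        """Straight-line recomputation of every term from raw coordinates."""
        prot, conf = helix
        xyz = conf.coords
        n = prot.length
        dmat = squareform(pdist(xyz))

        clash = sum(
            max(0.0, 4.0 - dmat[i, j]) ** 2
            for i in range(n)
            for j in range(i + 3, n)
        )
        rg_val = np.sqrt(((xyz - xyz.mean(0)) ** 2).sum(1).mean())
        rg = (rg_val - 2.2 * n**0.38) ** 2
        ideals = {"H": (89.0, 50.0), "E": (120.0, -170.0)}
        ss_local = 0.0
        for i, lab in enumerate(prot.ss_labels):
            if lab not in ideals:
                continue
            if 1 <= i <= n - 2:
                ss_local += (conf.bond_angles[i - 1] - ideals[lab][0]) ** 2
            if 1 <= i <= n - 3:
                diff = (conf.torsions[i - 1] - ideals[lab][1]) % 360.0
                diff = diff - 360.0 if diff > 180.0 else diff
                ss_local += diff**2
        ss_local /= 1000.0
        contact = -sum(
            1.0 for (i, j) in prot.attraction_pairs if dmat[i, j] < 8.0
        )
        hbond = sum(
            min((dmat[i, i + 4] - 6.2) ** 2, 25.0)
            for i in range(n - 4)
            if set(prot.ss_labels[i : i + 5]) == {"H"}
        )
        env = 0.0
        for i in range(n):
            if not prot.hydrophobic[i]:
                continue
            cnt = sum(
                1 for j in range(n) if abs(i - j) >= 3 and dmat[i, j] < 10.0
            )
            env += max(0, 4 - cnt)

        expected = np.array([clash, rg, ss_local, contact, hbond, env])
        np.testing.assert_allclose(
            term_energies(conf).values, expected, atol=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 7])
    def test_total_energy_linear_in_weights(self, seed):
        rng = np.random.default_rng(seed)
        conf = random_conformation(10, rng)
        w1 = WeightVector(TOY_SCHEMA, rng.uniform(0, 2, 6))
        w2 = WeightVector(TOY_SCHEMA, rng.uniform(0, 2, 6))
        a, b = 0.7, 1.9
        combo = WeightVector(TOY_SCHEMA, a * w1.values + b * w2.values)
        assert total_energy(conf, combo) == pytest.approx(
            a * total_energy(conf, w1) + b * total_energy(conf, w2), abs=1e-9
        )

    def test_zero_and_unit_weights(self):
        rng = np.random.default_rng(11)
        conf = random_conformation(10, rng)
        tv = term_energies(conf)
        zero = WeightVector(TOY_SCHEMA, np.zeros(6))
        assert total_energy(conf, zero) == 0.0
        for k in range(6):
            unit = WeightVector(TOY_SCHEMA, np.eye(6)[k])
            assert total_energy(conf, unit) == pytest.approx(tv.values[k])


class TestPerturb:
    def test_deterministic_given_seed(self, helix_native):
        a = perturb(helix_native, np.random.default_rng(42))
        b = perturb(helix_native, np.random.default_rng(42))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_input_unmodified_and_small_sigma_limit(self, helix_native):
        before = helix_native.torsions.copy()
        moved = perturb(helix_native, np.random.default_rng(0), sigma=1e-12)
        np.testing.assert_array_equal(helix_native.torsions, before)
        np.testing.assert_allclose(
            moved.torsions, helix_native.torsions, atol=1e-9
        )
        np.testing.assert_allclose(
            moved.bond_angles, helix_native.bond_angles, atol=1e-9
        )

    def test_invalid_window_rejected(self, helix_native):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            perturb(helix_native, rng, window=0)
        with pytest.raises(ValueError):
            perturb(helix_native, rng, window=14)

    def test_bond_invariant_survives_many_moves(self, helix_native):
        rng = np.random.default_rng(5)
        conf = helix_native
        for _ in range(300):
            conf = perturb(conf, rng)
        d = np.linalg.norm(np.diff(conf.coords, axis=0), axis=1)
        np.testing.assert_allclose(d, BOND_LENGTH, atol=1e-9)


def _kabsch_oracle(a, b):
    """Independent SVD Kabsch with explicit reflection correction."""
    ca = a - a.mean(0)
    cb = b - b.mean(0)
    h = cb.T @ ca
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    diff = ca - cb @ r.T
    return np.sqrt((diff**2).sum() / len(a))


class TestRMSD:
    def test_self_and_rigid_motion_invariance(self, helix_native):
        xyz = helix_native.coords
        assert kabsch_rmsd(xyz, xyz) == pytest.approx(0.0, abs=1e-9)
        theta = 0.8
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = xyz @ rot.T + np.array([5.0, -3.0, 11.0])
        assert kabsch_rmsd(xyz, moved) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_matches_independent_kabsch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 3))
        b = rng.normal(size=(7, 3))
        assert kabsch_rmsd(a, b) == pytest.approx(
            _kabsch_oracle(a, b), abs=1e-9
        )

    def test_never_exceeds_unsuperposed_rmsd(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(size=(6, 3))
            b = rng.normal(size=(6, 3))
            raw = np.sqrt(((a - b) ** 2).sum() / 6)
            assert kabsch_rmsd(a, b) <= raw + 1e-9

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))


class TestRadiusOfGyration:
    def test_point_and_pair(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(two) == pytest.approx(1.0)

    def test_matches_direct_formula(self, helix_native):
        xyz = helix_native.coords
        expected = np.sqrt(((xyz - xyz.mean(0)) ** 2).sum(1).mean())
        assert radius_of_gyration(xyz) == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariant(self, helix_native):
        xyz = helix_native.coords
        assert radius_of_gyration(xyz + 7.0) == pytest.approx(
            radius_of_gyration(xyz), abs=1e-9
        )
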