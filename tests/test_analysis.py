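"""Ensemble descriptors: Rg, pairwise RMSD, contact maps, helicity, clustering."""

import numpy as np
import pytest

import tsphi as T


def point_structure(xyz, element="C"):
    n = len(xyz)
    return T.Structure(np.array(["CB"] * n), np.array([element] * n),
                       np.arange(1, n + 1), np.array(["ALA"] * n),
                       np.array(["A"] * n), np.asarray(xyz, dtype=float))


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert T.radius_of_gyration(point_structure([[1, 2, 3]])) == \
            pytest.approx(0.0, abs=1e-12)

    def test_two_equal_masses_one_nm_apart(self):
        s = point_structure([[0, 0, 0], [1, 0, 0]])
        assert T.radius_of_gyration(s) == pytest.approx(0.5)

    def test_matches_direct_sum_oracle(self):
        rng = np.random.default_rng(3)
        xyz = rng.normal(size=(10, 3))
        elements = ["C", "N", "O", "S", "C", "H", "N", "C", "O", "C"]
        s = T.Structure(np.array(["CB"] * 10), np.array(elements),
                        np.arange(1, 11), np.array(["ALA"] * 10),
                        np.array(["A"] * 10), xyz)
        masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        m = np.array([masses[e] for e in elements])
        cm = (xyz * m[:, None]).sum(0) / m.sum()
        rg = np.sqrt((m * ((xyz - cm) ** 2).sum(1)).sum() / m.sum())
        assert T.radius_of_gyration(s) == pytest.approx(rg, rel=1e-12)

    def test_rigid_motion_invariant(self):
        rng = np.random.default_rng(4)
        s = point_structure(rng.normal(size=(8, 3)))
        moved = s.transformed(rotation=random_rotation(rng),
                              translation=np.array([5.0, -1.0, 2.0]))
        assert T.radius_of_gyration(moved) == pytest.approx(
            T.radius_of_gyration(s), rel=1e-12)


def quaternion_rmsd(P, Q):
    """Independent quaternion (Horn) superposition RMSD."""
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    M = P.T @ Q
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = (np.sum(P ** 2) + np.sum(Q ** 2) - 2 * lam) / len(P)
    return np.sqrt(max(msd, 0.0))


class TestPairwiseRMSD:
    def test_duplicates_zero(self):
        s = point_structure(np.random.default_rng(0).normal(size=(5, 3)))
        m = T.pairwise_rmsd(T.Ensemble([s, s, s]))
        np.testing.assert_allclose(m, 0.0, atol=1e-12)

    def test_rotated_copy_zero(self):
        rng = np.random.default_rng(1)
        s = point_structure(rng.normal(size=(6, 3)))
        moved = s.transformed(rotation=random_rotation(rng),
                              translation=np.array([2.0, 3.0, -1.0]))
        m = T.pairwise_rmsd(T.Ensemble([s, moved]))
        assert m[0, 1] < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        assert T.kabsch_rmsd(a, b) == pytest.approx(quaternion_rmsd(a, b),
                                                    rel=1e-9)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(2)
        ens = T.Ensemble([point_structure(rng.normal(size=(5, 3)))
                          for _ in range(4)])
        m = T.pairwise_rmsd(ens)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_too_few_atoms_rejected(self):
        s = point_structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            T.pairwise_rmsd(T.Ensemble([s, s]))


class TestContactProbabilityMap:
    def test_native_copies_reproduce_native_support_exactly(self):
        native, _, _ = T.gen_ensembles(T.EnsembleScenario(n_res=6,
                                                          n_conformers=1))
        ncs = T.build_native_contacts(native)
        ens = T.Ensemble([native] * 5)
        cm = T.contact_probability_map(ens, ncs)
        native_support = {tuple(sorted((ncs.residue_keys[i],
                                        ncs.residue_keys[j])))
                          for i, j in ncs.pair_res}
        assert cm.support(0.0) == {tuple(sorted(p))
                                   for p in native_support}
        for (ki, kj) in native_support:
            assert cm.prob(ki, kj) == 1.0

    def test_generator_probability_within_binomial_ci(self):
        p, n = 0.3, 400
        native, ens, _ = T.gen_ensembles(
            T.EnsembleScenario(n_res=8, probs=p, n_conformers=n, seed=5))
        cm = T.contact_probability_map(ens, T.build_native_contacts(native))
        tol = 3 * np.sqrt(p * (1 - p) / n)
        for i in range(1, 9):
            assert abs(cm.prob(("A", i), ("B", i)) - p) < tol

    def test_dissociated_ensemble_interchain_block_zero(self):
        native, _, _ = T.gen_ensembles(T.EnsembleScenario(n_res=5,
                                                          n_conformers=1))
        apart = native.coords.copy()
        apart[native.chain_id == "B"] += 10.0
        sep = T.Structure(native.atom_name, native.element, native.res_id,
                          native.res_name, native.chain_id, apart)
        cm = T.contact_probability_map(T.Ensemble([sep] * 3),
                                       T.build_native_contacts(native))
        assert np.all(cm.matrix == 0.0)


class TestHelicalContent:
    def test_ideal_helix_interior_fraction_one(self):
        h = T.make_ideal_helix(12)
        prof = T.helical_content(T.Ensemble([h]))
        interior = [prof.value("A", i) for i in range(3, 11)]
        assert all(v == 1.0 for v in interior)

    def test_ideal_helix_hbond_energies_negative(self):
        from tsphi.analysis import _backbone_table, _amide_h, _hbond_energy
        h = T.make_ideal_helix(12)
        bb = _backbone_table(h)
        for i in range(1, 8):
            acc = bb[("A", i)]
            don = bb[("A", i + 4)]
            hpos = _amide_h(don, bb[("A", i + 3)])
            e = _hbond_energy(don["N"], hpos, acc["C"], acc["O"])
            assert e < -0.5

    def test_extended_chain_zero_helix(self):
        e = T.make_extended_chain(12)
        prof = T.helical_content(T.Ensemble([e]))
        assert np.nansum(prof.helix_fraction) == 0.0

    def test_mixture_gives_half_at_interior(self):
        h = T.make_ideal_helix(12)
        e = T.make_extended_chain(12)
        prof = T.helical_content(T.Ensemble([h, e]))
        assert prof.value("A", 6) == pytest.approx(0.5)

    def test_missing_backbone_unassigned(self):
        s = point_structure(np.zeros((4, 3)))  # CB-only residues
        prof = T.helical_content(T.Ensemble([s]))
        assert np.all(np.isnan(prof.helix_fraction))


class TestClustering:
    def _families(self, n_per=10, seed=0):
        # two families with distinct internal shapes (translation/rotation
        # is removed by superposition, so families must differ in shape)
        rng = np.random.default_rng(seed)
        shapes = [rng.normal(size=(6, 3)), rng.normal(size=(6, 3))]
        members = []
        for shape in shapes:
            for _ in range(n_per):
                members.append(point_structure(
                    shape + rng.normal(scale=0.01, size=(6, 3))))
        return T.Ensemble(members)

    def test_identical_conformers_one_cluster(self):
        s = point_structure(np.random.default_rng(0).normal(size=(5, 3)))
        res = T.cluster_ensemble(T.Ensemble([s] * 6), rmsd_cutoff=0.1)
        assert res.n_clusters == 1
        assert np.all(res.assignments == 0)

    def test_two_separated_families_two_clusters(self):
        res = T.cluster_ensemble(self._families(), rmsd_cutoff=0.2)
        assert res.n_clusters == 2
        assert sorted(res.sizes()) == [10, 10]

    def test_huge_cutoff_one_cluster(self):
        res = T.cluster_ensemble(self._families(), rmsd_cutoff=100.0)
        assert res.n_clusters == 1

    def test_every_conformer_assigned_once(self):
        res = T.cluster_ensemble(self._families(seed=3), rmsd_cutoff=0.2)
        assert res.assignments.min() >= 0
        assert len(res.assignments) == 20

    def test_first_half_vs_all_cluster_count_converged(self):
        """With a fixed small number of conformational modes, the cluster
        count on the first half matches the full ensemble within 1."""
        rng = np.random.default_rng(8)
        base = [rng.normal(size=(6, 3)) for _ in range(3)]
        members = [point_structure(base[rng.integers(3)]
                                   + rng.normal(scale=0.01, size=(6, 3)))
                   for _ in range(40)]
        ens = T.Ensemble(members)
        full = T.cluster_ensemble(ens, rmsd_cutoff=0.2, subset="all")
        half = T.cluster_ensemble(ens, rmsd_cutoff=0.2, subset="first_half")
        assert abs(full.n_clusters - half.n_clusters) <= 1

    def test_rigid_motion_invariance_of_descriptors(self):
        rng = np.random.default_rng(12)
        ens = T.Ensemble([point_structure(rng.normal(size=(6, 3)))
                          for _ in range(4)])
        Rm = random_rotation(rng)
        moved = T.Ensemble([c.transformed(rotation=Rm,
                                          translation=np.array([1., 2., 3.]))
                            for c in ens])
        np.testing.assert_allclose(T.pairwise_rmsd(moved),
                                   T.pairwise_rmsd(ens), atol=1e-9)
        assert T.cluster_ensemble(moved, 0.5).n_clusters == \
            T.cluster_ensemble(ens, 0.5).n_clusters
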