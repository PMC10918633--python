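"""Fragmentation, fragment re-alignment, reassembly, and the flexible pipeline."""

import numpy as np
import pytest

from shapeflex import (
    RigidTransform,
    RunConfig,
    cloud_of,
    extract_neighborhood,
    flexible_align,
    flexible_align_ensemble,
    fragment_molecule,
    mmff94_energy,
    mmff94_minimize,
    realign_fragment,
    reassemble_and_minimize,
    rmsd_best_fit,
    rmsd_in_place,
)
from shapeflex.chem import ConformerEnsemble
from shapeflex.fixtures import make_decoy, make_fixture_set
from shapeflex.flex import attach_sub_clouds


class TestFragmentation:
    @pytest.mark.parametrize(
        "name,smiles,expected",
        [
            ("ethane", "CC", 1),
            ("toluene", None, 2),
            ("diphenylmethane", None, 3),
        ],
    )
    def test_known_fragment_counts(self, molecule_factory, name, smiles, expected):
        mol = molecule_factory(name, smiles=smiles)
        assert len(fragment_molecule(mol)) == expected

    def test_acyclic_molecule_is_single_substituent(self, molecule_factory):
        frags = fragment_molecule(molecule_factory("ethanol"))
        assert len(frags) == 1
        assert frags[0].kind == "substituent"

    def test_diphenylmethane_kinds(self, molecule_factory):
        kinds = sorted(f.kind for f in fragment_molecule(molecule_factory("diphenylmethane")))
        assert kinds == ["linker", "ring_system", "ring_system"]

    def test_partition_invariants_across_fixture_set(self):
        for case in make_fixture_set(12, seed=3, n_decoys=1):
            mol = case.reference
            frags = fragment_molecule(mol)
            # disjoint and exhaustive
            all_atoms = sorted(i for f in frags for i in f.atom_indices)
            assert all_atoms == list(range(mol.n_atoms))
            # connected induced subgraphs
            import networkx as nx

            g = nx.Graph()
            g.add_nodes_from(range(mol.n_atoms))
            g.add_edges_from((i, j) for i, j, _ in mol.bonds)
            for f in frags:
                assert nx.is_connected(g.subgraph(f.atom_indices))
            # every attachment bond appears in exactly two fragments' lists
            from collections import Counter

            counts = Counter()
            for f in frags:
                for bond in f.attachment_bonds:
                    counts[tuple(sorted(bond))] += 1
            assert all(v == 2 for v in counts.values())

    def test_hydrogens_travel_with_heavy_atom(self, molecule_factory):
        mol = molecule_factory("toluene")
        for f in fragment_molecule(mol):
            atom_set = set(f.atom_indices)
            for i in f.atom_indices:
                if mol.elements[i] == "H":
                    assert all(j in atom_set for j in mol.neighbors(i))


class TestNeighborhood:
    def test_infinite_radius_returns_whole_target(self, molecule_factory, default_config):
        mol = molecule_factory("toluene")
        cloud = cloud_of(mol, default_config)
        sub = cloud.subset(np.arange(len(cloud)) < 50)
        neigh = extract_neighborhood(cloud, sub, radius=1e9)
        assert len(neigh) == len(cloud)

    def test_distant_fragment_gets_empty_neighborhood(self, molecule_factory, default_config):
        cloud = cloud_of(molecule_factory("toluene"), default_config)
        far = cloud.transformed(
            RigidTransform.from_rotation_translation(np.eye(3), [100.0, 0, 0]).matrix
        )
        assert len(extract_neighborhood(cloud, far, radius=4.0)) == 0

    def test_counts_match_brute_force(self):
        from shapeflex.surface import ColoredPointCloud

        rng = np.random.default_rng(5)
        tgt_pts = rng.uniform(-10, 10, size=(20, 3))
        frag_pts = rng.uniform(-2, 2, size=(8, 3))
        tgt = ColoredPointCloud(tgt_pts, np.ones(20, int), np.zeros(20, int), 1.0)
        frag = ColoredPointCloud(frag_pts, np.ones(8, int), np.zeros(8, int), 1.0)
        radius = 4.0
        d = np.linalg.norm(tgt_pts[:, None, :] - frag_pts[None, :, :], axis=2)
        expected = int(np.sum(d.min(axis=1) <= radius))
        assert len(extract_neighborhood(tgt, frag, radius)) == expected


class TestRealignFragment:
    def _fragment_with_cloud(self, molecule_factory, default_config):
        mol = molecule_factory("diphenylmethane")
        cloud = cloud_of(mol, default_config)
        frags = attach_sub_clouds(fragment_molecule(mol), cloud)
        return mol, cloud, frags

    def test_perfect_embedding_is_fixed_point(self, molecule_factory, default_config):
        _, cloud, frags = self._fragment_with_cloud(molecule_factory, default_config)
        frag = max(frags, key=lambda f: len(f.sub_cloud))
        neigh = extract_neighborhood(cloud, frag.sub_cloud, 4.0)
        T, scores = realign_fragment(frag, neigh, RigidTransform.identity(), default_config)
        err = np.linalg.norm(T.apply(frag.sub_cloud.points) - frag.sub_cloud.points, axis=1).mean()
        assert err < 0.05
        assert scores.gfit == pytest.approx(1.0, abs=0.02)

    def test_offset_fragment_improves(self, molecule_factory, default_config):
        from shapeflex.registration import compute_fitness

        _, cloud, frags = self._fragment_with_cloud(molecule_factory, default_config)
        frag = max(frags, key=lambda f: len(f.sub_cloud))
        neigh = extract_neighborhood(cloud, frag.sub_cloud, 6.0)
        offset = RigidTransform.from_rotation_translation(np.eye(3), [1.0, 0.3, 0.0])
        f0 = compute_fitness(frag.sub_cloud, neigh, offset, config=default_config)
        T, f1 = realign_fragment(frag, neigh, offset, default_config)
        assert f1.total > f0.total

    def test_empty_neighborhood_returns_init(self, molecule_factory, default_config):
        _, cloud, frags = self._fragment_with_cloud(molecule_factory, default_config)
        frag = frags[0]
        empty = cloud.subset(np.zeros(len(cloud), dtype=bool))
        init = RigidTransform.identity()
        T, _ = realign_fragment(frag, empty, init, default_config)
        assert np.array_equal(T.matrix, init.matrix)


class TestReassembly:
    def test_identity_transforms_reduce_to_plain_minimization(
        self, molecule_factory, default_config
    ):
        mol = molecule_factory("paracetamol")
        frags = fragment_molecule(mol)
        identity = [RigidTransform.identity()] * len(frags)
        out = reassemble_and_minimize(mol, frags, identity, default_config)
        ref, _ = mmff94_minimize(mol, default_config.minimize_cycles)
        assert rmsd_best_fit(out, ref, scope="all").value < 0.1

    def test_translated_fragment_bond_lengths_repaired(self, molecule_factory, default_config):
        mol, _ = mmff94_minimize(molecule_factory("diphenylmethane"))
        frags = fragment_molecule(mol)
        transforms = [RigidTransform.identity()] * len(frags)
        moved_idx = max(range(len(frags)), key=lambda k: len(frags[k].atom_indices))
        transforms[moved_idx] = RigidTransform.from_rotation_translation(
            np.eye(3), [0.3, 0.0, 0.0]
        )
        out = reassemble_and_minimize(mol, frags, transforms, default_config)
        ref, _ = mmff94_minimize(mol, default_config.minimize_cycles)
        for i, j in frags[moved_idx].attachment_bonds:
            got = np.linalg.norm(out.coords[i] - out.coords[j])
            want = np.linalg.norm(ref.coords[i] - ref.coords[j])
            assert abs(got - want) < 0.05

    def test_graph_conserved(self, molecule_factory, default_config):
        mol = molecule_factory("ibuprofen")
        frags = fragment_molecule(mol)
        transforms = [RigidTransform.identity()] * len(frags)
        transforms[0] = RigidTransform.from_rotation_translation(np.eye(3), [0.2, 0.1, 0.0])
        out = reassemble_and_minimize(mol, frags, transforms, default_config)
        assert out.bond_graph_key() == mol.bond_graph_key()


def _torsion_case(molecule_factory, seed=3):
    """Reference + decoy with meaningfully perturbed heavy torsions."""
    ref = molecule_factory("naproxen", seed=seed)
    decoy, applied = make_decoy(ref, seed=41)
    assert applied, "decoy generation should perturb at least one torsion"
    return ref, decoy


class TestFlexibleAlign:
    def test_rigid_single_fragment_source_falls_back(self, molecule_factory, default_config):
        benzene = molecule_factory("benzene")
        target = cloud_of(benzene, default_config)
        res = flexible_align(benzene, target, default_config, seed=2)
        assert res.accepted is False
        assert res.n_fragments == 1
        assert np.array_equal(res.posed_molecule.coords, res.rigid_pose.coords)

    def test_score_dominance_and_graph_conservation(self, molecule_factory, default_config):
        ref, decoy = _torsion_case(molecule_factory)
        target = cloud_of(ref, default_config)
        res = flexible_align(decoy, target, default_config, seed=5)
        assert res.scores.total >= res.rigid_baseline.total
        assert res.accepted == (res.scores.total > res.rigid_baseline.total)
        assert res.posed_molecule.bond_graph_key() == decoy.bond_graph_key()

    def test_torsion_perturbation_recovered(self, molecule_factory, default_config):
        ref, decoy = _torsion_case(molecule_factory)
        target = cloud_of(ref, default_config)
        res = flexible_align(decoy, target, default_config, seed=7)
        rigid_rmsd = rmsd_in_place(res.rigid_pose, ref, scope="heavy").value
        flex_rmsd = rmsd_in_place(res.posed_molecule, ref, scope="heavy").value
        assert res.accepted
        assert flex_rmsd < rigid_rmsd

    def test_accepted_pose_energy_bounded(self, molecule_factory, default_config):
        ref, decoy = _torsion_case(molecule_factory)
        target = cloud_of(ref, default_config)
        ensemble = ConformerEnsemble(molecule=ref, coordinate_sets=[decoy.coords])
        res = flexible_align_ensemble(ensemble, target, runs=1, config=default_config, seed=7)
        e_pose = mmff94_energy(res.posed_molecule)
        e_min = mmff94_minimize(decoy)[1]
        assert np.isfinite(e_pose)
        assert e_pose <= e_min + default_config.energy_window

    def test_parameter_recovery_median(self, default_config):
        """Flexible beats rigid in median in-place RMSD over >= 20 decoy cases.

        Only molecules with rotatable heavy-atom torsions contribute: a
        rigid reference yields a decoy identical to itself, where both
        protocols are trivially exact.
        """
        pairs = []
        for case in make_fixture_set(30, seed=9, n_decoys=2):
            for j, applied in enumerate(case.perturbed_torsions):
                if applied:
                    pairs.append((case.reference, case.decoys.conformer(j)))
        assert len(pairs) >= 20
        rigid_rmsds, flex_rmsds = [], []
        for ref, decoy in pairs[:24]:
            target = cloud_of(ref, default_config)
            res = flexible_align(decoy, target, default_config, seed=13)
            rigid_rmsds.append(rmsd_in_place(res.rigid_pose, ref, scope="heavy").value)
            flex_rmsds.append(rmsd_in_place(res.posed_molecule, ref, scope="heavy").value)
        assert np.median(flex_rmsds) < np.median(rigid_rmsds)


class TestFlexibleEnsemble:
    def test_singleton_ensemble_equals_single_alignment(self, molecule_factory, default_config):
        from shapeflex.config import derive_seed

        ref, decoy = _torsion_case(molecule_factory)
        target = cloud_of(ref, default_config)
        ensemble = ConformerEnsemble(molecule=ref, coordinate_sets=[decoy.coords])
        res_e = flexible_align_ensemble(ensemble, target, runs=1, config=default_config, seed=21)
        res_s = flexible_align(
            ensemble.conformer(0), target, default_config, seed=derive_seed(21, "trial", 0, 0)
        )
        assert res_e.scores.total == pytest.approx(res_s.scores.total, abs=1e-12)
        assert np.allclose(res_e.posed_molecule.coords, res_s.posed_molecule.coords)

    def test_returns_max_total_over_trials(self, molecule_factory, default_config):
        from shapeflex.flex import ensemble_trials

        ref, decoy = _torsion_case(molecule_factory)
        target = cloud_of(ref, default_config)
        ensemble = ConformerEnsemble(
            molecule=ref, coordinate_sets=[ref.coords, decoy.coords]
        )
        trials = ensemble_trials(ensemble, target, runs=2, config=default_config, seed=3)
        best = flexible_align_ensemble(ensemble, target, runs=2, config=default_config, seed=3)
        assert best.scores.total == pytest.approx(
            max(t[2].scores.total for t in trials), abs=1e-12
        )
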