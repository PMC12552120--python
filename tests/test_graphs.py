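"""Interaction-graph construction, featurization and ablation."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from gems.complexes import AffinityLabel, ComplexRecord, LigandMolecule, ProteinStructure, Residue
from gems.fixtures import random_rotation, transform_ligand, transform_protein
from gems.graphs import (
    ROLE_LIGAND,
    ROLE_RESIDUE,
    FeatureSchema,
    StubEmbeddingProvider,
    ablate_protein,
    build_graph,
    find_pocket,
    load_graph,
    save_graph,
    stub_embedding_provider,
    virtual_cbeta,
)


def _residue(index, ca, name="ALA"):
    ca = np.asarray(ca, dtype=float)
    return Residue(
        name=name, chain="A", index=index,
        atoms={
            "N": ca + np.array([-1.2, 0.4, 0.0]),
            "CA": ca,
            "C": ca + np.array([1.2, 0.4, 0.0]),
        },
    )


def _linear_ligand(n_atoms=3, spacing=1.5, z=0.0):
    """n-carbon chain along x with explicit 3-D coordinates."""
    mol = Chem.RWMol()
    for _ in range(n_atoms):
        mol.AddAtom(Chem.Atom(6))
    for i in range(n_atoms - 1):
        mol.AddBond(i, i + 1, Chem.BondType.SINGLE)
    mol = mol.GetMol()
    Chem.SanitizeMol(mol)
    conf = Chem.Conformer(n_atoms)
    for i in range(n_atoms):
        conf.SetAtomPosition(i, (i * spacing, 0.0, z))
    mol.AddConformer(conf)
    return LigandMolecule(mol=mol)


def _record(protein, ligand, cid="gx01", pk=6.5):
    return ComplexRecord(
        id=cid, protein=protein, ligand=ligand,
        label=AffinityLabel(pk=pk, measure_kind="Kd", exact=True, raw_expression="Kd=1uM"),
    )


class TestFindPocket:
    @pytest.mark.parametrize("distance, included", [(4.9, True), (5.0, True), (5.1, False)])
    def test_cutoff_boundary_inclusive(self, distance, included):
        ligand = _linear_ligand(3)
        protein = ProteinStructure(residues=[_residue(1, [0.0, distance, 0.0])])
        # residue atoms offset from CA; use a residue whose nearest atom is CA
        protein.residues[0].atoms = {"N": np.array([0.0, distance + 1, 0.0]),
                                     "CA": np.array([0.0, distance, 0.0]),
                                     "C": np.array([1.0, distance + 1, 0.0])}
        pocket = find_pocket(protein, ligand, cutoff=5.0)
        assert (len(pocket.residues) == 1) is included

    def test_far_ligand_yields_empty_pocket_but_buildable_graph(self):
        ligand = _linear_ligand(3)
        protein = ProteinStructure(residues=[_residue(1, [0.0, 50.0, 0.0])])
        record = _record(protein, ligand)
        graph = build_graph(record)
        assert graph.n_nodes == 3
        assert set(graph.node_roles.tolist()) == {ROLE_LIGAND}

    def test_waters_never_enter_the_pocket(self):
        ligand = _linear_ligand(3)
        water = Residue(name="HOH", chain="A", index=2,
                        atoms={"O": np.array([0.0, 2.0, 0.0])}, is_hetero=True)
        protein = ProteinStructure(residues=[_residue(1, [0.0, 3.0, 0.0]), water])
        pocket = find_pocket(protein, ligand)
        assert pocket.hetero_atoms == []


class TestBuildGraph:
    def _two_residue_record(self):
        # 3-atom ligand at x = 0, 1.5, 3; residue A within 5 A of atoms 0 and 1,
        # residue B within 5 A of atom 2 only
        ligand = _linear_ligand(3)
        res_a = _residue(1, [0.75, 4.2, 0.0])
        res_b = _residue(2, [3.0, 4.8, 0.0], name="GLY")
        res_b.atoms = {k: v for k, v in res_b.atoms.items()}
        protein = ProteinStructure(residues=[res_a, res_b])
        return _record(protein, ligand)

    def test_hand_counted_nodes_and_edges(self):
        record = self._two_residue_record()
        graph = build_graph(record)
        pocket = find_pocket(record.protein, record.ligand)
        n_interactions = len(pocket.contacts)
        assert graph.n_nodes == 3 + len(pocket.residues)
        # directed edges: 2 per covalent bond + 2 per interaction + self-loops
        assert graph.n_edges == 2 * (2 + n_interactions) + graph.n_nodes
        graph.validate()

    def test_interaction_edge_count_matches_brute_force(self, scenario):
        for record in scenario.train[:4]:
            graph = build_graph(record)
            lig = record.ligand.heavy_atom_coords()
            expected = 0
            pocket = find_pocket(record.protein, record.ligand)
            for atom_xyz in lig:
                for res in pocket.residues:
                    if min(
                        np.linalg.norm(atom_xyz - a) for a in res.atoms.values()
                    ) <= 5.0:
                        expected += 1
            loops = graph.self_loop_mask()
            noncov = graph.edge_features[
                ~loops, graph_edge_type_offset(graph) + 2
            ].sum()
            assert int(noncov) == 2 * expected  # both directions

    def test_rigid_invariance_of_features(self, scenario, rng):
        record = scenario.train[0]
        graph = build_graph(record)
        rot = random_rotation(rng)
        shift = np.array([4.0, -7.0, 2.0])
        moved = ComplexRecord(
            id=record.id,
            protein=transform_protein(record.protein, rot, shift),
            ligand=transform_ligand(record.ligand, rot, shift),
            label=record.label,
        )
        moved_graph = build_graph(moved)
        assert np.allclose(graph.node_features, moved_graph.node_features, atol=1e-6)
        assert np.allclose(graph.edge_features, moved_graph.edge_features, atol=1e-6)
        assert np.array_equal(graph.edge_index, moved_graph.edge_index)

    def test_one_hot_blocks_and_finiteness(self, scenario):
        schema = FeatureSchema()
        graph = build_graph(scenario.train[0], schema=schema)
        assert np.all(np.isfinite(graph.node_features))
        atom_block = graph.node_features[:, :9]
        assert np.all(atom_block.sum(axis=1) <= 1.0 + 1e-12)
        aa_off = schema.node_offset("amino_acid")
        assert np.all(graph.node_features[:, aa_off:aa_off + 20].sum(axis=1) <= 1.0)

    def test_missing_backbone_raises(self):
        ligand = _linear_ligand(3)
        broken = _residue(1, [0.0, 3.0, 0.0])
        del broken.atoms["N"]
        protein = ProteinStructure(residues=[broken])
        with pytest.raises(Exception, match="lacks N/CA/C"):
            build_graph(_record(protein, ligand))

    def test_serialization_round_trip_bit_exact(self, scenario, tmp_path):
        graph = build_graph(scenario.train[1], provider=stub_embedding_provider(6, seed=2))
        path = tmp_path / "graph.npz"
        save_graph(graph, path)
        loaded = load_graph(path)
        assert loaded.id == graph.id and loaded.label == graph.label
        for attr in ("node_features", "edge_index", "edge_features",
                     "global_features", "node_roles"):
            assert np.array_equal(getattr(loaded, attr), getattr(graph, attr))


def graph_edge_type_offset(graph):
    return 0  # edge-type one-hot is the first edge block


class TestVirtualCbeta:
    def test_bond_length_fixed(self, rng):
        for _ in range(20):
            n, ca, c = rng.normal(size=(3, 3)) * 3
            if np.linalg.norm(np.cross(ca - n, c - ca)) < 1e-3:
                continue
            cb = virtual_cbeta(n, ca, c)
            assert np.linalg.norm(cb - ca) == pytest.approx(1.522, abs=1e-3)

    def test_translation_equivariance(self, rng):
        n, ca, c = rng.normal(size=(3, 3))
        shift = np.array([10.0, -5.0, 3.0])
        assert np.allclose(
            virtual_cbeta(n + shift, ca + shift, c + shift),
            virtual_cbeta(n, ca, c) + shift,
            atol=1e-9,
        )

    def test_fixed_handedness_under_mirror(self, rng):
        """The construction is chiral: it always places the out-of-plane
        component on the same side of the backbone frame, so a mirrored
        backbone keeps the same handedness (and all Cb-backbone distances)."""
        n, ca, c = rng.normal(size=(3, 3))
        mirror = np.diag([-1.0, 1.0, 1.0])
        cb = virtual_cbeta(n, ca, c)
        cb_m = virtual_cbeta(mirror @ n, mirror @ ca, mirror @ c)

        def handedness(n_, ca_, c_, cb_):
            return np.sign(np.dot(np.cross(ca_ - n_, c_ - ca_), cb_ - ca_))

        assert handedness(n, ca, c, cb) == handedness(
            mirror @ n, mirror @ ca, mirror @ c, cb_m
        )
        for ref, point in ((n, mirror @ n), (ca, mirror @ ca), (c, mirror @ c)):
            assert np.linalg.norm(cb - ref) == pytest.approx(
                np.linalg.norm(cb_m - point), abs=1e-9
            )

    def test_collinear_backbone_rejected(self):
        with pytest.raises(ValueError, match="collinear|degenerate"):
            virtual_cbeta([0, 0, 0], [1, 0, 0], [2, 0, 0])


class TestAblation:
    def test_counts_after_ablation(self):
        ligand = _linear_ligand(3)
        res = _residue(1, [0.75, 4.2, 0.0])
        protein = ProteinStructure(residues=[res])
        graph = build_graph(_record(protein, ligand))
        ablated = ablate_protein(graph)
        assert ablated.n_nodes == 3
        assert set(ablated.node_roles.tolist()) == {ROLE_LIGAND}
        # 2 covalent bonds both directions + 3 self-loops
        assert ablated.n_edges == 2 * 2 + 3
        assert ablated.label == graph.label
        assert np.array_equal(ablated.global_features, graph.global_features)

    def test_idempotent(self, scenario):
        graph = build_graph(scenario.train[0])
        once = ablate_protein(graph)
        twice = ablate_protein(once)
        assert np.array_equal(once.node_features, twice.node_features)
        assert np.array_equal(once.edge_index, twice.edge_index)


class TestStubEmbeddings:
    def test_deterministic_and_width(self):
        provider = StubEmbeddingProvider(residue_width=5, ligand_width=7, seed=3)
        seq = "ACDEFG"
        first = provider.residue_embeddings(seq)
        assert first.shape == (6, 5)
        assert np.array_equal(first, provider.residue_embeddings(seq))
        lig = provider.ligand_embedding("c1ccccc1O")
        assert lig.shape == (7,)
        assert np.array_equal(lig, provider.ligand_embedding("c1ccccc1O"))

    def test_seed_changes_output(self):
        a = StubEmbeddingProvider(seed=1).ligand_embedding("CCO")
        b = StubEmbeddingProvider(seed=2).ligand_embedding("CCO")
        assert not np.allclose(a, b)
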