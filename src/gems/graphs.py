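"""Sparse interaction graphs of protein-ligand complexes.

A complex becomes a graph whose nodes are the ligand's heavy atoms plus one
node per binding-pocket residue (anchored at its Calpha) and per non-water
heteroatom in contact. Edges are the ligand's covalent bonds, one self-loop
per node, and ligand-atom/residue interaction edges for every contact
within the pocket cutoff (5 angstrom by default). All geometric features
are inter-atomic distances, so the representation is invariant under rigid
rotation and translation of the input complex.

Node features: atom-type one-hot (B, C, N, O, P, S, Se, metal, halogen),
ring membership, hybridization, formal charge, aromaticity, atomic mass,
bonded hydrogens, degree, chirality, amino-acid one-hot, and an optional
residue-embedding slot filled by a pluggable provider. Blocks that do not
apply to a node (e.g. amino-acid type for a ligand atom) are zero-padded so
every row has the same width.

Edge features: edge-type one-hot (covalent / self-loop / non-covalent),
four distance slots (covalent edges use the first for bond length;
interaction edges carry the distances from the ligand atom to the residue's
N, Calpha, C and virtual Cbeta), bond type, conjugation, ring membership
and stereochemistry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from rdkit import Chem
from scipy.spatial import cKDTree

from .complexes import ComplexRecord, LigandMolecule, ProteinStructure, Residue

SCHEMA_VERSION = "1.0"

ATOM_TYPES = ("B", "C", "N", "O", "P", "S", "Se", "metal", "halogen")
HALOGENS = ("F", "Cl", "Br", "I", "At")
METALS = (
    "Li", "Na", "K", "Rb", "Cs", "Be", "Mg", "Ca", "Sr", "Ba",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg", "Al", "Ga",
)
HYBRIDIZATIONS = ("SP", "SP2", "SP3", "SP3D", "SP3D2")
AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)
BOND_TYPES = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
EDGE_TYPES = ("covalent", "self_loop", "noncovalent")

ROLE_LIGAND, ROLE_RESIDUE, ROLE_HETEROATOM = 0, 1, 2

#: Virtual Cbeta construction: unit combination coefficients for the frame
#: built from cross(b1, b2), b1 = Ca - N and b2 = C - Ca (all normalized),
#: rescaled to the ideal Ca-Cb bond length.
CBETA_BOND_LENGTH = 1.522
_CB_COEFFS = (-0.58273431, 0.56802827, -0.54067466)


@dataclass(frozen=True)
class FeatureSchema:
    """Fixed block layout of node and edge feature rows, versioned."""

    residue_embedding_width: int = 0
    global_width: int = 8
    version: str = SCHEMA_VERSION

    # node blocks: (name, width)
    @property
    def node_blocks(self) -> tuple[tuple[str, int], ...]:
        return (
            ("atom_type", len(ATOM_TYPES)),
            ("in_ring", 1),
            ("hybridization", len(HYBRIDIZATIONS)),
            ("formal_charge", 1),
            ("aromatic", 1),
            ("atomic_mass", 1),
            ("n_hydrogens", 1),
            ("degree", 1),
            ("chirality", 2),
            ("amino_acid", len(AMINO_ACIDS)),
            ("residue_embedding", self.residue_embedding_width),
        )

    @property
    def edge_blocks(self) -> tuple[tuple[str, int], ...]:
        return (
            ("edge_type", len(EDGE_TYPES)),
            ("distances", 4),
            ("bond_type", len(BOND_TYPES)),
            ("conjugated", 1),
            ("in_ring", 1),
            ("stereo", 2),
        )

    @property
    def node_width(self) -> int:
        return sum(w for _, w in self.node_blocks)

    @property
    def edge_width(self) -> int:
        return sum(w for _, w in self.edge_blocks)

    def node_offset(self, block: str) -> int:
        offset = 0
        for name, width in self.node_blocks:
            if name == block:
                return offset
            offset += width
        raise KeyError(block)

    def edge_offset(self, block: str) -> int:
        offset = 0
        for name, width in self.edge_blocks:
            if name == block:
                return offset
            offset += width
        raise KeyError(block)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "residue_embedding_width": self.residue_embedding_width,
            "global_width": self.global_width,
            "metals": list(METALS),
            "halogens": list(HALOGENS),
        }


class EmbeddingProvider(Protocol):
    """Contract for (language-model) embedding sources.

    ``residue_embeddings`` maps a one-letter protein sequence to one vector
    per residue; ``ligand_embedding`` maps a ligand line notation to a
    single vector. Both must be deterministic for a fixed input and honour
    the declared widths.
    """

    residue_width: int
    ligand_width: int

    def residue_embeddings(self, sequence: str) -> np.ndarray: ...

    def ligand_embedding(self, line_notation: str) -> np.ndarray: ...


class StubEmbeddingProvider:
    """Deterministic pseudo-random embeddings for download-free operation.

    Vectors are keyed by (seed, sequence, position) for residues and by
    (seed, line notation) for ligands via a cryptographic hash, so they are
    reproducible across runs and platforms without any model weights.
    """

    def __init__(self, residue_width: int = 8, ligand_width: int = 8, seed: int = 0) -> None:
        if residue_width <= 0 or ligand_width <= 0:
            raise ValueError("embedding widths must be positive")
        self.residue_width = residue_width
        self.ligand_width = ligand_width
        self.seed = seed

    def _vector(self, key: str, width: int) -> np.ndarray:
        digest = hashlib.sha256(f"{self.seed}|{key}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        return rng.standard_normal(width)

    def residue_embeddings(self, sequence: str) -> np.ndarray:
        return np.stack(
            [self._vector(f"res|{sequence}|{i}", self.residue_width)
             for i in range(len(sequence))]
        )

    def ligand_embedding(self, line_notation: str) -> np.ndarray:
        return self._vector(f"lig|{line_notation}", self.ligand_width)


def stub_embedding_provider(width: int, seed: int = 0) -> StubEmbeddingProvider:
    return StubEmbeddingProvider(residue_width=width, ligand_width=width, seed=seed)


@dataclass
class InteractionGraph:
    """Featurized sparse graph of one complex, plus its global context."""

    id: str
    node_features: np.ndarray     # (N, node_width)
    edge_index: np.ndarray        # (2, E) directed; both directions + self-loops
    edge_features: np.ndarray     # (E, edge_width)
    global_features: np.ndarray   # (global_width,)
    node_roles: np.ndarray        # (N,) ROLE_* codes
    label: float | None = None    # pK
    schema_version: str = SCHEMA_VERSION

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def self_loop_mask(self) -> np.ndarray:
        return self.edge_index[0] == self.edge_index[1]

    def validate(self) -> None:
        src, dst = self.edge_index
        loops = self.self_loop_mask()
        if int(loops.sum()) != self.n_nodes:
            raise ValueError("expected exactly one self-loop per node")
        undirected = {(int(s), int(d)) for s, d in zip(src[~loops], dst[~loops])}
        if any((d, s) not in undirected for s, d in undirected):
            raise ValueError("edge list is not symmetric")
        if not np.all(np.isfinite(self.node_features)):
            raise ValueError("non-finite node features")
        if not np.all(np.isfinite(self.edge_features)):
            raise ValueError("non-finite edge features")


class MissingBackboneError(ValueError):
    """A pocket residue lacks the backbone atoms needed for edge features."""


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Idealized Cbeta position from backbone N/Ca/C coordinates.

    Built from the orthogonal frame (b1 = Ca - N, b2 = C - Ca, b1 x b2),
    each normalized, combined with fixed coefficients and rescaled to a
    Ca-Cb bond length of exactly 1.522 angstrom. Defined identically for
    every residue type, glycine included; mirrors and translations of the
    backbone mirror/translate the result.
    """
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    b1 = ca - n
    b2 = c - ca
    cross = np.cross(b1, b2)
    norm = np.linalg.norm
    if norm(b1) < 1e-8 or norm(b2) < 1e-8 or norm(cross) < 1e-8:
        raise ValueError("degenerate (collinear) backbone geometry")
    direction = (
        _CB_COEFFS[0] * cross / norm(cross)
        + _CB_COEFFS[1] * b1 / norm(b1)
        + _CB_COEFFS[2] * b2 / norm(b2)
    )
    return ca + CBETA_BOND_LENGTH * direction / norm(direction)


@dataclass
class PocketContacts:
    """Residues/heteroatoms in contact with the ligand plus the contact pairs."""

    residues: list[Residue]
    contacts: list[tuple[int, int]]          # (ligand atom idx, residue idx into residues)
    hetero_atoms: list[tuple[str, str, np.ndarray]]  # (residue name, atom name, xyz)
    hetero_contacts: list[tuple[int, int]]   # (ligand atom idx, hetero idx)


def find_pocket(
    protein: ProteinStructure, ligand: LigandMolecule, cutoff: float = 5.0
) -> PocketContacts:
    """All residues and non-water heteroatoms within ``cutoff`` of the ligand.

    A residue is in the pocket if any of its heavy atoms lies within the
    cutoff (inclusive) of any ligand heavy atom; the per-(ligand atom,
    residue) contact pairs are retained for interaction-edge construction.
    Waters never enter the pocket.
    """
    lig_coords = ligand.heavy_atom_coords()
    if lig_coords.size == 0:
        raise ValueError("ligand has no heavy-atom coordinates")
    tree = cKDTree(lig_coords)
    residues: list[Residue] = []
    contacts: list[tuple[int, int]] = []
    hetero_atoms: list[tuple[str, str, np.ndarray]] = []
    hetero_contacts: list[tuple[int, int]] = []
    for res in protein.polymer_residues():
        dists, _ = tree.query(res.coords())
        if np.min(dists) > cutoff:
            continue
        res_idx = len(residues)
        residues.append(res)
        res_tree = cKDTree(res.coords())
        for atom_idx, xyz in enumerate(lig_coords):
            d, _ = res_tree.query(xyz)
            if d <= cutoff:
                contacts.append((atom_idx, res_idx))
    for res in protein.hetero_residues():
        for atom_name, xyz in res.atoms.items():
            d, _ = tree.query(xyz)
            if d > cutoff:
                continue
            het_idx = len(hetero_atoms)
            hetero_atoms.append((res.name, atom_name, np.asarray(xyz, dtype=float)))
            for atom_idx, lig_xyz in enumerate(lig_coords):
                if np.linalg.norm(lig_xyz - xyz) <= cutoff:
                    hetero_contacts.append((atom_idx, het_idx))
    return PocketContacts(residues, contacts, hetero_atoms, hetero_contacts)


def _atom_type_onehot(symbol: str) -> np.ndarray:
    row = np.zeros(len(ATOM_TYPES))
    if symbol in HALOGENS:
        row[ATOM_TYPES.index("halogen")] = 1.0
    elif symbol in METALS:
        row[ATOM_TYPES.index("metal")] = 1.0
    elif symbol in ATOM_TYPES:
        row[ATOM_TYPES.index(symbol)] = 1.0
    return row


def _ligand_atom_row(atom: Chem.Atom, schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.node_width)
    off = schema.node_offset
    row[off("atom_type"):off("atom_type") + len(ATOM_TYPES)] = _atom_type_onehot(
        atom.GetSymbol()
    )
    row[off("in_ring")] = float(atom.IsInRing())
    hyb = str(atom.GetHybridization())
    if hyb in HYBRIDIZATIONS:
        row[off("hybridization") + HYBRIDIZATIONS.index(hyb)] = 1.0
    row[off("formal_charge")] = float(atom.GetFormalCharge())
    row[off("aromatic")] = float(atom.GetIsAromatic())
    row[off("atomic_mass")] = atom.GetMass() / 100.0
    row[off("n_hydrogens")] = float(atom.GetTotalNumHs())
    row[off("degree")] = float(atom.GetDegree())
    tag = atom.GetChiralTag()
    if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
        row[off("chirality")] = 1.0
    elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
        row[off("chirality") + 1] = 1.0
    return row


def _residue_row(res: Residue, embedding: np.ndarray | None, schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.node_width)
    if res.name in AMINO_ACIDS:
        row[schema.node_offset("amino_acid") + AMINO_ACIDS.index(res.name)] = 1.0
    if embedding is not None:
        off = schema.node_offset("residue_embedding")
        row[off:off + schema.residue_embedding_width] = embedding
    return row


def _hetero_row(atom_name: str, schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.node_width)
    symbol = atom_name[:2].capitalize() if len(atom_name) > 1 else atom_name
    onehot = _atom_type_onehot(symbol)
    if not onehot.any():
        onehot = _atom_type_onehot(atom_name[0].upper())
    off = schema.node_offset("atom_type")
    row[off:off + len(ATOM_TYPES)] = onehot
    return row


def _covalent_edge_row(bond: Chem.Bond, length: float, schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.edge_width)
    off = schema.edge_offset
    row[off("edge_type") + EDGE_TYPES.index("covalent")] = 1.0
    row[off("distances")] = length
    btype = str(bond.GetBondType())
    if btype in BOND_TYPES:
        row[off("bond_type") + BOND_TYPES.index(btype)] = 1.0
    row[off("conjugated")] = float(bond.GetIsConjugated())
    row[off("in_ring")] = float(bond.IsInRing())
    stereo = bond.GetStereo()
    if stereo in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
        row[off("stereo")] = 1.0
    elif stereo in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
        row[off("stereo") + 1] = 1.0
    return row


def _interaction_edge_row(distances: np.ndarray, schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.edge_width)
    off = schema.edge_offset
    row[off("edge_type") + EDGE_TYPES.index("noncovalent")] = 1.0
    row[off("distances"):off("distances") + 4] = distances
    return row


def _self_loop_row(schema: FeatureSchema) -> np.ndarray:
    row = np.zeros(schema.edge_width)
    row[schema.edge_offset("edge_type") + EDGE_TYPES.index("self_loop")] = 1.0
    return row


def build_graph(
    record: ComplexRecord,
    schema: FeatureSchema | None = None,
    provider: EmbeddingProvider | None = None,
    cutoff: float = 5.0,
) -> InteractionGraph:
    """Build the featurized interaction graph of a preprocessed complex.

    Raises :class:`MissingBackboneError` when a pocket residue lacks the
    N/Ca/C atoms needed for the interaction-edge distance features (such a
    complex should have been dropped in preprocessing).
    """
    if schema is None:
        schema = FeatureSchema(
            residue_embedding_width=provider.residue_width if provider else 0,
            global_width=provider.ligand_width if provider else 8,
        )
    mol = record.ligand.heavy_mol()
    lig_coords = record.ligand.heavy_atom_coords()
    pocket = find_pocket(record.protein, record.ligand, cutoff)

    node_rows: list[np.ndarray] = []
    roles: list[int] = []
    for atom in mol.GetAtoms():
        node_rows.append(_ligand_atom_row(atom, schema))
        roles.append(ROLE_LIGAND)

    residue_embeddings = None
    if provider is not None and pocket.residues:
        sequence = record.protein.sequence()
        full = provider.residue_embeddings(sequence)
        polymer = record.protein.polymer_residues()
        index_of = {id(res): i for i, res in enumerate(polymer)}
        residue_embeddings = [full[index_of[id(res)]] for res in pocket.residues]

    residue_offset = len(node_rows)
    for k, res in enumerate(pocket.residues):
        if not res.has_backbone():
            raise MissingBackboneError(
                f"{record.id}: pocket residue {res.name}{res.index} lacks N/CA/C"
            )
        emb = residue_embeddings[k] if residue_embeddings is not None else None
        node_rows.append(_residue_row(res, emb, schema))
        roles.append(ROLE_RESIDUE)

    hetero_offset = len(node_rows)
    for name, atom_name, _ in pocket.hetero_atoms:
        node_rows.append(_hetero_row(atom_name, schema))
        roles.append(ROLE_HETEROATOM)

    src: list[int] = []
    dst: list[int] = []
    edge_rows: list[np.ndarray] = []

    def add_undirected(i: int, j: int, row: np.ndarray) -> None:
        src.extend((i, j))
        dst.extend((j, i))
        edge_rows.extend((row, row.copy()))

    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        length = float(np.linalg.norm(lig_coords[i] - lig_coords[j]))
        add_undirected(i, j, _covalent_edge_row(bond, length, schema))

    for atom_idx, res_idx in pocket.contacts:
        res = pocket.residues[res_idx]
        anchor = [res.atoms["N"], res.atoms["CA"], res.atoms["C"],
                  virtual_cbeta(res.atoms["N"], res.atoms["CA"], res.atoms["C"])]
        distances = np.asarray(
            [np.linalg.norm(lig_coords[atom_idx] - a) for a in anchor]
        )
        add_undirected(
            atom_idx, residue_offset + res_idx, _interaction_edge_row(distances, schema)
        )

    for atom_idx, het_idx in pocket.hetero_contacts:
        xyz = pocket.hetero_atoms[het_idx][2]
        d = float(np.linalg.norm(lig_coords[atom_idx] - xyz))
        # heteroatoms have no backbone: single distance in the first slot
        add_undirected(
            atom_idx,
            hetero_offset + het_idx,
            _interaction_edge_row(np.asarray([d, 0.0, 0.0, 0.0]), schema),
        )

    for i in range(len(node_rows)):
        src.append(i)
        dst.append(i)
        edge_rows.append(_self_loop_row(schema))

    if provider is not None:
        global_features = provider.ligand_embedding(record.ligand.line_notation)
    else:
        global_features = np.zeros(schema.global_width)

    graph = InteractionGraph(
        id=record.id,
        node_features=np.asarray(node_rows, dtype=float),
        edge_index=np.asarray([src, dst], dtype=np.int64),
        edge_features=(
            np.asarray(edge_rows, dtype=float)
            if edge_rows
            else np.zeros((0, schema.edge_width))
        ),
        global_features=np.asarray(global_features, dtype=float),
        node_roles=np.asarray(roles, dtype=np.int64),
        label=record.pk,
        schema_version=schema.version,
    )
    graph.validate()
    return graph


def ablate_protein(graph: InteractionGraph) -> InteractionGraph:
    """Drop every protein node (residues and heteroatoms) from a graph.

    Keeps the ligand's covalent topology, its self-loops, the global
    features and the label; idempotent on already ligand-only graphs.
    """
    keep_nodes = np.flatnonzero(graph.node_roles == ROLE_LIGAND)
    remap = -np.ones(graph.n_nodes, dtype=np.int64)
    remap[keep_nodes] = np.arange(len(keep_nodes))
    src, dst = graph.edge_index
    keep_edges = (remap[src] >= 0) & (remap[dst] >= 0)
    return InteractionGraph(
        id=graph.id,
        node_features=graph.node_features[keep_nodes].copy(),
        edge_index=np.stack([remap[src[keep_edges]], remap[dst[keep_edges]]]),
        edge_features=graph.edge_features[keep_edges].copy(),
        global_features=graph.global_features.copy(),
        node_roles=graph.node_roles[keep_nodes].copy(),
        label=graph.label,
        schema_version=graph.schema_version,
    )


def save_graph(graph: InteractionGraph, path: str | Path) -> None:
    """Serialize one graph to ``.npz`` (bit-exact round trip)."""
    meta = {"id": graph.id, "label": graph.label, "schema_version": graph.schema_version}
    np.savez(
        path,
        node_features=graph.node_features,
        edge_index=graph.edge_index,
        edge_features=graph.edge_features,
        global_features=graph.global_features,
        node_roles=graph.node_roles,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_graph(path: str | Path) -> InteractionGraph:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        return InteractionGraph(
            id=meta["id"],
            node_features=data["node_features"],
            edge_index=data["edge_index"],
            edge_features=data["edge_features"],
            global_features=data["global_features"],
            node_roles=data["node_roles"],
            label=meta["label"],
            schema_version=meta["schema_version"],
        )
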