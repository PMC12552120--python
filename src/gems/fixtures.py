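"""Synthetic protein-ligand complexes with controlled similarity structure.

Every algorithm in this package is testable without downloads: this module
generates toy helical proteins, small decorated ligands and whole datasets
("scenarios") in which the pairwise Tanimoto / TM / RMSD / delta-pK
relationships are planted by construction. Planted leaked pairs are exact
structural copies of a test complex with a nearby label; planted redundancy
clusters are groups of near-identical training complexes. Everything else
is built from distinct scaffolds and distinct backbone geometries so it
stays clear of the filter thresholds.

Scenarios are self-verifying: after generation the actual similarity
matrices are computed with the fixture aligner and every pair is checked to
sit at least a safety margin (0.05) away from the thresholds it is meant to
trigger or avoid; realization failures raise rather than silently yielding
an ambiguous ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .cleansplit import (
    LEAK_COMBINED,
    LEAK_DPK,
    LEAK_TANIMOTO_IDENTITY,
    LEAK_TM,
    REDUND_COMBINED,
    REDUND_DPK,
    REDUND_TM,
)
from .complexes import (
    AffinityLabel,
    ComplexRecord,
    LigandMolecule,
    ProteinStructure,
    Residue,
)
from .similarity import Aligner, KabschAligner, SimilarityTable, similarity_matrix

MARGIN = 0.05

_AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Small built-in scaffold library (each has >= 5 heavy atoms).
SCAFFOLDS: dict[str, str] = {
    "phenol": "c1ccccc1O",
    "picoline": "Cc1ccncc1",
    "cyclohexylamine": "NC1CCCCC1",
    "naphthalene": "c1ccc2ccccc2c1",
    "acetanilide": "CC(=O)Nc1ccccc1",
    "thiophene_acid": "OC(=O)c1cccs1",
    "furfurylamine": "NCc1ccco1",
    "pipecolamide": "NC(=O)C1CCNCC1",
    "azaindole": "c1cc2cc[nH]c2nc1",
    "ribose": "OCC1OC(O)C(O)C1O",
    "benzenesulfonamide": "NS(=O)(=O)c1ccccc1",
    "ibuprofen": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "methyl_benzoate": "COC(=O)c1ccccc1",
    "thf_methanol": "OCC1CCCO1",
    "acetylpiperazine": "CC(=O)N1CCNCC1",
    "fluorobenzonitrile": "N#Cc1ccc(F)cc1",
    "cyclopropylbenzene": "C1CC1c1ccccc1",
    "succinate": "OC(=O)CCC(=O)O",
    "methylquinone": "CC1=CC(=O)C=CC1=O",
    "pyridyl_acetamide": "CC(=O)Nc1ccccn1",
    "cyclohexanecarboxylate": "OC(=O)C1CCCCC1",
    "ethyl_benzoate": "CCOC(=O)c1ccccc1",
    "toluidine": "Cc1ccc(N)cc1",
    "chlorobenzylamine": "NCc1ccc(Cl)cc1",
}

_DECORATIONS = ("C", "N", "O", "F", "Cl")


class ScenarioRealizationError(RuntimeError):
    """A generated dataset failed its planted-regime verification."""


def make_toy_protein(
    length: int,
    seed: int,
    twist_deg: float | None = None,
    rise: float = 1.5,
    wobble: float = 0.3,
) -> ProteinStructure:
    """Idealized helical backbone with a randomized sequence.

    Calpha atoms lie on a helix (default rise 1.5 A per residue, ~100 deg
    turn); N and C are placed off the local tangent so the backbone frame is
    never degenerate. The twist is drawn per seed (88-112 deg) unless given,
    so two independent seeds produce geometrically distinct folds, and a
    small coordinate wobble breaks residual symmetry.
    """
    if length < 8:
        raise ValueError("toy proteins need at least 8 residues")
    rng = np.random.default_rng(seed)
    if twist_deg is None:
        twist_deg = float(rng.uniform(88.0, 112.0))
    theta = np.deg2rad(twist_deg) * np.arange(length)
    radius = 2.3
    ca = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(length)],
        axis=1,
    )
    ca = ca + rng.normal(0.0, wobble, size=ca.shape)
    residues: list[Residue] = []
    names = rng.choice(_AA3, size=length)
    for i in range(length):
        prev_ca = ca[i - 1] if i > 0 else ca[i] - np.array([0.0, 0.0, rise])
        next_ca = ca[i + 1] if i < length - 1 else ca[i] + np.array([0.0, 0.0, rise])
        tangent = next_ca - prev_ca
        tangent = tangent / np.linalg.norm(tangent)
        radial = np.array([np.cos(theta[i]), np.sin(theta[i]), 0.0])
        n_atom = ca[i] - 0.75 * tangent - 0.55 * radial
        c_atom = ca[i] + 0.75 * tangent - 0.55 * radial
        o_atom = c_atom - 0.6 * radial
        residues.append(
            Residue(
                name=str(names[i]),
                chain="A",
                index=i + 1,
                atoms={"N": n_atom, "CA": ca[i], "C": c_atom, "O": o_atom},
            )
        )
    return ProteinStructure(residues=residues)


def transform_protein(
    protein: ProteinStructure, rotation: np.ndarray, translation: np.ndarray
) -> ProteinStructure:
    """Apply a rigid transform to every atom (new structure, same metadata)."""
    residues = [
        Residue(
            name=r.name,
            chain=r.chain,
            index=r.index,
            atoms={k: rotation @ v + translation for k, v in r.atoms.items()},
            is_hetero=r.is_hetero,
        )
        for r in protein.residues
    ]
    return ProteinStructure(residues=residues, resolution=protein.resolution)


def transform_ligand(
    ligand: LigandMolecule, rotation: np.ndarray, translation: np.ndarray
) -> LigandMolecule:
    mol = Chem.Mol(ligand.mol)
    conf = mol.GetConformer()
    for idx in range(mol.GetNumAtoms()):
        p = conf.GetAtomPosition(idx)
        x, y, z = rotation @ np.array([p.x, p.y, p.z]) + translation
        conf.SetAtomPosition(idx, (float(x), float(y), float(z)))
    return LigandMolecule(mol=mol, line_notation=ligand.line_notation)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_toy_ligand(
    scaffold: str, decoration_count: int = 0, seed: int = 0
) -> LigandMolecule:
    """A valid 3-D ligand built from a scaffold with optional decorations.

    ``scaffold`` is a key of :data:`SCAFFOLDS` or a line notation. Each
    decoration attaches one small substituent at a random position with free
    valence, moving the fingerprint away from the bare scaffold.
    """
    smiles = SCAFFOLDS.get(scaffold, scaffold)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad scaffold {scaffold!r}")
    rng = np.random.default_rng(seed)
    work = Chem.RWMol(mol)
    for _ in range(decoration_count):
        candidates = [
            a.GetIdx()
            for a in work.GetAtoms()
            if a.GetImplicitValence() > 0 and a.GetAtomicNum() == 6
        ]
        if not candidates:
            break
        anchor = int(rng.choice(candidates))
        new_idx = work.AddAtom(Chem.Atom(str(rng.choice(_DECORATIONS))))
        work.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
        Chem.SanitizeMol(work)
    final = work.GetMol()
    Chem.SanitizeMol(final)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed % (2**31 - 1))
    if AllChem.EmbedMolecule(final, params) != 0:
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(final, params) != 0:
            raise ValueError(f"3-D embedding failed for scaffold {scaffold!r}")
    return LigandMolecule(mol=final)


def place_ligand_near_protein(
    ligand: LigandMolecule, protein: ProteinStructure, rng: np.random.Generator,
    offset: float = 4.0,
) -> LigandMolecule:
    """Translate the ligand so it binds the outside of the mid-helix."""
    ca = protein.ca_coords()
    mid = ca[len(ca) // 2]
    axis_point = np.array([0.0, 0.0, mid[2]])
    outward = mid - axis_point
    outward = outward / np.linalg.norm(outward)
    site = mid + offset * outward
    coords = ligand.heavy_atom_coords()
    shift = site - coords.mean(axis=0)
    return transform_ligand(ligand, np.eye(3), shift)


def _record(
    cid: str,
    protein: ProteinStructure,
    ligand: LigandMolecule,
    pk: float,
    subset: str,
    resolution: float | None,
) -> ComplexRecord:
    molar = 10.0 ** (-pk)
    label = AffinityLabel(
        pk=pk, measure_kind="Kd", exact=True,
        raw_expression=f"Kd={molar:.3e}M",
    )
    return ComplexRecord(
        id=cid, protein=protein, ligand=ligand, label=label,
        subset=subset, resolution=resolution,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Size and planting parameters of a synthetic dataset scenario."""

    n_background_train: int = 10
    n_test: int = 5
    n_overlap: int = 3          # planted leaked training complexes
    n_clusters: int = 2         # planted redundancy clusters
    cluster_size: int = 3
    label_range: tuple[float, float] = (2.0, 12.0)
    protein_length: int = 40
    seed: int = 0
    max_retries: int = 5

    def __post_init__(self) -> None:
        needed = self.n_background_train + self.n_test + self.n_clusters
        if needed > len(SCAFFOLDS):
            raise ValueError(
                f"scenario needs {needed} distinct scaffolds, "
                f"library has {len(SCAFFOLDS)}"
            )
        if self.n_overlap > self.n_test:
            raise ValueError("cannot plant more overlaps than test complexes")


@dataclass
class Scenario:
    """A realized synthetic dataset with its ground truth and similarity tables."""

    train: list[ComplexRecord]
    test: list[ComplexRecord]
    planted_overlap_ids: set[str]
    redundancy_clusters: list[set[str]]
    train_test_table: SimilarityTable
    train_train_table: SimilarityTable
    spec: ScenarioSpec

    @property
    def train_ids(self) -> list[str]:
        return [r.id for r in self.train]

    @property
    def test_ids(self) -> list[str]:
        return [r.id for r in self.test]

    def train_labels(self) -> dict[str, float]:
        return {r.id: r.pk for r in self.train}

    def test_labels(self) -> dict[str, float]:
        return {r.id: r.pk for r in self.test}

    def subsets(self) -> dict[str, str]:
        return {r.id: r.subset for r in self.train}

    def resolutions(self) -> dict[str, float | None]:
        return {r.id: r.resolution for r in self.train}


def _build_scenario(spec: ScenarioSpec, salt: int) -> Scenario:
    rng = np.random.default_rng((spec.seed + 7919 * salt) % 2**31)
    scaffold_names = list(SCAFFOLDS)
    rng.shuffle(scaffold_names)
    lo, hi = spec.label_range
    seed_base = int(rng.integers(0, 2**20))

    def fresh_protein(k: int) -> ProteinStructure:
        return make_toy_protein(spec.protein_length, seed=seed_base + k)

    test: list[ComplexRecord] = []
    for i in range(spec.n_test):
        protein = fresh_protein(i)
        ligand = make_toy_ligand(
            scaffold_names[i], decoration_count=int(rng.integers(0, 3)),
            seed=seed_base + i,
        )
        ligand = place_ligand_near_protein(ligand, protein, rng)
        test.append(
            _record(f"te{i:02d}", protein, ligand, float(rng.uniform(lo, hi)),
                    "test", float(rng.uniform(1.5, 2.5)))
        )

    train: list[ComplexRecord] = []
    planted_overlap: set[str] = set()
    # Planted leakage: structural copies of test complexes with nearby labels.
    for i in range(spec.n_overlap):
        source = test[i]
        delta = float(rng.uniform(-(LEAK_DPK - 2 * MARGIN), LEAK_DPK - 2 * MARGIN))
        pk = float(np.clip(source.pk + delta, lo, hi))
        cid = f"tr_leak{i:02d}"
        train.append(
            _record(cid, source.protein, source.ligand, pk,
                    str(rng.choice(["general", "refined"])),
                    float(rng.uniform(1.5, 3.0)))
        )
        planted_overlap.add(cid)

    # Background training complexes: distinct scaffolds and geometries.
    for i in range(spec.n_background_train):
        protein = fresh_protein(100 + i)
        ligand = make_toy_ligand(
            scaffold_names[spec.n_test + i],
            decoration_count=int(rng.integers(0, 3)),
            seed=seed_base + 100 + i,
        )
        ligand = place_ligand_near_protein(ligand, protein, rng)
        train.append(
            _record(f"tr_bg{i:02d}", protein, ligand, float(rng.uniform(lo, hi)),
                    str(rng.choice(["general", "refined"])),
                    float(rng.uniform(1.5, 3.0)))
        )

    # Planted redundancy clusters: near-identical copies within the train set.
    clusters: list[set[str]] = []
    for c in range(spec.n_clusters):
        protein = fresh_protein(200 + c)
        ligand = make_toy_ligand(
            scaffold_names[spec.n_test + spec.n_background_train + c],
            decoration_count=1, seed=seed_base + 200 + c,
        )
        ligand = place_ligand_near_protein(ligand, protein, rng)
        base_pk = float(rng.uniform(lo + 1, hi - 1))
        members: set[str] = set()
        for m in range(spec.cluster_size):
            offset = float(
                rng.uniform(-(REDUND_DPK / 2 - MARGIN), REDUND_DPK / 2 - MARGIN)
            )
            cid = f"tr_red{c}{m}"
            train.append(
                _record(cid, protein, ligand, base_pk + offset,
                        str(rng.choice(["general", "refined"])),
                        float(rng.uniform(1.5, 3.0)))
            )
            members.add(cid)
        clusters.append(members)

    aligner = KabschAligner()
    train_test = similarity_matrix(train, test, aligner)
    train_train = similarity_matrix(train, train, aligner)
    scenario = Scenario(
        train=train,
        test=test,
        planted_overlap_ids=planted_overlap,
        redundancy_clusters=clusters,
        train_test_table=train_test,
        train_train_table=train_train,
        spec=spec,
    )
    _verify_scenario(scenario)
    return scenario


def _verify_scenario(scenario: Scenario) -> None:
    """Check every pair sits >= MARGIN away from the thresholds it must
    trigger or avoid; raise naming the first offending pair otherwise."""
    cluster_of = {cid: k for k, members in enumerate(scenario.redundancy_clusters)
                  for cid in members}
    for tr in scenario.train:
        for te in scenario.test:
            sim = scenario.train_test_table.get(tr.id, te.id)
            if tr.id in scenario.planted_overlap_ids and te.id == f"te{tr.id[-2:]}":
                ok = (
                    sim.tanimoto >= LEAK_TANIMOTO_IDENTITY + MARGIN
                    and sim.tm_score >= LEAK_TM + MARGIN
                    and sim.delta_pk <= LEAK_DPK - MARGIN
                )
                if not ok:
                    raise ScenarioRealizationError(
                        f"planted overlap ({tr.id}, {te.id}) missed its regime: {sim}"
                    )
            else:
                near_identity = (
                    sim.tanimoto > LEAK_TANIMOTO_IDENTITY - MARGIN
                    and sim.delta_pk <= LEAK_DPK + MARGIN
                )
                near_structural = (
                    sim.tm_score > LEAK_TM - MARGIN
                    and sim.tanimoto + (1.0 - sim.ligand_rmsd) > LEAK_COMBINED - MARGIN
                    and sim.delta_pk <= LEAK_DPK + MARGIN
                )
                if near_identity or near_structural:
                    raise ScenarioRealizationError(
                        f"unplanted pair ({tr.id}, {te.id}) is too close to the "
                        f"leakage thresholds: {sim}"
                    )
    ids = scenario.train_ids
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1:]:
            sim = scenario.train_train_table.get(id_a, id_b)
            same_cluster = (
                id_a in cluster_of and cluster_of.get(id_a) == cluster_of.get(id_b)
            )
            if same_cluster:
                ok = (
                    sim.tm_score >= REDUND_TM + MARGIN
                    and sim.tanimoto + (1.0 - sim.ligand_rmsd)
                    >= REDUND_COMBINED + MARGIN
                    and sim.delta_pk <= REDUND_DPK - MARGIN
                )
                if not ok:
                    raise ScenarioRealizationError(
                        f"planted cluster pair ({id_a}, {id_b}) missed its regime: {sim}"
                    )
            else:
                near = (
                    sim.tm_score > REDUND_TM - MARGIN
                    and sim.tanimoto + (1.0 - sim.ligand_rmsd)
                    > REDUND_COMBINED - MARGIN
                    and sim.delta_pk < REDUND_DPK + MARGIN
                )
                if near:
                    raise ScenarioRealizationError(
                        f"unplanted train pair ({id_a}, {id_b}) is too close to the "
                        f"redundancy thresholds: {sim}"
                    )


def make_toy_graphs(
    n: int,
    seed: int = 0,
    label_mode: str = "global_linear",
    node_width: int = 10,
    edge_width: int = 6,
    global_width: int = 4,
) -> list["InteractionGraph"]:
    """Small random interaction graphs with controllable label structure.

    ``label_mode`` decides where the label signal lives:

    * ``"global_linear"`` -- the label is a linear function of the first
      global feature (pK = 7 + 2 * g0), so it is learnable from the global
      channel alone;
    * ``"interaction_distance"`` -- the label is a linear function of the
      mean ligand-residue interaction-edge distance, so deleting the
      protein nodes destroys the signal entirely.

    Used by the model-training sanity checks and the ablation study.
    """
    from .graphs import InteractionGraph, ROLE_LIGAND, ROLE_RESIDUE

    rng = np.random.default_rng(seed)
    graphs: list[InteractionGraph] = []
    for g_idx in range(n):
        n_lig = int(rng.integers(3, 7))
        n_res = int(rng.integers(2, 4))
        n_nodes = n_lig + n_res
        # low-amplitude node noise: the label-bearing signal lives in the
        # global features or the edge distances, never in the node features
        node_features = 0.2 * rng.standard_normal((n_nodes, node_width))
        roles = np.array([ROLE_LIGAND] * n_lig + [ROLE_RESIDUE] * n_res)
        src: list[int] = []
        dst: list[int] = []
        edge_rows: list[np.ndarray] = []

        def undirected(i: int, j: int, row: np.ndarray) -> None:
            src.extend((i, j))
            dst.extend((j, i))
            edge_rows.extend((row, row.copy()))

        for i in range(n_lig - 1):  # covalent chain through the ligand
            row = np.zeros(edge_width)
            row[0] = 1.0
            row[3] = rng.uniform(1.3, 1.6)
            undirected(i, i + 1, row)
        interaction_distances = []
        for r in range(n_res):  # each residue contacts one random ligand atom
            atom = int(rng.integers(0, n_lig))
            d = float(rng.uniform(2.5, 5.0))
            interaction_distances.append(d)
            row = np.zeros(edge_width)
            row[2] = 1.0
            row[3] = d
            undirected(atom, n_lig + r, row)
        for i in range(n_nodes):
            row = np.zeros(edge_width)
            row[1] = 1.0
            src.append(i)
            dst.append(i)
            edge_rows.append(row)
        global_features = rng.standard_normal(global_width)
        if label_mode == "global_linear":
            label = 7.0 + 2.0 * global_features[0]
        elif label_mode == "interaction_distance":
            label = 2.0 * (float(np.mean(interaction_distances)) - 3.75) + 7.0
        else:
            raise ValueError(f"unknown label mode {label_mode!r}")
        graphs.append(
            InteractionGraph(
                id=f"toy{g_idx:03d}",
                node_features=node_features,
                edge_index=np.asarray([src, dst], dtype=np.int64),
                edge_features=np.asarray(edge_rows),
                global_features=global_features,
                node_roles=roles,
                label=float(label),
            )
        )
    return graphs


def make_scenario(spec: ScenarioSpec = ScenarioSpec()) -> Scenario:
    """Generate a self-verified scenario; retries with fresh randomness on
    realization failures, then raises the last error."""
    last: ScenarioRealizationError | None = None
    for salt in range(spec.max_retries):
        try:
            return _build_scenario(spec, salt)
        except ScenarioRealizationError as exc:
            last = exc
    raise last  # type: ignore[misc]
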