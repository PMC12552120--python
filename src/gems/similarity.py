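"""Pairwise similarity metrics for protein-ligand complexes.

Four metrics quantify how alike two complexes are:

* **Tanimoto** similarity between count-based circular fingerprints of the
  ligands (radius 2, 2048 buckets): sum(min)/sum(max) over buckets.
* **TM-score** of the protein structures, normalized by both chain lengths
  with the larger value used, so a protein embedded in a bigger one still
  scores high.
* **Pocket-aligned ligand RMSD**: ligand coordinates are carried through the
  protein superposition and compared by nearest-neighbour RMSD, so it
  measures whether the ligands occupy the same place in the aligned pockets.
* **delta pK**: absolute difference of the affinity labels.

They combine into the display score ``S = TM + Tanimoto + (1 - RMSD) - dpK``.

Structural alignment is a pluggable contract: the default
:class:`KabschAligner` superposes index-matched Calpha atoms by least
squares (suitable for synthetic fixtures with known correspondence), while
:class:`TMAlignAligner` shells out to an external TM-align binary when one
is installed.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit.Chem import rdFingerprintGenerator
from scipy.spatial import cKDTree

from .complexes import ComplexRecord, LigandMolecule, ProteinStructure

FINGERPRINT_RADIUS = 2
FINGERPRINT_SIZE = 2048

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(
    radius=FINGERPRINT_RADIUS, fpSize=FINGERPRINT_SIZE
)


@dataclass(frozen=True)
class CountFingerprint:
    """Sparse count fingerprint: bucket index -> non-negative count."""

    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        for bucket, count in self.counts.items():
            if not (0 <= bucket < FINGERPRINT_SIZE):
                raise ValueError(f"bucket {bucket} out of range")
            if count < 0:
                raise ValueError(f"negative count for bucket {bucket}")


def ligand_fingerprint(ligand: LigandMolecule) -> CountFingerprint:
    """Count-based circular fingerprint (radius 2, 2048 buckets) of a ligand."""
    try:
        fp = _MORGAN.GetCountFingerprint(ligand.heavy_mol())
    except Exception as exc:
        raise ValueError(f"fingerprint failed for {ligand.line_notation!r}: {exc}") from exc
    return CountFingerprint(counts=dict(fp.GetNonzeroElements()))


def tanimoto_count(a: CountFingerprint, b: CountFingerprint) -> float:
    """Tanimoto similarity for count fingerprints: sum(min) / sum(max).

    Two empty fingerprints are identical by convention and score 1.0.
    """
    buckets = set(a.counts) | set(b.counts)
    if not buckets:
        return 1.0
    num = sum(min(a.counts.get(k, 0), b.counts.get(k, 0)) for k in buckets)
    den = sum(max(a.counts.get(k, 0), b.counts.get(k, 0)) for k in buckets)
    return num / den


@dataclass
class StructuralAlignment:
    """Rigid superposition of protein B onto protein A with TM-scores.

    ``transform`` maps coordinates expressed in B's frame into A's frame:
    ``x_a = R @ x_b + t``.
    """

    rotation: np.ndarray      # (3, 3) orthonormal
    translation: np.ndarray   # (3,)
    tm_norm_a: float          # normalized by chain A length
    tm_norm_b: float          # normalized by chain B length
    seq_identity: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")

    def transform(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def tm_score(alignment: StructuralAlignment) -> float:
    """Similarity score of an alignment: the larger of the two normalizations."""
    return max(alignment.tm_norm_a, alignment.tm_norm_b)


class AlignmentError(RuntimeError):
    """Structural alignment failed; carries both complex identifiers."""


class Aligner(Protocol):
    def align(self, a: ProteinStructure, b: ProteinStructure) -> StructuralAlignment:
        ...


def _tm_d0(length: int) -> float:
    """Length-dependent distance scale of the TM-score, floored at 0.5 A."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def _tm_from_distances(distances: np.ndarray, norm_length: int) -> float:
    d0 = _tm_d0(norm_length)
    return float(np.sum(1.0 / (1.0 + (distances / d0) ** 2)) / norm_length)


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with target ~ moving @ R.T + t."""
    mu_m = moving.mean(axis=0)
    mu_t = target.mean(axis=0)
    h = (moving - mu_m).T @ (target - mu_t)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_t - rot @ mu_m
    return rot, trans


class KabschAligner:
    """Least-squares superposition on index-matched Calpha atoms.

    Residue correspondence is positional (residue i of A pairs with residue
    i of B over the shorter chain), so this aligner is meant for synthetic
    structures where the correspondence is known by construction, not for
    detecting remote structural homology in real proteins.
    """

    def align(self, a: ProteinStructure, b: ProteinStructure) -> StructuralAlignment:
        ca_a = a.ca_coords()
        ca_b = b.ca_coords()
        if len(ca_a) < 3 or len(ca_b) < 3:
            raise AlignmentError("need at least 3 Calpha coordinates per protein")
        n = min(len(ca_a), len(ca_b))
        rot, trans = kabsch(ca_b[:n], ca_a[:n])
        moved = ca_b[:n] @ rot.T + trans
        dist = np.linalg.norm(ca_a[:n] - moved, axis=1)
        seq_a = a.sequence()[:n]
        seq_b = b.sequence()[:n]
        ident = sum(x == y for x, y in zip(seq_a, seq_b)) / n if n else 0.0
        return StructuralAlignment(
            rotation=rot,
            translation=trans,
            tm_norm_a=_tm_from_distances(dist, len(ca_a)),
            tm_norm_b=_tm_from_distances(dist, len(ca_b)),
            seq_identity=ident,
        )


class TMAlignAligner:
    """Adapter that runs an external TM-align binary.

    Parses both length normalizations, the sequence identity and the
    rotation matrix (``-m`` output). Raises :class:`AlignmentError` when the
    binary is missing or fails.
    """

    def __init__(self, executable: str = "TMalign") -> None:
        self.executable = executable

    def align(self, a: ProteinStructure, b: ProteinStructure) -> StructuralAlignment:
        from .io import write_protein_pdb

        if shutil.which(self.executable) is None:
            raise AlignmentError(
                f"TM-align binary {self.executable!r} not found on PATH; "
                "use KabschAligner for fixture data"
            )
        with tempfile.TemporaryDirectory() as tmp:
            pa = Path(tmp) / "a.pdb"
            pb = Path(tmp) / "b.pdb"
            matrix = Path(tmp) / "matrix.txt"
            write_protein_pdb(a, pa)
            write_protein_pdb(b, pb)
            # TM-align's "Chain_1" is its first argument; we pass B first so
            # the reported matrix maps B onto A.
            proc = subprocess.run(
                [self.executable, str(pb), str(pa), "-m", str(matrix)],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise AlignmentError(f"TM-align failed: {proc.stderr[:500]}")
            return _parse_tmalign_output(proc.stdout, matrix.read_text())


def _parse_tmalign_output(stdout: str, matrix_text: str) -> StructuralAlignment:
    tm_b = tm_a = seq_id = None
    for line in stdout.splitlines():
        if line.startswith("TM-score=") and "Chain_1" in line:
            tm_b = float(line.split("=")[1].split()[0])
        elif line.startswith("TM-score=") and "Chain_2" in line:
            tm_a = float(line.split("=")[1].split()[0])
        elif "Seq_ID" in line:
            seq_id = float(line.rstrip().split("=")[-1])
    rows = []
    trans = []
    for line in matrix_text.splitlines():
        parts = line.split()
        if parts and parts[0] in ("0", "1", "2") and len(parts) == 5:
            trans.append(float(parts[1]))
            rows.append([float(x) for x in parts[2:5]])
    if tm_a is None or tm_b is None or len(rows) != 3:
        raise AlignmentError("could not parse TM-align output")
    return StructuralAlignment(
        rotation=np.asarray(rows),
        translation=np.asarray(trans),
        tm_norm_a=tm_a,
        tm_norm_b=tm_b,
        seq_identity=seq_id if seq_id is not None else 0.0,
    )


def pocket_aligned_ligand_rmsd(
    lig_a: np.ndarray, lig_b: np.ndarray, alignment: StructuralAlignment
) -> float:
    """Nearest-neighbour RMSD between ligand atom clouds after superposition.

    ``lig_b`` is carried through the protein alignment first. With unequal
    atom counts, distances run from each atom of the larger cloud to its
    nearest neighbour in the smaller one (penalizing size mismatch); with
    equal counts, from each atom of A to its nearest neighbour in B.
    """
    lig_a = np.asarray(lig_a, dtype=float)
    lig_b = np.asarray(lig_b, dtype=float)
    if lig_a.size == 0 or lig_b.size == 0:
        raise ValueError("ligand coordinate sets must be non-empty")
    moved_b = alignment.transform(lig_b)
    if len(moved_b) > len(lig_a):
        source, pool = moved_b, lig_a
    else:
        source, pool = lig_a, moved_b
    dists, _ = cKDTree(pool).query(source)
    return float(np.sqrt(np.mean(dists**2)))


@dataclass(frozen=True)
class PairSimilarity:
    """The four similarity metrics plus the combined S score for one pair."""

    tanimoto: float
    tm_score: float
    ligand_rmsd: float
    delta_pk: float

    @property
    def s_score(self) -> float:
        return self.tm_score + self.tanimoto + (1.0 - self.ligand_rmsd) - self.delta_pk


def pair_similarity(
    a: ComplexRecord,
    b: ComplexRecord,
    aligner: Aligner,
    fingerprints: Mapping[str, CountFingerprint] | None = None,
) -> PairSimilarity:
    """Compute all similarity metrics for one pair of complexes."""
    try:
        if fingerprints is not None:
            fp_a, fp_b = fingerprints[a.id], fingerprints[b.id]
        else:
            fp_a, fp_b = ligand_fingerprint(a.ligand), ligand_fingerprint(b.ligand)
        alignment = aligner.align(a.protein, b.protein)
        rmsd = pocket_aligned_ligand_rmsd(
            a.ligand.heavy_atom_coords(), b.ligand.heavy_atom_coords(), alignment
        )
    except Exception as exc:
        raise AlignmentError(f"similarity failed for pair ({a.id}, {b.id}): {exc}") from exc
    return PairSimilarity(
        tanimoto=tanimoto_count(fp_a, fp_b),
        tm_score=tm_score(alignment),
        ligand_rmsd=rmsd,
        delta_pk=abs(a.pk - b.pk),
    )


@dataclass
class SimilarityTable:
    """All pairwise similarities between two datasets, keyed by id pair."""

    entries: dict[tuple[str, str], PairSimilarity]
    failures: dict[tuple[str, str], str] = field(default_factory=dict)

    def get(self, id_a: str, id_b: str) -> PairSimilarity:
        try:
            return self.entries[(id_a, id_b)]
        except KeyError:
            pass
        try:
            sim = self.entries[(id_b, id_a)]
        except KeyError:
            raise KeyError(f"no similarity entry for pair ({id_a}, {id_b})") from None
        return sim

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id_a": ia,
                "id_b": ib,
                "tanimoto": s.tanimoto,
                "tm_score": s.tm_score,
                "ligand_rmsd": s.ligand_rmsd,
                "delta_pk": s.delta_pk,
                "s_score": s.s_score,
            }
            for (ia, ib), s in self.entries.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["id_a", "id_b", "tanimoto", "tm_score", "ligand_rmsd", "delta_pk", "s_score"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SimilarityTable":
        frame = pd.read_csv(path)
        entries = {
            (str(r.id_a), str(r.id_b)): PairSimilarity(
                tanimoto=r.tanimoto,
                tm_score=r.tm_score,
                ligand_rmsd=r.ligand_rmsd,
                delta_pk=r.delta_pk,
            )
            for r in frame.itertuples()
        }
        return cls(entries=entries)


def similarity_matrix(
    dataset_a: Sequence[ComplexRecord],
    dataset_b: Sequence[ComplexRecord],
    aligner: Aligner,
) -> SimilarityTable:
    """All |A| x |B| pairwise similarities.

    When the two sequences are the same object, symmetry is exploited: each
    unordered pair is computed once and mirrored. Per-pair failures are
    recorded in the table rather than aborting the whole matrix.
    """
    fingerprints: dict[str, CountFingerprint] = {}
    for rec in list(dataset_a) + list(dataset_b):
        if rec.id not in fingerprints:
            fingerprints[rec.id] = ligand_fingerprint(rec.ligand)
    entries: dict[tuple[str, str], PairSimilarity] = {}
    failures: dict[tuple[str, str], str] = {}
    symmetric = dataset_a is dataset_b
    for i, rec_a in enumerate(dataset_a):
        for j, rec_b in enumerate(dataset_b):
            if symmetric and j < i:
                continue
            if symmetric and i == j:
                entries[(rec_a.id, rec_b.id)] = PairSimilarity(1.0, 1.0, 0.0, 0.0)
                continue
            try:
                sim = pair_similarity(rec_a, rec_b, aligner, fingerprints)
            except AlignmentError as exc:
                failures[(rec_a.id, rec_b.id)] = str(exc)
                continue
            entries[(rec_a.id, rec_b.id)] = sim
            if symmetric:
                entries[(rec_b.id, rec_a.id)] = sim
    return SimilarityTable(entries=entries, failures=failures)
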