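"""Protein-ligand complex records: parsing, affinity labels and preprocessing.

This module owns the dataset layer: reading PDBbind-style index files,
protein structures (PDB) and ligand structures (SDF), converting affinity
expressions such as ``Kd=30nM`` to pK values, and applying the preprocessing
exclusion rules (inexact labels, unparseable ligands, unknown pocket
residues, unresolved pocket atoms, tiny ligands) that curate a raw dataset
before any similarity analysis or model training.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Gas constant in kcal K^-1 mol^-1, used for pK -> binding free energy.
GAS_CONSTANT_KCAL = 1.987e-3

#: The twenty standard amino acids (three-letter codes).
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_RESIDUES = {"HOH", "WAT", "DOD"}

_UNIT_TO_MOLAR = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
    "fm": 1e-15,
}

# operator taxonomy: only "=" denotes an exact measurement
_INEXACT_OPERATORS = {"<", ">", "<=", ">=", "~"}

_AFFINITY_RE = re.compile(
    r"(?P<kind>Ki|Kd|IC50)\s*(?P<op><=|>=|=|<|>|~)\s*"
    r"(?P<mag>[0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s*"
    r"(?P<unit>[a-zA-Zµ]+)",
    re.IGNORECASE,
)


class AffinityParseError(ValueError):
    """An affinity expression or index line could not be interpreted."""


def to_pk(molar: float) -> float:
    """Convert a molar concentration (Ki/Kd/IC50) to a pK value.

    pK = -log10(concentration in mol/l). Raises for non-positive input.
    """
    if not molar > 0:
        raise ValueError(f"concentration must be positive, got {molar!r}")
    return -math.log10(molar)


def delta_g(pk: float, temperature: float = 297.0) -> float:
    """Binding free energy in kcal/mol for a pK value.

    dG = -ln(10) * R * T * pK with R = 1.987e-3 kcal K^-1 mol^-1.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return -math.log(10.0) * GAS_CONSTANT_KCAL * temperature * pk


@dataclass(frozen=True)
class AffinityLabel:
    """A binding affinity measurement converted to the pK scale."""

    pk: float
    measure_kind: str  # "Ki" | "Kd" | "IC50"
    exact: bool
    raw_expression: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.pk):
            raise ValueError(f"pK must be finite, got {self.pk}")
        if self.measure_kind not in ("Ki", "Kd", "IC50"):
            raise ValueError(f"unknown measure kind {self.measure_kind!r}")


def parse_affinity_expression(expression: str) -> AffinityLabel:
    """Parse an expression like ``Kd=30nM`` or ``Ki<100nM`` into a label."""
    match = _AFFINITY_RE.search(expression)
    if match is None:
        raise AffinityParseError(f"cannot parse affinity expression {expression!r}")
    kind = match.group("kind")
    kind = {"ki": "Ki", "kd": "Kd", "ic50": "IC50"}[kind.lower()]
    operator = match.group("op")
    magnitude = float(match.group("mag"))
    unit = match.group("unit").lower()
    if unit not in _UNIT_TO_MOLAR:
        raise AffinityParseError(f"unknown unit {match.group('unit')!r} in {expression!r}")
    molar = magnitude * _UNIT_TO_MOLAR[unit]
    return AffinityLabel(
        pk=to_pk(molar),
        measure_kind=kind,
        exact=operator not in _INEXACT_OPERATORS,
        raw_expression=expression.strip(),
    )


@dataclass
class IndexEntry:
    """One row of a PDBbind-style index file."""

    id: str
    resolution: float | None
    year: int | None
    label: AffinityLabel


@dataclass
class IndexReport:
    """Per-line parse failures collected while reading an index file."""

    errors: list[tuple[int, str, str]] = field(default_factory=list)  # (line no, line, reason)

    @property
    def n_errors(self) -> int:
        return len(self.errors)


def parse_index(text: str) -> tuple[list[IndexEntry], IndexReport]:
    """Parse a PDBbind-style index file.

    Expected dialect per data line: ``<id> <resolution> <year> <-logKd/Ki>
    <affinity expression> [// comment]``; lines starting with ``#`` are
    comments. Malformed lines are collected in the report, never raised.
    """
    entries: list[IndexEntry] = []
    report = IndexReport()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < 5:
            report.errors.append((lineno, line, "fewer than 5 fields"))
            continue
        pdb_id = fields[0]
        try:
            resolution = None if fields[1].upper() in ("NMR", "NA", "-") else float(fields[1])
        except ValueError:
            report.errors.append((lineno, line, f"bad resolution field {fields[1]!r}"))
            continue
        try:
            year = int(fields[2])
        except ValueError:
            year = None
        try:
            label = parse_affinity_expression(fields[4])
        except AffinityParseError as exc:
            report.errors.append((lineno, line, str(exc)))
            continue
        entries.append(IndexEntry(id=pdb_id, resolution=resolution, year=year, label=label))
    return entries, report


def write_index(entries: Iterable[IndexEntry]) -> str:
    """Serialize entries back into the index dialect read by :func:`parse_index`."""
    lines = ["# id  resolution  year  -log(K)  affinity"]
    for e in entries:
        res = f"{e.resolution:.2f}" if e.resolution is not None else "NMR"
        year = e.year if e.year is not None else 0
        lines.append(f"{e.id}  {res}  {year}  {e.label.pk:.2f}  {e.label.raw_expression}")
    return "\n".join(lines) + "\n"


@dataclass
class Residue:
    """One protein residue (or hetero group) with its heavy-atom coordinates."""

    name: str                      # 3-letter code
    chain: str
    index: int                     # author residue number
    atoms: dict[str, np.ndarray]   # atom name -> xyz (angstrom, heavy atoms)
    is_hetero: bool = False

    @property
    def ca(self) -> np.ndarray | None:
        return self.atoms.get("CA")

    def coords(self) -> np.ndarray:
        return np.asarray(list(self.atoms.values()), dtype=float)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class ProteinStructure:
    """A protein as an ordered list of residues with heavy-atom coordinates."""

    residues: list[Residue]
    resolution: float | None = None

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]

    def hetero_residues(self) -> list[Residue]:
        """Non-water hetero groups (ions, cofactors)."""
        return [r for r in self.residues if r.is_hetero and r.name not in WATER_RESIDUES]

    def ca_coords(self) -> np.ndarray:
        """Calpha coordinates of polymer residues that have one, (L, 3)."""
        return np.asarray(
            [r.ca for r in self.polymer_residues() if r.ca is not None], dtype=float
        )

    def sequence(self) -> str:
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.polymer_residues()
        )


def read_protein_pdb(path: str | Path, resolution: float | None = None) -> ProteinStructure:
    """Read the first model of a PDB file into a :class:`ProteinStructure`.

    Hydrogens are dropped; water molecules are kept (flagged hetero) so the
    pocket logic can decide their fate explicitly.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("protein", str(path))
    model = next(structure.get_models())  # first NMR model only
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            hetflag = res.id[0].strip()
            atoms = {
                atom.get_name(): np.asarray(atom.get_coord(), dtype=float)
                for atom in res
                if atom.element != "H"
            }
            if not atoms:
                continue
            residues.append(
                Residue(
                    name=res.get_resname().strip(),
                    chain=chain.id,
                    index=res.id[1],
                    atoms=atoms,
                    is_hetero=bool(hetflag),
                )
            )
    if resolution is None:
        resolution = structure.header.get("resolution")
    return ProteinStructure(residues=residues, resolution=resolution)


@dataclass
class LigandMolecule:
    """A small-molecule ligand backed by an RDKit molecule with 3-D coordinates."""

    mol: Chem.Mol
    line_notation: str = ""

    def __post_init__(self) -> None:
        if not self.line_notation:
            self.line_notation = Chem.MolToSmiles(Chem.RemoveHs(self.mol))

    @property
    def n_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def heavy_atom_coords(self) -> np.ndarray:
        conf = self.mol.GetConformer()
        coords = [
            conf.GetAtomPosition(a.GetIdx())
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() > 1
        ]
        return np.asarray([[p.x, p.y, p.z] for p in coords], dtype=float)

    def heavy_mol(self) -> Chem.Mol:
        return Chem.RemoveHs(self.mol)


class LigandParseError(ValueError):
    """SDF parsing or sanitization failed for a ligand."""


def read_ligand_sdf(path: str | Path) -> LigandMolecule:
    """Read the first molecule of an SDF file.

    Multiple records in one file are not merged: the first is used and a
    warning is emitted. Sanitization failures raise :class:`LigandParseError`.
    """
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mols = [m for m in supplier if m is not None]
    if not mols:
        raise LigandParseError(f"no parseable molecule in {path}")
    if len(mols) > 1:
        warnings.warn(f"{path}: {len(mols)} molecules in SDF; using the first")
    mol = mols[0]
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # rdkit raises several exception types here
        raise LigandParseError(f"sanitization failed for {path}: {exc}") from exc
    return LigandMolecule(mol=mol)


@dataclass
class ComplexRecord:
    """A protein-ligand complex with its affinity label and provenance."""

    id: str
    protein: ProteinStructure
    ligand: LigandMolecule | None
    label: AffinityLabel
    subset: str = "general"          # "general" | "refined" | "test"
    resolution: float | None = None
    issues: list[str] = field(default_factory=list)  # loader-recorded problems

    @property
    def pk(self) -> float:
        return self.label.pk


# Exclusion criteria in the order they are attributed when several match.
EXCLUSION_CRITERIA = (
    "inexact_label",
    "ligand_hydrogen_error",
    "unknown_pocket_residue",
    "ligand_valence_error",
    "missing_pocket_atoms",
    "small_ligand",
    "structure_parse_error",
)

MIN_HEAVY_ATOMS = 5
POCKET_CUTOFF = 5.0  # angstrom


@dataclass
class PreprocessReport:
    """Outcome of dataset preprocessing: what was excluded and why."""

    criterion_counts: dict[str, int]
    attributed: dict[str, str]        # excluded id -> first matching criterion
    total_excluded: int
    total_kept: int

    def to_rows(self) -> list[dict[str, str]]:
        return [{"id": i, "criterion": c} for i, c in sorted(self.attributed.items())]


def _pocket_residues(record: ComplexRecord, cutoff: float = POCKET_CUTOFF) -> list[Residue]:
    from scipy.spatial import cKDTree

    lig = record.ligand.heavy_atom_coords()
    tree = cKDTree(lig)
    pocket = []
    for res in record.protein.residues:
        if res.name in WATER_RESIDUES:
            continue
        d, _ = tree.query(res.coords())
        if np.min(d) <= cutoff:
            pocket.append(res)
    return pocket


def _violations(record: ComplexRecord, cutoff: float) -> list[str]:
    found: list[str] = []
    if not record.label.exact:
        found.append("inexact_label")
    if "ligand_hydrogen_error" in record.issues:
        found.append("ligand_hydrogen_error")
    if "ligand_valence_error" in record.issues:
        found.append("ligand_valence_error")
    if "structure_parse_error" in record.issues or record.ligand is None:
        found.append("structure_parse_error")
        return found
    pocket = _pocket_residues(record, cutoff)
    if any(
        (not r.is_hetero and r.name not in STANDARD_RESIDUES)
        or r.name in ("UNK", "DOD")
        for r in pocket
    ):
        found.append("unknown_pocket_residue")
    if any(not r.is_hetero and not r.has_backbone() for r in pocket):
        found.append("missing_pocket_atoms")
    if record.ligand.n_heavy_atoms < MIN_HEAVY_ATOMS:
        found.append("small_ligand")
    return found


def preprocess_dataset(
    records: Sequence[ComplexRecord], cutoff: float = POCKET_CUTOFF
) -> tuple[list[ComplexRecord], PreprocessReport]:
    """Apply the preprocessing exclusion rules to a dataset.

    A record is dropped if it matches any criterion; the report counts every
    matched criterion (so per-criterion counts can sum to more than the
    number of exclusions) and attributes each excluded record to the first
    criterion in :data:`EXCLUSION_CRITERIA` order.
    """
    kept: list[ComplexRecord] = []
    counts = {c: 0 for c in EXCLUSION_CRITERIA}
    attributed: dict[str, str] = {}
    for record in records:
        found = _violations(record, cutoff)
        if not found:
            kept.append(record)
            continue
        for criterion in found:
            counts[criterion] += 1
        attributed[record.id] = min(found, key=EXCLUSION_CRITERIA.index)
    report = PreprocessReport(
        criterion_counts=counts,
        attributed=attributed,
        total_excluded=len(attributed),
        total_kept=len(kept),
    )
    return kept, report
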