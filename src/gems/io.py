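"""Readers and writers for the on-disk dialects used across the package.

PDB and SDF writing is needed both by the fixture generator (which emits
complete toy datasets in the same formats the real pipeline reads) and by
the TM-align adapter (which communicates through temporary PDB files).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .complexes import (
    ComplexRecord,
    IndexEntry,
    LigandMolecule,
    ProteinStructure,
    parse_index,
    read_ligand_sdf,
    read_protein_pdb,
    write_index,
)

_ELEMENT_FROM_ATOM = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OXT": "O",
}


def write_protein_pdb(protein: ProteinStructure, path: str | Path) -> None:
    """Write a protein in minimal PDB format (heavy atoms, single model)."""
    lines = []
    serial = 1
    for res in protein.residues:
        record = "HETATM" if res.is_hetero else "ATOM  "
        for atom_name, xyz in res.atoms.items():
            element = _ELEMENT_FROM_ATOM.get(atom_name, atom_name[:1])
            name_field = atom_name if len(atom_name) == 4 else f" {atom_name:<3s}"
            lines.append(
                f"{record}{serial:>5d} {name_field:<4s} {res.name:>3s} "
                f"{res.chain:1s}{res.index:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ligand_sdf(ligand: LigandMolecule, path: str | Path, name: str = "ligand") -> None:
    mol = Chem.Mol(ligand.mol)
    mol.SetProp("_Name", name)
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()


def write_dataset(
    records: Sequence[ComplexRecord], out_dir: str | Path
) -> Path:
    """Emit a dataset as PDBbind-style files: per-complex dir + index file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        cdir = out_dir / rec.id
        cdir.mkdir(exist_ok=True)
        write_protein_pdb(rec.protein, cdir / f"{rec.id}_protein.pdb")
        if rec.ligand is not None:
            write_ligand_sdf(rec.ligand, cdir / f"{rec.id}_ligand.sdf", name=rec.id)
        entries.append(
            IndexEntry(id=rec.id, resolution=rec.resolution, year=2020, label=rec.label)
        )
    (out_dir / "index.txt").write_text(write_index(entries))
    return out_dir


def read_dataset(data_dir: str | Path, subset: str = "general") -> list[ComplexRecord]:
    """Read a dataset written by :func:`write_dataset` (or shaped like one)."""
    data_dir = Path(data_dir)
    entries, report = parse_index((data_dir / "index.txt").read_text())
    records = []
    for entry in entries:
        cdir = data_dir / entry.id
        protein = read_protein_pdb(cdir / f"{entry.id}_protein.pdb", resolution=entry.resolution)
        issues: list[str] = []
        ligand = None
        try:
            ligand = read_ligand_sdf(cdir / f"{entry.id}_ligand.sdf")
        except Exception:
            issues.append("ligand_valence_error")
        records.append(
            ComplexRecord(
                id=entry.id,
                protein=protein,
                ligand=ligand,
                label=entry.label,
                subset=subset,
                resolution=entry.resolution,
                issues=issues,
            )
        )
    return records
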