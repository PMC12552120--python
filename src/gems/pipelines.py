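"""End-to-end curation pipeline against a local PDBbind-style data tree.

This is the full-scale entry point: given a locally downloaded PDBbind-style
dataset (index file plus per-complex ``<id>_protein.pdb`` /
``<id>_ligand.sdf`` directories) and held-out benchmark id lists, it runs
preprocessing, the leakage filter and the redundancy filter, and reports
the resulting counts (complexes kept after preprocessing, excluded by the
overlap filter, excluded by redundancy removal, independent test
complexes). The computation is identical to what the synthetic-scenario
tests exercise at small scale; only the inputs differ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .cleansplit import assemble_cleansplit
from .complexes import preprocess_dataset
from .io import read_dataset
from .similarity import Aligner, KabschAligner, TMAlignAligner, similarity_matrix


class BenchmarkDataMissingError(FileNotFoundError):
    """The external benchmark data tree is not available locally."""


@dataclass
class CurationSummary:
    n_input_train: int
    n_after_preprocess: int
    n_excluded_overlap: int
    n_excluded_redundancy: int
    n_retained: int
    n_independent_test: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def run_curation(
    data_dir: str | Path,
    test_list_files: Sequence[str | Path],
    aligner: Aligner | None = None,
) -> CurationSummary:
    """Curate a local dataset tree against one or more benchmark id lists.

    ``data_dir`` must contain ``index.txt`` and per-complex directories;
    each entry of ``test_list_files`` is a text file with one test id per
    line. Raises :class:`BenchmarkDataMissingError` when the tree is absent
    (nothing is downloaded on the caller's behalf).
    """
    data_dir = Path(data_dir)
    if not (data_dir / "index.txt").exists():
        raise BenchmarkDataMissingError(
            f"no dataset at {data_dir} (expected index.txt plus per-complex "
            "directories); download the external data and point data_dir at it"
        )
    test_ids_by_name: dict[str, list[str]] = {}
    for list_file in test_list_files:
        list_file = Path(list_file)
        if not list_file.exists():
            raise BenchmarkDataMissingError(f"missing test id list {list_file}")
        test_ids_by_name[list_file.stem] = [
            line.strip() for line in list_file.read_text().splitlines() if line.strip()
        ]
    if aligner is None:
        aligner = TMAlignAligner() if _tmalign_available() else KabschAligner()

    records = read_dataset(data_dir)
    test_id_union = {tid for ids in test_ids_by_name.values() for tid in ids}
    train_records = [r for r in records if r.id not in test_id_union]
    test_records = {
        name: [r for r in records if r.id in set(ids)]
        for name, ids in test_ids_by_name.items()
    }
    kept, _report = preprocess_dataset(train_records)
    train_test_tables = {
        name: similarity_matrix(kept, recs, aligner)
        for name, recs in test_records.items()
    }
    train_train_table = similarity_matrix(kept, kept, aligner)
    result = assemble_cleansplit(
        [r.id for r in kept],
        {name: [r.id for r in recs] for name, recs in test_records.items()},
        train_test_tables,
        train_train_table,
        subsets={r.id: r.subset for r in kept},
        resolutions={r.id: r.resolution for r in kept},
    )
    return CurationSummary(
        n_input_train=len(train_records),
        n_after_preprocess=len(kept),
        n_excluded_overlap=len(result.excluded_overlap),
        n_excluded_redundancy=len(result.excluded_redundancy),
        n_retained=len(result.retained_train),
        n_independent_test={k: len(v) for k, v in result.independent_test.items()},
    )


def _tmalign_available() -> bool:
    import shutil

    return shutil.which("TMalign") is not None
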