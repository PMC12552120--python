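"""Train-test leakage removal and training-set redundancy removal.

Two filters curate a training dataset against one or more held-out test
sets:

1. **Leakage filter** (train vs test). A training complex is excluded when a
   test complex has (a) an essentially identical ligand (Tanimoto > 0.9) at
   a similar affinity (|dpK| <= 1), or (b) high protein similarity
   (TM > 0.8), a combined ligand/pose similarity Tanimoto + (1 - RMSD) > 0.8
   and a similar affinity (|dpK| <= 1). Pairs with very different affinity
   are never excluded: structurally similar complexes with divergent
   activity are activity cliffs and carry signal.

2. **Redundancy filter** (train vs train). Stricter thresholds (TM > 0.8,
   Tanimoto + (1 - RMSD) > 1.3, |dpK| < 0.5) define an adjacency graph of
   near-duplicates; a greedy loop removes the most-connected complex until
   no edges remain, preferring to drop general-set members over refined-set
   members and, among those, the structure with the worst (numerically
   largest) resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .similarity import PairSimilarity, SimilarityTable

# Leakage (train vs test) thresholds.
LEAK_TM = 0.8               # strict: TM must exceed this
LEAK_COMBINED = 0.8         # strict: Tanimoto + (1 - RMSD) must exceed this
LEAK_TANIMOTO_IDENTITY = 0.9  # strict: near-identical ligand
LEAK_DPK = 1.0              # inclusive band: |dpK| <= 1 counts as similar

# Redundancy (train vs train) thresholds.
REDUND_TM = 0.8             # strict
REDUND_COMBINED = 1.3       # strict
REDUND_DPK = 0.5            # strict: |dpK| < 0.5


@dataclass(frozen=True)
class LeakageDecision:
    excluded: bool
    rule: str                     # "ligand_identity" | "structural_overlap" | "none"
    against_test_id: str | None = None

    def __post_init__(self) -> None:
        if self.excluded != (self.rule != "none"):
            raise ValueError("excluded flag inconsistent with rule")


def leakage_exclude(sim: PairSimilarity, against_test_id: str | None = None) -> LeakageDecision:
    """Decide whether a training complex leaks a test complex's label.

    The affinity band gates everything: |dpK| > 1 never excludes.
    """
    if sim.delta_pk > LEAK_DPK:
        return LeakageDecision(False, "none")
    if sim.tanimoto > LEAK_TANIMOTO_IDENTITY:
        return LeakageDecision(True, "ligand_identity", against_test_id)
    if sim.tm_score > LEAK_TM and sim.tanimoto + (1.0 - sim.ligand_rmsd) > LEAK_COMBINED:
        return LeakageDecision(True, "structural_overlap", against_test_id)
    return LeakageDecision(False, "none")


@dataclass
class OverlapReport:
    """Per-excluded-id list of (test id, rule) pairs that triggered exclusion."""

    triggers: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.triggers)

    @property
    def n_pair_hits(self) -> int:
        """Number of leaking train-test pairs (a train id may appear several times)."""
        return sum(len(v) for v in self.triggers.values())


def filter_train_test(
    train_ids: Sequence[str],
    test_id_sets: Sequence[Sequence[str]],
    tables: Sequence[SimilarityTable],
) -> OverlapReport:
    """Exclude every training complex that leaks any test complex.

    ``tables[k]`` must cover all train x test pairs for ``test_id_sets[k]``;
    a missing pair raises (silently keeping it would hide leakage). Multiple
    test sets are filtered as a union.
    """
    if len(test_id_sets) != len(tables):
        raise ValueError("one similarity table per test set required")
    report = OverlapReport()
    for test_ids, table in zip(test_id_sets, tables):
        for train_id in train_ids:
            for test_id in test_ids:
                decision = leakage_exclude(table.get(train_id, test_id), test_id)
                if decision.excluded:
                    report.triggers.setdefault(train_id, []).append(
                        (test_id, decision.rule)
                    )
    return report


def independent_subset(
    test_ids: Sequence[str], train_ids: Sequence[str], table: SimilarityTable
) -> set[str]:
    """Test complexes with no leakage partner in the (unfiltered) training set."""
    independent = set()
    for test_id in test_ids:
        if not any(
            leakage_exclude(table.get(train_id, test_id)).excluded
            for train_id in train_ids
        ):
            independent.add(test_id)
    return independent


def redundancy_edge(sim: PairSimilarity) -> bool:
    return (
        sim.tm_score > REDUND_TM
        and sim.tanimoto + (1.0 - sim.ligand_rmsd) > REDUND_COMBINED
        and sim.delta_pk < REDUND_DPK
    )


def redundancy_adjacency(
    train_ids: Sequence[str],
    table: SimilarityTable,
    subsets: Mapping[str, str] | None = None,
    resolutions: Mapping[str, float | None] | None = None,
) -> nx.Graph:
    """Adjacency graph of near-duplicate training complexes.

    Nodes carry ``subset`` and ``resolution`` metadata for the greedy
    tie-breaks; all unordered train pairs must be present in the table.
    """
    graph = nx.Graph()
    for cid in train_ids:
        graph.add_node(
            cid,
            subset=(subsets or {}).get(cid, "general"),
            resolution=(resolutions or {}).get(cid),
        )
    ids = list(train_ids)
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1:]:
            if redundancy_edge(table.get(id_a, id_b)):
                graph.add_edge(id_a, id_b)
    return graph


@dataclass(frozen=True)
class RemovalStep:
    removed_id: str
    degree: int
    tie_break: str  # "degree" | "subset" | "resolution" | "id"


@dataclass
class RemovalTrace:
    steps: list[RemovalStep] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        return [s.removed_id for s in self.steps]


def _removal_key(graph: nx.Graph, node: str) -> tuple:
    # larger degree first; general before refined; worst (largest) resolution
    # first with missing metadata sorting as worst; then smallest id.
    data = graph.nodes[node]
    resolution = data.get("resolution")
    return (
        -graph.degree(node),
        0 if data.get("subset", "general") == "general" else 1,
        -(resolution if resolution is not None else float("inf")),
        node,
    )


def greedy_redundancy_removal(graph: nx.Graph) -> RemovalTrace:
    """Iteratively remove the most-connected complex until no edges remain.

    Ties on degree prefer general-set over refined-set complexes, then the
    worst diffraction resolution (largest angstrom value, missing counted as
    worst), then the lexicographically smallest id so the trace is fully
    deterministic regardless of node insertion order.
    """
    work = graph.copy()
    trace = RemovalTrace()
    while work.number_of_edges() > 0:
        candidates = sorted(
            (n for n in work.nodes if work.degree(n) > 0),
            key=lambda n: _removal_key(work, n),
        )
        victim = candidates[0]
        degree = work.degree(victim)
        tie_break = "degree"
        if len(candidates) > 1 and work.degree(candidates[1]) == degree:
            runner = candidates[1]
            v_data, r_data = work.nodes[victim], work.nodes[runner]
            if v_data.get("subset") != r_data.get("subset"):
                tie_break = "subset"
            elif v_data.get("resolution") != r_data.get("resolution"):
                tie_break = "resolution"
            else:
                tie_break = "id"
        trace.steps.append(RemovalStep(victim, degree, tie_break))
        work.remove_node(victim)
    return trace


@dataclass
class SplitResult:
    """Outcome of the full curation: retained ids plus both exclusion sets."""

    retained_train: set[str]
    excluded_overlap: set[str]
    excluded_redundancy: set[str]
    independent_test: dict[str, set[str]]   # test-set name -> independent ids
    overlap_report: OverlapReport
    removal_trace: RemovalTrace

    def __post_init__(self) -> None:
        if self.retained_train & self.excluded_overlap:
            raise ValueError("retained and overlap-excluded sets intersect")
        if self.retained_train & self.excluded_redundancy:
            raise ValueError("retained and redundancy-excluded sets intersect")
        if self.excluded_overlap & self.excluded_redundancy:
            raise ValueError("the two exclusion sets intersect")

    def audit_rows(self) -> list[dict[str, str]]:
        rows = []
        for cid, hits in sorted(self.overlap_report.triggers.items()):
            for test_id, rule in hits:
                rows.append(
                    {"id": cid, "stage": "overlap", "rule": rule, "partner": test_id}
                )
        for step in self.removal_trace.steps:
            rows.append(
                {
                    "id": step.removed_id,
                    "stage": "redundancy",
                    "rule": f"degree={step.degree}",
                    "partner": step.tie_break,
                }
            )
        return rows


def assemble_cleansplit(
    train_ids: Sequence[str],
    test_id_sets: Mapping[str, Sequence[str]],
    train_test_tables: Mapping[str, SimilarityTable],
    train_train_table: SimilarityTable,
    subsets: Mapping[str, str] | None = None,
    resolutions: Mapping[str, float | None] | None = None,
) -> SplitResult:
    """Run the overlap filter, then redundancy removal, and assemble the split.

    The overlap filter runs against the union of all test sets first; the
    redundancy graph is then built on the surviving training complexes only.
    """
    names = list(test_id_sets)
    overlap = filter_train_test(
        train_ids,
        [test_id_sets[n] for n in names],
        [train_test_tables[n] for n in names],
    )
    surviving = [tid for tid in train_ids if tid not in overlap.excluded_ids]
    graph = redundancy_adjacency(surviving, train_train_table, subsets, resolutions)
    trace = greedy_redundancy_removal(graph)
    redundant = set(trace.removed_ids)
    independent = {
        name: independent_subset(test_id_sets[name], train_ids, train_test_tables[name])
        for name in names
    }
    return SplitResult(
        retained_train={tid for tid in surviving if tid not in redundant},
        excluded_overlap=overlap.excluded_ids,
        excluded_redundancy=redundant,
        independent_test=independent,
        overlap_report=overlap,
        removal_trace=trace,
    )
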