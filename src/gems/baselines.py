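"""Nearest-neighbour label-averaging baselines and evaluation metrics.

These baselines predict a test complex's affinity by looking up the most
similar training complexes and averaging their labels. Their performance on
a benchmark is a direct readout of train-test leakage: a memorization-only
predictor can only be accurate if near-duplicates of the test complexes
exist in the training set.

* complex search ranks by structural similarity TM + Tanimoto + (1 - RMSD)
  (the label term of the S score is unavailable at prediction time);
* ligand search ranks by Tanimoto only;
* the mean-label baseline predicts the training-set mean everywhere.

Evaluation covers scoring power (Pearson r, RMSE on the pK scale) and
ranking power (Spearman rank correlation within fixed-protein clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .similarity import SimilarityTable


@dataclass
class PredictionSet:
    """Per-test-id prediction plus the neighbour list that produced it."""

    predictions: dict[str, float]
    neighbours: dict[str, list[tuple[str, float]]]  # id -> [(train id, score) desc]


def _structural_score(table: SimilarityTable, test_id: str, train_id: str) -> float:
    sim = table.get(train_id, test_id)
    return sim.tm_score + sim.tanimoto + (1.0 - sim.ligand_rmsd)


def _ligand_score(table: SimilarityTable, test_id: str, train_id: str) -> float:
    return table.get(train_id, test_id).tanimoto


def _knn_predict(
    test_ids: Sequence[str],
    train_labels: Mapping[str, float],
    score,
    k: int,
) -> PredictionSet:
    if not train_labels:
        raise ValueError("training set is empty")
    train_ids = sorted(train_labels)  # lexicographic tie-break baked into sort
    predictions: dict[str, float] = {}
    neighbours: dict[str, list[tuple[str, float]]] = {}
    for test_id in test_ids:
        ranked = sorted(
            ((tid, score(test_id, tid)) for tid in train_ids),
            key=lambda pair: (-pair[1], pair[0]),
        )
        top = ranked[: min(k, len(ranked))]
        predictions[test_id] = float(np.mean([train_labels[tid] for tid, _ in top]))
        neighbours[test_id] = top
    return PredictionSet(predictions=predictions, neighbours=neighbours)


def predict_by_complex_search(
    test_ids: Sequence[str],
    train_labels: Mapping[str, float],
    table: SimilarityTable,
    k: int = 5,
) -> PredictionSet:
    """Average the labels of the k most structurally similar training complexes."""
    return _knn_predict(
        test_ids,
        train_labels,
        lambda te, tr: _structural_score(table, te, tr),
        k,
    )


def predict_by_ligand_search(
    test_ids: Sequence[str],
    train_labels: Mapping[str, float],
    table: SimilarityTable,
    k: int = 5,
) -> PredictionSet:
    """Average the labels of the k training complexes with the most similar ligands."""
    return _knn_predict(
        test_ids,
        train_labels,
        lambda te, tr: _ligand_score(table, te, tr),
        k,
    )


def mean_label_baseline(train_labels: Mapping[str, float]):
    """Constant predictor returning the mean training label for any id."""
    if not train_labels:
        raise ValueError("training set is empty")
    mean = float(np.mean(list(train_labels.values())))

    def predict(test_ids: Sequence[str]) -> PredictionSet:
        return PredictionSet(
            predictions={tid: mean for tid in test_ids},
            neighbours={tid: [] for tid in test_ids},
        )

    return predict


@dataclass
class ScoringResult:
    pearson_r: float | None   # None when predictions have zero variance
    rmse: float


def evaluate_scoring(
    predictions: Mapping[str, float], truth: Mapping[str, float]
) -> ScoringResult:
    """Scoring power: Pearson correlation and RMSE over shared ids (pK units)."""
    ids = sorted(set(predictions) & set(truth))
    if len(ids) < 2:
        raise ValueError("need at least 2 paired values")
    pred = np.asarray([predictions[i] for i in ids], dtype=float)
    true = np.asarray([truth[i] for i in ids], dtype=float)
    rmse = float(np.sqrt(np.mean((pred - true) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(true) == 0:  # constant input: r undefined
        return ScoringResult(pearson_r=None, rmse=rmse)
    r, _ = stats.pearsonr(pred, true)
    return ScoringResult(pearson_r=float(r), rmse=rmse)


def evaluate_ranking(
    predictions: Mapping[str, float],
    truth: Mapping[str, float],
    clusters: Mapping[str, Sequence[str]],
) -> dict[str, float]:
    """Ranking power: Spearman correlation within each fixed-protein cluster.

    Ties receive average ranks (scipy default). Clusters with fewer than two
    evaluable members are skipped with a warning.
    """
    out: dict[str, float] = {}
    for name, member_ids in clusters.items():
        ids = [i for i in member_ids if i in predictions and i in truth]
        if len(ids) < 2:
            warnings.warn(f"cluster {name!r} has fewer than 2 members; skipped")
            continue
        pred = [predictions[i] for i in ids]
        true = [truth[i] for i in ids]
        rho, _ = stats.spearmanr(pred, true)
        out[name] = float(rho)
    return out
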