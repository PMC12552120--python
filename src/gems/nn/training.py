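"""Training protocol: SGD on the RMSE loss, early stopping, k-fold CV.

Each fold trains until the validation RMSE has not improved for a patience
window (100 epochs by default), keeping the parameters of the best
validation checkpoint. All folds of one run share a single split
realization fixed by the seed; the final predictor averages the fold models
(an ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from ..graphs import InteractionGraph
from .autodiff import Tensor
from .layers import GEMSModel, GraphBatch, ModelConfig


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during optimization."""


@dataclass(frozen=True)
class TrainConfig:
    folds: int = 5
    learning_rate: float = 0.02
    momentum: float = 0.9
    max_epochs: int = 1000
    patience: int = 100
    dropout_in_training: bool = True
    init_output_bias_to_mean: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.folds < 2:
            raise ValueError("need at least 2 folds")


def rmse_loss(pred: Tensor, y: np.ndarray) -> Tensor:
    return ((pred - Tensor(y)) ** 2).mean().sqrt()


def rmse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(pred) - np.asarray(y)) ** 2)))


@dataclass
class FoldResult:
    model: GEMSModel
    best_val_rmse: float
    best_epoch: int
    epochs_run: int
    history: list[tuple[float, float]] = field(default_factory=list)  # (train, val)


def train_model(
    model: GEMSModel,
    train_graphs: list[InteractionGraph],
    val_graphs: list[InteractionGraph],
    config: TrainConfig,
) -> FoldResult:
    """Full-batch SGD with momentum, early stopping on validation RMSE."""
    train_batch = GraphBatch.from_graphs(train_graphs)
    val_batch = GraphBatch.from_graphs(val_graphs)
    if config.init_output_bias_to_mean:
        # start the regression head at the training-label mean so the early
        # epochs fit structure, not the DC offset
        model.head2.bias.data[:] = float(np.mean(train_batch.y))
    params = model.parameters()
    velocity = [np.zeros_like(p.data) for p in params]
    rng = np.random.default_rng(config.seed)
    best_state = model.state_dict()
    best_val = float("inf")
    best_epoch = 0
    history: list[tuple[float, float]] = []
    for epoch in range(config.max_epochs):
        for p in params:
            p.grad = None
        drop_rng = rng if config.dropout_in_training else None
        loss = rmse_loss(model.forward(train_batch, rng=drop_rng), train_batch.y)
        if not np.isfinite(loss.data):
            raise TrainingDivergedError(
                f"non-finite training loss at epoch {epoch}"
            )
        loss.backward()
        for p, v in zip(params, velocity):
            if p.grad is None:
                continue
            v *= config.momentum
            v -= config.learning_rate * p.grad
            p.data = p.data + v
        val_rmse = rmse(model.forward(val_batch).data, val_batch.y)
        history.append((float(loss.data), val_rmse))
        if val_rmse < best_val:
            best_val = val_rmse
            best_epoch = epoch
            best_state = model.state_dict()
        elif epoch - best_epoch >= config.patience:
            break
    model.load_state_dict(best_state)
    return FoldResult(
        model=model,
        best_val_rmse=best_val,
        best_epoch=best_epoch,
        epochs_run=len(history),
        history=history,
    )


def train_cv(
    graphs: list[InteractionGraph],
    model_config: ModelConfig,
    train_config: TrainConfig = TrainConfig(),
) -> list[FoldResult]:
    """k-fold cross-validated training; one trained model per fold.

    The fold memberships are a single split realization determined by the
    seed, shared by every model variant trained with the same config.
    """
    if len(graphs) < 2 * train_config.folds:
        raise ValueError("dataset too small for the requested fold count")
    splitter = KFold(
        n_splits=train_config.folds, shuffle=True, random_state=train_config.seed
    )
    results = []
    for fold, (train_idx, val_idx) in enumerate(splitter.split(graphs)):
        model = GEMSModel(model_config, seed=train_config.seed + fold)
        results.append(
            train_model(
                model,
                [graphs[i] for i in train_idx],
                [graphs[i] for i in val_idx],
                train_config,
            )
        )
    return results
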