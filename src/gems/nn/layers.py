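"""Graph network layers and the full affinity-scoring architecture.

The scoring model alternates attention-based node convolutions with edge
convolutions (five convolutions in total by default: three node, two edge)
while a global context vector is refreshed with mean-pooled node features
after every node convolution; a dropout + two-layer fully connected head
maps the final global vector to a pK prediction.

The node convolution implements the attention update

    x'_i = a_ii * Th_s x_i + sum_{j in N(i)} a_ij * Th_t x_j

with attention coefficients

    a_ij = softmax_{k in N(i) u {i}} ( a^T LeakyReLU(Th_s x_i + Th_t x_k) )

where ``Th_s`` acts on the receiving (source) node and ``Th_t`` on its
neighbours. Self-loops are explicit edges of the graph; multi-head outputs
are concatenated. When an edge dimension is configured, a third learnable
matrix lifts edge features into both the attention argument and the
message, which is how geometric (distance) information reaches the nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..graphs import InteractionGraph
from .autodiff import Tensor, concat, glorot, parameter


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.weight = glorot((n_in, n_out), rng)
        # small random bias keeps pre-activations off the exact ReLU kink
        bound = 1.0 / np.sqrt(n_in)
        self.bias = parameter(rng.uniform(-bound, bound, size=n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class AttentionHead:
    """One attention head of the node convolution (see module docstring)."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 edge_dim: int | None = None, negative_slope: float = 0.2) -> None:
        self.theta_s = glorot((n_in, n_out), rng)
        self.theta_t = glorot((n_in, n_out), rng)
        self.att = glorot((n_out, 1), rng)
        self.theta_e = glorot((edge_dim, n_out), rng) if edge_dim else None
        self.negative_slope = negative_slope

    def parameters(self) -> list[Tensor]:
        params = [self.theta_s, self.theta_t, self.att]
        if self.theta_e is not None:
            params.append(self.theta_e)
        return params

    def attention(self, x: Tensor, edge_index: np.ndarray,
                  edge_attr: Tensor | None) -> Tensor:
        """Per-edge attention coefficients, softmax-normalized per receiver."""
        src, dst = edge_index
        n_nodes = x.shape[0]
        xs = x.matmul(self.theta_s)   # receiver transform
        xt = x.matmul(self.theta_t)   # neighbour transform
        arg = xs.gather(dst) + xt.gather(src)
        if self.theta_e is not None and edge_attr is not None:
            arg = arg + edge_attr.matmul(self.theta_e)
        score = arg.leaky_relu(self.negative_slope).matmul(self.att)  # (E, 1)
        # numerically stable softmax per destination; the shift is constant
        shift = np.full(n_nodes, -np.inf)
        np.maximum.at(shift, dst, score.data[:, 0])
        exp = (score - Tensor(shift[dst][:, None])).exp()
        denom = exp.segment_sum(dst, n_nodes)
        return exp / denom.gather(dst)

    def __call__(self, x: Tensor, edge_index: np.ndarray,
                 edge_attr: Tensor | None) -> Tensor:
        src, dst = edge_index
        n_nodes = x.shape[0]
        alpha = self.attention(x, edge_index, edge_attr)
        xs = x.matmul(self.theta_s)
        xt = x.matmul(self.theta_t)
        # self-loop messages use the receiver transform, neighbour messages
        # the neighbour transform
        self_mask = (src == dst).astype(float)[:, None]
        message = xt.gather(src) * Tensor(1.0 - self_mask) + xs.gather(src) * Tensor(self_mask)
        if self.theta_e is not None and edge_attr is not None:
            message = message + edge_attr.matmul(self.theta_e)
        return (alpha * message).segment_sum(dst, n_nodes)


class NodeConv:
    """Multi-head attention node convolution with concatenated heads."""

    def __init__(self, n_in: int, n_out: int, heads: int, rng: np.random.Generator,
                 edge_dim: int | None = None) -> None:
        if n_out % heads:
            raise ValueError("output width must be divisible by the head count")
        self.heads = [
            AttentionHead(n_in, n_out // heads, rng, edge_dim) for _ in range(heads)
        ]

    def parameters(self) -> list[Tensor]:
        return [p for h in self.heads for p in h.parameters()]

    def __call__(self, x: Tensor, edge_index: np.ndarray,
                 edge_attr: Tensor | None = None) -> Tensor:
        outs = [head(x, edge_index, edge_attr) for head in self.heads]
        return outs[0] if len(outs) == 1 else concat(outs, axis=1)


class EdgeConv:
    """Two-layer perceptron updating each edge from (source, target, edge)."""

    def __init__(self, node_dim: int, edge_dim: int, n_out: int,
                 rng: np.random.Generator, hidden: int | None = None) -> None:
        hidden = hidden or n_out
        self.fc1 = Linear(2 * node_dim + edge_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_out, rng)

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.fc2.parameters()

    def __call__(self, x: Tensor, edge_index: np.ndarray, edge_attr: Tensor) -> Tensor:
        src, dst = edge_index
        stacked = concat([x.gather(src), x.gather(dst), edge_attr], axis=1)
        return self.fc2(self.fc1(stacked).relu())


class GlobalUpdate:
    """Refresh the global vector from (previous global, mean-pooled nodes)."""

    def __init__(self, global_dim: int, node_dim: int, rng: np.random.Generator) -> None:
        self.fc = Linear(global_dim + node_dim, global_dim, rng)

    def parameters(self) -> list[Tensor]:
        return self.fc.parameters()

    def __call__(self, g: Tensor, x: Tensor, node_graph: np.ndarray,
                 n_graphs: int) -> Tensor:
        counts = np.bincount(node_graph, minlength=n_graphs).astype(float)
        pooled = x.segment_sum(node_graph, n_graphs) * Tensor(1.0 / counts[:, None])
        return self.fc(concat([g, pooled], axis=1)).relu()


@dataclass
class GraphBatch:
    """Several interaction graphs packed into one disjoint union."""

    x: np.ndarray            # (N, F) node features
    edge_index: np.ndarray   # (2, E) with batch-level node ids
    edge_attr: np.ndarray    # (E, Fe)
    globals: np.ndarray      # (B, G)
    node_graph: np.ndarray   # (N,) graph id per node
    y: np.ndarray            # (B,) labels (nan when absent)
    ids: list[str] = field(default_factory=list)

    @property
    def n_graphs(self) -> int:
        return self.globals.shape[0]

    @classmethod
    def from_graphs(cls, graphs: list[InteractionGraph]) -> "GraphBatch":
        xs, eis, eas, gls, ngs, ys, ids = [], [], [], [], [], [], []
        offset = 0
        for gid, graph in enumerate(graphs):
            xs.append(graph.node_features)
            eis.append(graph.edge_index + offset)
            eas.append(graph.edge_features)
            gls.append(graph.global_features)
            ngs.append(np.full(graph.n_nodes, gid, dtype=np.int64))
            ys.append(np.nan if graph.label is None else graph.label)
            ids.append(graph.id)
            offset += graph.n_nodes
        return cls(
            x=np.concatenate(xs),
            edge_index=np.concatenate(eis, axis=1),
            edge_attr=np.concatenate(eas),
            globals=np.stack(gls),
            node_graph=np.concatenate(ngs),
            y=np.asarray(ys, dtype=float),
            ids=ids,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (desk-scale defaults)."""

    node_in: int
    edge_in: int
    global_in: int
    hidden: int = 32
    heads: int = 2
    n_node_convs: int = 3
    n_edge_convs: int = 2
    dropout: float = 0.1
    head_hidden: int = 32

    def __post_init__(self) -> None:
        if self.n_node_convs != self.n_edge_convs + 1:
            raise ValueError("convolutions must alternate: node convs = edge convs + 1")
        if self.hidden <= 0 or self.head_hidden <= 0:
            raise ValueError("widths must be positive")


class GEMSModel:
    """Attention GNN regressor from interaction graphs to pK values."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.dim_red = Linear(c.node_in, c.hidden, rng)
        self.global_embed = Linear(c.global_in, c.hidden, rng)
        self.node_convs = []
        self.edge_convs = []
        self.global_updates = []
        edge_dim = c.edge_in
        for layer in range(c.n_node_convs):
            self.node_convs.append(
                NodeConv(c.hidden, c.hidden, c.heads, rng, edge_dim=edge_dim)
            )
            self.global_updates.append(GlobalUpdate(c.hidden, c.hidden, rng))
            if layer < c.n_edge_convs:
                self.edge_convs.append(EdgeConv(c.hidden, edge_dim, c.hidden, rng))
                edge_dim = c.hidden
        self.head1 = Linear(c.hidden, c.head_hidden, rng)
        self.head2 = Linear(c.head_hidden, 1, rng)

    def parameters(self) -> list[Tensor]:
        params = self.dim_red.parameters() + self.global_embed.parameters()
        for conv in self.node_convs:
            params += conv.parameters()
        for conv in self.edge_convs:
            params += conv.parameters()
        for upd in self.global_updates:
            params += upd.parameters()
        return params + self.head1.parameters() + self.head2.parameters()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state does not match model parameterization")
        for p, data in zip(params, state):
            if p.data.shape != data.shape:
                raise ValueError("parameter shape mismatch")
            p.data = data.copy()

    def forward(self, batch: GraphBatch,
                rng: np.random.Generator | None = None) -> Tensor:
        """Predicted pK per graph; pass ``rng`` to enable training dropout."""
        if batch.x.shape[1] != self.config.node_in:
            raise ValueError(
                f"node feature width {batch.x.shape[1]} does not match "
                f"model schema width {self.config.node_in}"
            )
        x = self.dim_red(Tensor(batch.x))
        e = Tensor(batch.edge_attr)
        g = self.global_embed(Tensor(batch.globals)).relu()
        edge_index = batch.edge_index
        for layer, conv in enumerate(self.node_convs):
            x = conv(x, edge_index, e).relu()
            g = self.global_updates[layer](g, x, batch.node_graph, batch.n_graphs)
            if layer < len(self.edge_convs):
                e = self.edge_convs[layer](x, edge_index, e).relu()
        h = g.dropout(self.config.dropout, rng)
        return self.head2(self.head1(h).relu()).reshape(-1)

    def predict(self, graphs: list[InteractionGraph]) -> np.ndarray:
        """Deterministic (dropout-free) predictions for a list of graphs."""
        if not graphs:
            return np.zeros(0)
        return self.forward(GraphBatch.from_graphs(graphs)).data.copy()


def ensemble_predict(models: list[GEMSModel],
                     graphs: list[InteractionGraph]) -> np.ndarray:
    """Arithmetic mean of the per-model predictions (the ensemble output)."""
    if not models:
        raise ValueError("need at least one model")
    if not graphs:
        return np.zeros(0)
    return np.mean([m.predict(graphs) for m in models], axis=0)
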