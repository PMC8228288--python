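"""End-to-end gated signed graph-attention model (SN-GGAT).

Pipeline: from the training adjacency A_train (held-out test pairs set to
0, "unknown"), run the gating recursion to order m; use the second-order
accessibility matrix of A_train as the node feature table; pass it through
two gated attention layers (6-head elu layer to 128 dims, single-head tanh
layer to 32 dims by default); decode pair scores with the inner product
S = Z Z^T; and train with mean binary cross-entropy-with-logits over the
observed training edges (+1 -> label 1, -1 -> label 0), full-batch Adam.

Everything derived from the graph — gating matrices, features, attention
masks, loss — sees only training edges, which is the leakage-free reading
of the transductive protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, bce_with_logits
from .gating import AccessibilityState, accessibility_matrix, run_gating
from .graph import SignedGraph, build_adjacency, sgn
from .layers import GatedAttentionLayer

__all__ = [
    "TrainConfig",
    "EdgeSplit",
    "Predictions",
    "GgatModel",
    "build_features",
    "forward",
    "edge_loss",
    "train",
    "predict_signs",
]


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults follow the reference setting: order-2 gating with memory
    weight 0.8 and reset weight 0.2; layer dims 128 and 32 with 6 and 1
    heads; elu then tanh activations; Adam at learning rate 0.002.
    """

    order: int = 2
    alpha_mem: float = 0.8
    beta_reset: float = 0.2
    dims: tuple[int, ...] = (128, 32)
    heads: tuple[int, ...] = (6, 1)
    activations: tuple[str, ...] = ("elu", "tanh")
    head_merge: str = "average"
    leaky_slope: float = 0.2
    learning_rate: float = 0.002
    epochs: int = 300
    seed: int = 0
    threshold: float = 0.0

    def __post_init__(self):
        if not (len(self.dims) == len(self.heads) == len(self.activations)):
            raise ValueError("dims, heads and activations must have equal length")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key in ("dims", "heads", "activations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class EdgeSplit:
    """Train/test partition of the signed edges of one graph.

    ``A_train`` is built from training edges only; held-out pairs are 0
    ("unknown") and never touch gating, features, masks, or the loss.
    """

    graph: SignedGraph
    train_edges: tuple[tuple[int, int, int], ...]
    test_edges: tuple[tuple[int, int, int], ...]

    def __post_init__(self):
        tr, te = set(self.train_edges), set(self.test_edges)
        if tr & te:
            raise ValueError("train and test edges overlap")
        if tr | te != set(self.graph.edges):
            raise ValueError("split does not cover the full edge set")

    @property
    def train_graph(self) -> SignedGraph:
        return self.graph.with_edges(self.train_edges)

    @property
    def A_train(self) -> np.ndarray:
        return build_adjacency(self.train_graph)


def full_split(graph: SignedGraph) -> EdgeSplit:
    """Degenerate split with every edge in the training set."""
    return EdgeSplit(graph, tuple(sorted(graph.edges)), ())


@dataclass
class Predictions:
    """Embeddings and the decoded, reconstructed signed network.

    ``S = Z Z^T`` holds pair logits; ``A_r = sgn(S)`` is the reconstructed
    sign matrix (0 kept where the score is exactly 0).
    """

    Z: np.ndarray
    node_ids: tuple[str, ...]

    @property
    def S(self) -> np.ndarray:
        return self.Z @ self.Z.T

    @property
    def A_r(self) -> np.ndarray:
        return sgn(self.S)


class GgatModel:
    """Stack of gated attention layers producing node embeddings."""

    def __init__(self, n_features: int, config: TrainConfig):
        self.config = config
        self.layers: list[GatedAttentionLayer] = []
        in_dim = n_features
        for dim, n_heads, act in zip(config.dims, config.heads, config.activations):
            self.layers.append(GatedAttentionLayer(
                in_dim=in_dim, out_dim=dim, n_heads=n_heads, activation=act,
                head_merge=config.head_merge, leaky_slope=config.leaky_slope))
            in_dim = dim if (config.head_merge == "average" or n_heads == 1) \
                else dim * n_heads
        self.out_dim = in_dim

    def init_params(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init_params(rng)

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.layers for p in layer.parameters()]

    def embed(self, X: np.ndarray, state: AccessibilityState) -> Tensor:
        """Differentiable forward pass to the embedding matrix Z."""
        mask = state.memory != 0
        H = Tensor(np.asarray(X, dtype=np.float64))
        for idx, layer in enumerate(self.layers):
            H = layer.forward(H, mask, state.attention)
            if not np.all(np.isfinite(H.data)):
                raise FloatingPointError(f"non-finite values after layer {idx}")
        return H


def build_features(A_train: np.ndarray, k: int = 2) -> np.ndarray:
    """Node features: each row of the order-k accessibility matrix of A_train."""
    return accessibility_matrix(A_train, k).astype(np.float64)


def forward(model: GgatModel, X: np.ndarray, state: AccessibilityState,
            node_ids: Sequence[str]) -> Predictions:
    """Non-differentiable forward pass returning decoded predictions."""
    Z = model.embed(X, state)
    return Predictions(Z.data.copy(), tuple(node_ids))


def edge_loss(S: np.ndarray, edges: Sequence[tuple[int, int, int]]) -> float:
    """Mean BCE-with-logits of pair scores over the given edges.

    Labels: +1 -> 1, -1 -> 0; logit = S(i, j); each undirected edge
    counted once.
    """
    edges = list(edges)
    if not edges:
        raise ValueError("edge set is empty")
    arr = np.array(edges, dtype=np.int64)
    logits = np.asarray(S)[arr[:, 0], arr[:, 1]]
    labels = (arr[:, 2] > 0).astype(np.float64)
    return float(np.mean(np.logaddexp(0.0, logits) - labels * logits))


@dataclass
class TrainResult:
    model: GgatModel
    predictions: Predictions
    state: AccessibilityState
    history: list[dict] = field(default_factory=list)


def train(graph: SignedGraph, split: EdgeSplit | None = None,
          config: TrainConfig | None = None) -> TrainResult:
    """Train on the split's training edges; return model and predictions.

    Fully deterministic given the config seed.  Raises if the loss goes
    non-finite (advice: reduce the learning rate).
    """
    config = config or TrainConfig()
    split = split or full_split(graph)
    if not split.train_edges:
        raise ValueError("training edge set is empty")

    A_train = split.A_train
    state = run_gating(A_train, config.order, config.alpha_mem, config.beta_reset)
    X = build_features(A_train)

    rng = np.random.default_rng(config.seed)
    model = GgatModel(X.shape[1], config)
    model.init_params(rng)
    opt = Adam(model.parameters(), lr=config.learning_rate)

    arr = np.array(split.train_edges, dtype=np.int64)
    rows, cols = arr[:, 0], arr[:, 1]
    labels = (arr[:, 2] > 0).astype(np.float64)
    signs = arr[:, 2]

    history: list[dict] = []
    for epoch in range(config.epochs):
        Z = model.embed(X, state)
        S = Z @ Z.T
        logits = S.gather_pairs(rows, cols)
        loss = bce_with_logits(logits, labels)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                "training loss is non-finite; consider reducing the learning rate")
        opt.zero_grad()
        loss.backward()
        opt.step()
        pred = np.where(logits.data > config.threshold, 1, -1)
        history.append({
            "epoch": epoch + 1,
            "loss": float(loss.data),
            "train_accuracy": float(np.mean(pred == signs)),
        })

    preds = forward(model, X, state, graph.node_ids)
    return TrainResult(model, preds, state, history)


def predict_signs(predictions: Predictions,
                  pairs: Sequence[tuple[int, int]],
                  threshold: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Predicted signs and raw scores for node-index pairs.

    Sign is +1 when the inner-product score exceeds ``threshold``, else -1
    (a score exactly at the threshold maps to -1 so every pair receives a
    binary prediction; the raw 0 is preserved in ``A_r``).
    """
    n = predictions.Z.shape[0]
    S = predictions.S
    out_signs, out_scores = [], []
    for i, j in pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise IndexError(f"pair ({i},{j}) references unknown node (n={n})")
        score = S[i, j]
        out_scores.append(score)
        out_signs.append(1 if score > threshold else -1)
    return np.array(out_signs, dtype=np.int64), np.array(out_scores, dtype=np.float64)
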