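"""Gated signed graph-attention layer.

The layer follows the usual graph-attention recipe — a shared linear map
W, a learned attention vector a, LeakyReLU scoring and a softmax over the
neighborhood — with two signed-network changes:

* the neighborhood N(i) comes from the memory accessibility matrix (all
  nodes with a nonzero entry in row i, including i itself under the +1
  diagonal convention), so m-order neighbors participate; and
* the softmax coefficients are re-weighted by the attention accessibility
  matrix and re-normalized to unit absolute sum, so each weight carries
  the sign of the relation and its magnitude decays with neighbor order:
  "low-order high attention, high-order low attention, different signs
  opposite".

With an all-positive attention matrix the layer reduces exactly to
standard unsigned graph attention.

Two implementations live here.  The ``*_node`` functions are a plain-numpy
per-node reference used by tests and for explanation; ``GatedAttentionLayer``
is the vectorized, differentiable version used for training.  They compute
the same map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, masked_softmax

__all__ = [
    "AttentionLayerParams",
    "neighborhood",
    "raw_coefficients",
    "signed_attention",
    "update_node",
    "GatedAttentionLayer",
]

LEAKY_SLOPE_DEFAULT = 0.2
_ACTIVATIONS = {
    "elu": lambda x: np.where(x > 0, x, np.expm1(x)),
    "tanh": np.tanh,
}


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class AttentionLayerParams:
    """Parameters of one attention head group.

    ``W`` maps input features to the head dimension; ``a`` (length twice
    the head dimension) scores a node pair on the concatenation
    [W h_i || W h_j].  One (W, a) pair per head.
    """

    W: list[np.ndarray]
    a: list[np.ndarray]
    n_heads: int
    head_merge: str = "average"
    activation: str = "elu"
    leaky_slope: float = LEAKY_SLOPE_DEFAULT

    def __post_init__(self):
        if self.head_merge not in ("average", "concat"):
            raise ValueError(f"head_merge must be 'average' or 'concat', got {self.head_merge!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")
        if not (len(self.W) == len(self.a) == self.n_heads):
            raise ValueError("need one (W, a) pair per head")
        for W, a in zip(self.W, self.a):
            if a.shape[0] != 2 * W.shape[1]:
                raise ValueError("attention vector length must be 2 x head dim")


# ----------------------------------------------------------------------
# Per-node reference implementation (numpy, no autodiff)
# ----------------------------------------------------------------------

def neighborhood(M_mem: np.ndarray, i: int) -> set[int]:
    """N(i): indices with a nonzero entry in row i of the memory matrix."""
    M_mem = np.asarray(M_mem)
    if not 0 <= i < M_mem.shape[0]:
        raise IndexError(f"node index {i} out of range for n={M_mem.shape[0]}")
    return set(np.flatnonzero(M_mem[i]).tolist())


def raw_coefficients(H: np.ndarray, W: np.ndarray, a: np.ndarray,
                     nbrs: list[int], i: int,
                     leaky_slope: float = LEAKY_SLOPE_DEFAULT) -> np.ndarray:
    """Softmax attention coefficients of node ``i`` over ``nbrs``.

    coef[j] = softmax_j( LeakyReLU( a^T [W h_i || W h_j] ) ); strictly
    positive and summing to one.
    """
    if len(nbrs) == 0:
        raise ValueError(f"node {i} has an empty neighborhood; cannot normalize")
    d = W.shape[1]
    hi = H[i] @ W
    scores = np.array([a[:d] @ hi + a[d:] @ (H[j] @ W) for j in nbrs])
    scores = np.where(scores > 0, scores, leaky_slope * scores)
    ex = np.exp(scores - scores.max())
    return ex / ex.sum()


def signed_attention(coef: np.ndarray, att_row: np.ndarray) -> np.ndarray:
    """Re-weight softmax coefficients by the attention accessibility row.

    weight[j] = coef[j] * att_row[j] / sum_k |coef[k] * att_row[k]|; the
    weights have unit absolute sum and inherit the sign of ``att_row``.
    """
    prod = np.asarray(coef) * np.asarray(att_row)
    denom = np.abs(prod).sum()
    if denom == 0:
        raise ValueError("degenerate neighborhood: all attention products are zero")
    return prod / denom


def update_node(H: np.ndarray, W: np.ndarray, weights: np.ndarray,
                nbrs: list[int], activation: str = "tanh") -> np.ndarray:
    """New feature vector: activation( sum_j weight[j] * W h_j )."""
    agg = sum(w * (H[j] @ W) for w, j in zip(weights, nbrs))
    return _ACTIVATIONS[activation](agg)


# ----------------------------------------------------------------------
# Vectorized differentiable layer
# ----------------------------------------------------------------------

@dataclass
class GatedAttentionLayer:
    """One gated signed attention layer over the whole node set.

    ``mask`` (boolean n x n, nonzero pattern of the memory accessibility
    matrix) fixes the neighborhoods; ``att`` is the real-valued attention
    accessibility matrix.  Both are constants of the forward pass; only
    W and a are learned.
    """

    in_dim: int
    out_dim: int
    n_heads: int = 1
    activation: str = "elu"
    head_merge: str = "average"
    leaky_slope: float = LEAKY_SLOPE_DEFAULT
    W: list[Tensor] = field(default_factory=list)
    a_src: list[Tensor] = field(default_factory=list)
    a_dst: list[Tensor] = field(default_factory=list)

    def __post_init__(self):
        if self.head_merge not in ("average", "concat"):
            raise ValueError(f"head_merge must be 'average' or 'concat', got {self.head_merge!r}")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")

    def init_params(self, rng: np.random.Generator) -> None:
        self.W, self.a_src, self.a_dst = [], [], []
        for _ in range(self.n_heads):
            self.W.append(Tensor(
                glorot(rng, self.in_dim, self.out_dim, (self.in_dim, self.out_dim)),
                requires_grad=True))
            # a = [a_src; a_dst]: scoring splits over source and destination
            a_full = glorot(rng, 2 * self.out_dim, 1, (2 * self.out_dim, 1))
            self.a_src.append(Tensor(a_full[: self.out_dim], requires_grad=True))
            self.a_dst.append(Tensor(a_full[self.out_dim:], requires_grad=True))

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.a_src, *self.a_dst]

    def attention_weights(self, H: np.ndarray, mask: np.ndarray,
                          att: np.ndarray) -> list[np.ndarray]:
        """Per-head signed attention weight matrices (for inspection).

        Row i holds the normalized signed weights node i assigns to its
        neighborhood; entries outside the neighborhood are exactly 0.
        """
        out = []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            HW = np.asarray(H) @ W.data
            scores = HW @ a_s.data + (HW @ a_d.data).T
            scores = np.where(scores > 0, scores, self.leaky_slope * scores)
            ex = np.where(mask, np.exp(scores - scores.max(axis=1, keepdims=True)), 0.0)
            coef = ex / ex.sum(axis=1, keepdims=True)
            prod = coef * att
            out.append(prod / np.abs(prod).sum(axis=1, keepdims=True))
        return out

    def forward(self, H: Tensor, mask: np.ndarray, att: np.ndarray) -> Tensor:
        if not self.W:
            raise RuntimeError("layer parameters not initialized")
        att_t = Tensor(att)
        heads = []
        for W, a_s, a_d in zip(self.W, self.a_src, self.a_dst):
            HW = H @ W
            f_src = HW @ a_s                     # (n, 1)
            f_dst = HW @ a_d
            scores = (f_src + f_dst.T).leaky_relu(self.leaky_slope)
            coef = masked_softmax(scores, mask)
            prod = coef * att_t
            denom = prod.abs().sum(axis=1, keepdims=True)
            if np.any(denom.data == 0):
                bad = int(np.flatnonzero(denom.data == 0)[0])
                raise ValueError(
                    f"degenerate neighborhood at node {bad}: all attention products zero")
            weights = prod / denom
            agg = weights @ HW
            heads.append(agg.tanh() if self.activation == "tanh" else agg.elu())
        if self.n_heads == 1:
            return heads[0]
        if self.head_merge == "average":
            out = heads[0]
            for h in heads[1:]:
                out = out + h
            return out * (1.0 / self.n_heads)
        # concat: hstack via successive matmul-free concatenation
        return _concat_cols(heads)


def _concat_cols(tensors: list[Tensor]) -> Tensor:
    """Column-wise concatenation with gradient routing."""
    data = np.concatenate([t.data for t in tensors], axis=1)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        widths = [t.data.shape[1] for t in tensors]
        offsets = np.cumsum([0] + widths)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    t._accum(g[:, lo:hi])

        out._backward = backward
    return out
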