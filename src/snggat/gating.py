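"""Signed accessibility matrices and the update/memory/reset gate recursion.

The order-k accessibility matrix of a signed network records, for each node
pair, the sign of the surplus of positive-product over negative-product
walks of length k: M0 = I, M1 = A, and M_k = sgn(M_{k-1} . A) elementwise
on the matrix product.  Because the adjacency carries +1 self-loops, a
nonzero order-k entry means the pair is reachable within k steps.

Raising the order forgets low-order structure (a +1 first-order edge can
appear as -1 at second order when negative two-step routes dominate).  The
gating recursion fixes this with three gates, iterated from order 1 to m:

* update gate   Mbar_{m+1} = sgn(Mmem_m . A)           -- raw next order
* memory gate   Mmem_{m+1} = sgn((1-a) Mbar_{m+1} + a Mmem_m),  0.5 < a < 1
* reset gate    Matt_{m+1} = (1-b) Matt_m + b Mmem_{m+1},       0 < b <= 1

With a > 0.5 the memory gate is sign-dominant: wherever Mmem_m is nonzero
its sign survives to order m+1, so low-order edge signs are never
overwritten.  The reset gate leaves first-order edges at magnitude 1 while
pairs first reached at higher order enter attenuated by b, giving the
"low-order high attention, high-order low attention" profile the attention
layer consumes.  Mmem defines neighborhoods (who may attend to whom) and
Matt re-weights the attention coefficients by sign and order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import sgn, sign_matrix_ok

__all__ = [
    "AccessibilityState",
    "accessibility_matrix",
    "update_gate",
    "memory_gate",
    "reset_gate",
    "run_gating",
]

ALPHA_MEM_DEFAULT = 0.8
BETA_RESET_DEFAULT = 0.2
ORDER_DEFAULT = 2


def _check_alpha(alpha_mem: float) -> None:
    if not 0.5 < alpha_mem < 1:
        raise ValueError(f"alpha_mem={alpha_mem} outside (0.5, 1); require 0.5 < alpha < 1")


def _check_beta(beta_reset: float) -> None:
    if not 0 < beta_reset <= 1:
        raise ValueError(f"beta_reset={beta_reset} outside (0, 1]; require 0 < beta <= 1")


@dataclass(frozen=True)
class AccessibilityState:
    """Gating, memory, and attention accessibility matrices at order ``m``.

    ``gating`` and ``memory`` are sign matrices (entries in {-1,0,1});
    ``attention`` is real-valued in [-1, 1].  At order 1 all three equal
    the adjacency (the ungated ablation).
    """

    order: int
    gating: np.ndarray
    memory: np.ndarray
    attention: np.ndarray
    alpha_mem: float = ALPHA_MEM_DEFAULT
    beta_reset: float = BETA_RESET_DEFAULT

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("order must be >= 1")
        _check_alpha(self.alpha_mem)
        _check_beta(self.beta_reset)
        if not (sign_matrix_ok(self.gating) and sign_matrix_ok(self.memory)):
            raise ValueError("gating/memory matrices must have entries in {-1,0,1}")
        if np.abs(self.attention).max(initial=0.0) > 1 + 1e-12:
            raise ValueError("attention matrix entries must lie in [-1, 1]")


def accessibility_matrix(A: np.ndarray, k: int) -> np.ndarray:
    """Order-``k`` signed accessibility matrix of adjacency ``A``.

    M0 is the identity, M1 = A, and each further order is the elementwise
    sign of the product with A.  At k = 2 this equals the sign of the
    surplus of positive over negative length-2 walks; at higher orders the
    recursion (not global walk counting) is the definition.
    """
    A = np.asarray(A)
    if k < 0:
        raise ValueError("order k must be >= 0")
    M = np.eye(A.shape[0], dtype=np.int64)
    for _ in range(k):
        M = sgn(M @ A)
    return M


def update_gate(M_mem: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Next-order gating matrix: elementwise sign of ``M_mem @ A``."""
    M_mem, A = np.asarray(M_mem), np.asarray(A)
    if M_mem.shape != A.shape:
        raise ValueError(f"shape mismatch: {M_mem.shape} vs {A.shape}")
    return sgn(M_mem @ A)


def memory_gate(M_gate_next: np.ndarray, M_mem: np.ndarray,
                alpha_mem: float = ALPHA_MEM_DEFAULT) -> np.ndarray:
    """Blend the raw next order with the current memory, sign-dominantly.

    Returns ``sgn((1-alpha) * M_gate_next + alpha * M_mem)``.  For
    alpha > 0.5 any nonzero entry of ``M_mem`` keeps its sign.
    """
    _check_alpha(alpha_mem)
    return sgn((1 - alpha_mem) * np.asarray(M_gate_next) + alpha_mem * np.asarray(M_mem))


def reset_gate(M_att: np.ndarray, M_mem_next: np.ndarray,
               beta_reset: float = BETA_RESET_DEFAULT) -> np.ndarray:
    """Attenuated attention matrix ``(1-beta) * M_att + beta * M_mem_next``.

    No sign clipping: first-order entries stay at magnitude 1, newly
    reachable pairs enter at magnitude beta.  beta = 1 gives high-order
    neighbors the same influence as low-order ones.
    """
    _check_beta(beta_reset)
    return (1 - beta_reset) * np.asarray(M_att, dtype=np.float64) \
        + beta_reset * np.asarray(M_mem_next, dtype=np.float64)


def run_gating(A: np.ndarray, m: int = ORDER_DEFAULT,
               alpha_mem: float = ALPHA_MEM_DEFAULT,
               beta_reset: float = BETA_RESET_DEFAULT) -> AccessibilityState:
    """Iterate the three gates from order 1 to ``m``.

    Order 1 returns memory = attention = A (the ungated SN-GAT ablation).
    """
    if m < 1:
        raise ValueError("order m must be >= 1")
    _check_alpha(alpha_mem)
    _check_beta(beta_reset)
    A = np.asarray(A)
    gating = A.copy()
    memory = A.copy()
    attention = A.astype(np.float64)
    for _ in range(2, m + 1):
        gating = update_gate(memory, A)
        memory_next = memory_gate(gating, memory, alpha_mem)
        attention = reset_gate(attention, memory_next, beta_reset)
        memory = memory_next
    return AccessibilityState(m, gating, memory, attention, alpha_mem, beta_reset)
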