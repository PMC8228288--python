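"""Signed-graph data model, adjacency construction, and edge-list I/O.

A protein-protein interaction (PPI) signed network is an undirected graph
whose edges carry a polarity: +1 for a positive interaction, -1 for a
negative one.  Unobserved pairs are encoded 0 ("unknown") in the adjacency
matrix, and every node is taken to be positively related to itself, so the
adjacency diagonal is fixed to +1.  Self-loops are implicit and may not be
declared in input files.

Node labels are opaque strings; internal indexing is 0-based in
first-appearance order, which keeps matrices reproducible from a given
edge-list file.  Figures in the docs use 1-based node labels and say so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SignedGraph",
    "sgn",
    "sign_matrix_ok",
    "build_adjacency",
    "read_edge_list",
    "write_edge_list",
]

#: accepted textual sign tokens -> integer sign
_SIGN_TOKENS = {"1": 1, "+1": 1, "-1": -1, "−1": -1}


def sgn(x):
    """Elementwise sign: 1 for positive, -1 for negative, 0 for zero.

    Accepts scalars or arrays; rejects non-finite input, which would
    indicate invalid arithmetic upstream.
    """
    arr = np.asarray(x)
    if not np.all(np.isfinite(arr)):
        raise ValueError("sgn() requires finite input")
    out = np.sign(arr).astype(np.int64)
    return out if out.ndim else int(out)


def sign_matrix_ok(M: np.ndarray) -> bool:
    """True when every entry of ``M`` lies in {-1, 0, +1}."""
    return bool(np.isin(np.asarray(M), (-1, 0, 1)).all())


@dataclass(frozen=True)
class SignedGraph:
    """Undirected signed graph over an ordered node set.

    Parameters
    ----------
    node_ids
        Ordered node labels; position defines the 0-based matrix index.
    edges
        Tuples ``(i, j, s)`` of node *indices* with ``i < j`` and sign
        ``s`` in {+1, -1}.  Each unordered pair appears at most once.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node labels")
        seen: dict[tuple[int, int], int] = {}
        for i, j, s in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references unknown node")
            if i == j:
                raise ValueError(f"self-loop on node index {i}; self-relation is implicit")
            if s not in (-1, 1):
                raise ValueError(f"edge sign must be +1 or -1, got {s}")
            key = (min(i, j), max(i, j))
            if key in seen and seen[key] != s:
                raise ValueError(
                    f"conflicting duplicate edge between "
                    f"{self.node_ids[key[0]]!r} and {self.node_ids[key[1]]!r}"
                )
            seen[key] = s

    @classmethod
    def from_edges(
        cls,
        edge_triples: Iterable[tuple[str, str, int]],
        node_ids: Sequence[str] | None = None,
    ) -> "SignedGraph":
        """Build a graph from ``(label_a, label_b, sign)`` triples.

        Unless ``node_ids`` is given, nodes are ordered by first appearance.
        """
        triples = list(edge_triples)
        if node_ids is None:
            order: dict[str, int] = {}
            for a, b, _ in triples:
                for lab in (a, b):
                    if lab not in order:
                        order[lab] = len(order)
            node_ids = list(order)
        index = {lab: k for k, lab in enumerate(node_ids)}
        edges = set()
        for a, b, s in triples:
            if a not in index or b not in index:
                raise ValueError(f"edge ({a!r},{b!r}) references unknown node")
            i, j = index[a], index[b]
            if i == j:
                raise ValueError(f"self-loop on node {a!r}; self-relation is implicit")
            edges.add((min(i, j), max(i, j), int(s)))
        return cls(tuple(node_ids), frozenset(edges))

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(n_edges, 3)`` int array, canonically sorted."""
        if not self.edges:
            return np.empty((0, 3), dtype=np.int64)
        return np.array(sorted(self.edges), dtype=np.int64)

    def with_edges(self, edges: Iterable[tuple[int, int, int]]) -> "SignedGraph":
        """Same node set, different edge set (used for train-only graphs)."""
        canon = frozenset((min(i, j), max(i, j), int(s)) for i, j, s in edges)
        return SignedGraph(self.node_ids, canon)


def build_adjacency(g: SignedGraph) -> np.ndarray:
    """Signed adjacency matrix of ``g``: symmetric, diagonal +1.

    Off-diagonal entry (i, j) is the edge sign, or 0 for an unknown pair.
    """
    A = np.eye(g.n, dtype=np.int64)
    for i, j, s in g.edges:
        A[i, j] = s
        A[j, i] = s
    return A


def _parse_sign(token: str, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[token.strip()]
    except KeyError:
        raise ValueError(f"line {lineno}: unparsable sign token {token!r}") from None


def read_edge_list(path: str | Path, dialect: str = "tsv") -> SignedGraph:
    """Read a signed edge list: rows ``node_a <sep> node_b <sep> sign``.

    ``dialect`` is ``"tsv"`` (tab/whitespace separated) or ``"csv"``.
    Sign tokens accepted: ``1``, ``+1``, ``-1`` (ASCII or minus-sign).
    Lines beginning with ``#`` and blank lines are skipped.  Self-loop rows
    are rejected: the positive self-relation is implicit in the model.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    triples: list[tuple[str, str, int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if dialect == "csv" else line.split()
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 fields, got {len(parts)}")
            a, b, tok = (p.strip() for p in parts)
            if a == b:
                raise ValueError(f"line {lineno}: self-loop {a!r}; self-relation is implicit")
            triples.append((a, b, _parse_sign(tok, lineno)))
    return SignedGraph.from_edges(triples)


def write_edge_list(g: SignedGraph, path: str | Path, dialect: str = "tsv") -> None:
    """Write ``g`` in the edge-list format read by :func:`read_edge_list`."""
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w", encoding="utf-8") as fh:
        for i, j, s in sorted(g.edges):
            fh.write(f"{g.node_ids[i]}{sep}{g.node_ids[j]}{sep}{'+1' if s > 0 else '-1'}\n")
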