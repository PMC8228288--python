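"""Synthetic signed networks with controllable balance structure.

The generator implements the two-faction (generalizable to f-faction)
balanced model: nodes are assigned uniformly to factions, each unordered
pair becomes an edge with probability p, the sign is + within a faction
and - across factions, and each sign is independently flipped with
probability eps.  At eps = 0 every triangle is balanced (the structural
theorem of balance), which is exactly the inductive bias the gated signed
attention model encodes — so faction networks are the canonical
recoverable ground truth for it.

The worked seven-node example network also lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .graph import SignedGraph

__all__ = ["SyntheticConfig", "generate", "fixture_seven_node"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Faction-model parameters; generation is a pure function of these."""

    n_nodes: int
    n_factions: int = 2
    density: float = 0.1
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_factions < 1:
            raise ValueError("n_factions must be >= 1")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")


def generate(config: SyntheticConfig) -> tuple[SignedGraph, np.ndarray]:
    """Sample a faction network; returns the graph and hidden faction labels.

    The labels are diagnostics only — nothing downstream may use them.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_nodes
    factions = rng.integers(0, config.n_factions, size=n)
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < config.density
    signs = np.where(factions[iu] == factions[ju], 1, -1)
    flips = rng.random(iu.size) < config.noise
    signs = np.where(flips, -signs, signs)
    edges = frozenset(
        (int(i), int(j), int(s))
        for i, j, s, keep in zip(iu, ju, signs, present) if keep
    )
    node_ids = tuple(f"N{k}" for k in range(n))
    return SignedGraph(node_ids, edges), factions


def fixture_seven_node() -> SignedGraph:
    """The packaged seven-protein example network.

    Nodes are labelled "1".."7" (matching the 1-based figure labels); the
    positive self-relations are implicit, so its adjacency has diagonal +1.
    """
    from .graph import read_edge_list

    with resources.as_file(
        resources.files("snggat.data").joinpath("seven_node_edges.tsv")
    ) as path:
        return read_edge_list(path)
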