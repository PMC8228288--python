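"""Metrics, PR curves, cross-validation, and balance-theory analysis.

The positive interaction is the positive class throughout.  auPR is the
average-precision summation sum_n (R_n - R_{n-1}) P_n over descending
score thresholds — not trapezoidal interpolation, which is optimistic on
PR curves.

Balance analysis: a triangle is structurally balanced when the product of
its three edge signs is positive.  An edge (i, j) of a predicted complete
network "satisfies balance" when its sign agrees with the majority sign
of the route products over all routes of the configured length between i
and j (self-loops are ignored, so an edge never votes on itself); edges
with no routes, or a tied vote, are excluded from the denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .graph import SignedGraph
from .model import EdgeSplit, TrainConfig, predict_signs, train

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "EvalReport",
    "confusion",
    "metrics",
    "pr_curve",
    "split_k_fold",
    "crossval",
    "balance_satisfaction",
    "triangle_balance_census",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_signs, true_signs) -> ConfusionCounts:
    """Confusion counts for sign vectors in {-1, +1}; +1 is positive."""
    pred = np.asarray(pred_signs)
    true = np.asarray(true_signs)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == -1))),
        tn=int(np.sum((pred == -1) & (true == -1))),
        fn=int(np.sum((pred == -1) & (true == 1))),
    )


def metrics(c: ConfusionCounts) -> tuple[float | None, float | None, float | None]:
    """(accuracy, precision, recall); an undefined metric is None, not 0."""
    acc = (c.tp + c.tn) / c.total if c.total else None
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else None
    rec = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    return acc, prec, rec


def pr_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision/recall points over descending thresholds, and auPR.

    ``labels`` are signs in {-1, +1}.  auPR is the average-precision
    summation.  Raises on single-class label vectors.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    if pos.all() or (~pos).all():
        raise ValueError("PR curve requires both classes present")
    order = np.argsort(-scores, kind="stable")
    pos_sorted = pos[order].astype(np.float64)
    tp = np.cumsum(pos_sorted)
    fp = np.cumsum(1.0 - pos_sorted)
    # one threshold per distinct score: keep the last index of each tie block
    distinct = np.flatnonzero(np.diff(scores[order], append=np.nan))
    precision = tp[distinct] / (tp[distinct] + fp[distinct])
    recall = tp[distinct] / pos.sum()
    au_pr = float(np.sum(np.diff(recall, prepend=0.0) * precision))
    return precision, recall, au_pr


def split_k_fold(graph: SignedGraph, k: int = 5, seed: int = 0) -> list[EdgeSplit]:
    """Stratified-by-sign k-fold partition of the edge set."""
    edges = graph.edge_array()
    signs = edges[:, 2]
    for cls in (-1, 1):
        if np.sum(signs == cls) < k:
            raise ValueError(f"need at least {k} edges of sign {cls:+d} for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for train_idx, test_idx in skf.split(edges, signs):
        splits.append(EdgeSplit(
            graph,
            tuple(map(tuple, edges[train_idx])),
            tuple(map(tuple, edges[test_idx])),
        ))
    return splits


@dataclass
class FoldResult:
    accuracy: float
    precision: float | None
    recall: float | None
    au_pr: float


@dataclass
class EvalReport:
    """Per-fold metrics with mean and standard deviation."""

    folds: list[FoldResult]
    balance_fraction: float | None = None
    config: dict = field(default_factory=dict)

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("accuracy", "precision", "recall", "au_pr"):
            vals = [getattr(f, name) for f in self.folds if getattr(f, name) is not None]
            out[name] = (float(np.mean(vals)), float(np.std(vals)))
        return out

    def to_text(self) -> str:
        lines = ["fold\taccuracy\tprecision\trecall\tauPR"]
        for k, f in enumerate(self.folds, start=1):
            fmt = lambda v: "NA" if v is None else f"{v:.4f}"
            lines.append(f"{k}\t{fmt(f.accuracy)}\t{fmt(f.precision)}\t{fmt(f.recall)}\t{fmt(f.au_pr)}")
        s = self.summary()
        lines.append("mean\t" + "\t".join(
            f"{s[n][0]:.4f}±{s[n][1]:.4f}" for n in ("accuracy", "precision", "recall", "au_pr")))
        if self.balance_fraction is not None:
            lines.append(f"balance_satisfaction\t{self.balance_fraction:.4f}")
        return "\n".join(lines)


def _eval_split(graph: SignedGraph, split: EdgeSplit, config: TrainConfig) -> FoldResult:
    result = train(graph, split, config)
    test = np.array(split.test_edges, dtype=np.int64)
    pairs = list(zip(test[:, 0], test[:, 1]))
    pred, scores = predict_signs(result.predictions, pairs, config.threshold)
    true = test[:, 2]
    acc, prec, rec = metrics(confusion(pred, true))
    try:
        _, _, au_pr = pr_curve(scores, true)
    except ValueError:
        au_pr = float("nan")
    return FoldResult(acc, prec, rec, au_pr)


def crossval(graph: SignedGraph, k: int = 5, repeats: int = 3,
             config: TrainConfig | None = None, seed: int = 0,
             compute_balance: bool = False) -> EvalReport:
    """Repeated stratified k-fold cross-validation.

    Each fold is trained ``repeats`` times with distinct seeds and the
    fold's metrics are the average of the repeats.  Optionally trains once
    on the full edge set and reports the balance-satisfaction fraction of
    the reconstructed network.
    """
    config = config or TrainConfig()
    folds = []
    for f, split in enumerate(split_k_fold(graph, k=k, seed=seed)):
        runs = []
        for r in range(repeats):
            cfg = TrainConfig.from_dict(
                {**config.to_dict(), "seed": (config.seed + 1000 * f + r) % (2**31)})
            runs.append(_eval_split(graph, split, cfg))
        folds.append(FoldResult(*[
            float(np.mean([getattr(x, nm) for x in runs]))
            for nm in ("accuracy", "precision", "recall", "au_pr")]))
    balance = None
    if compute_balance:
        result = train(graph, None, config)
        balance = balance_satisfaction(result.predictions.A_r)
    return EvalReport(folds, balance_fraction=balance, config=config.to_dict())


def _signed_route_counts(A0: np.ndarray, route_length: int) -> np.ndarray:
    """Signed count of simple routes of the given length between pairs.

    ``A0`` must have a zero diagonal.  Entry (i, j) is (positive-product
    routes) - (negative-product routes) over routes whose intermediates
    avoid i and j.
    """
    if route_length == 2:
        counts = A0 @ A0
    elif route_length == 3:
        # walks of length 3 minus those revisiting an endpoint
        P3 = A0 @ A0 @ A0
        deg = np.abs(A0).sum(axis=1)       # (A0^2) diagonal = node degree
        counts = P3 - A0 * deg[np.newaxis, :] - deg[:, np.newaxis] * A0 + A0
    else:
        raise ValueError("route_length must be 2 or 3")
    np.fill_diagonal(counts, 0)            # self-routes are not meaningful
    return counts


def balance_satisfaction(A_full: np.ndarray, route_length: int = 2) -> float:
    """Fraction of edges whose sign matches the majority route product.

    Edges with no routes of the given length, or a tied vote, are excluded
    from the denominator.  Raises when no edge is evaluable.
    """
    A0 = np.asarray(A_full).copy().astype(np.int64)
    np.fill_diagonal(A0, 0)
    routes = _signed_route_counts(A0, route_length)
    iu = np.triu_indices_from(A0, k=1)
    edge_sign = A0[iu]
    vote = routes[iu]
    evaluable = (edge_sign != 0) & (vote != 0)
    if not evaluable.any():
        raise ValueError("no evaluable edges: every edge has no routes or a tied vote")
    satisfied = np.sign(vote[evaluable]) == edge_sign[evaluable]
    return float(satisfied.mean())


def triangle_balance_census(A: np.ndarray) -> tuple[int, int]:
    """(balanced, unbalanced) triangle counts; diagonal excluded.

    Uses trace identities: trace(|A0|^3)/6 counts triangles and
    trace(A0^3)/6 is the balanced-minus-unbalanced surplus.
    """
    A0 = np.asarray(A).copy().astype(np.int64)
    np.fill_diagonal(A0, 0)
    B = np.abs(A0)
    total = int(np.trace(B @ B @ B)) // 6
    surplus = int(np.trace(A0 @ A0 @ A0)) // 6
    return (total + surplus) // 2, (total - surplus) // 2


def enumerate_triangles(A: np.ndarray):
    """Yield (i, j, k, sign_product) for each triangle; a slow reference."""
    A0 = np.asarray(A).copy()
    np.fill_diagonal(A0, 0)
    n = A0.shape[0]
    for i, j, k in itertools.combinations(range(n), 3):
        if A0[i, j] and A0[j, k] and A0[i, k]:
            yield i, j, k, int(A0[i, j] * A0[j, k] * A0[i, k])
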