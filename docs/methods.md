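# Methods

## Model

`snggat` treats a PPI corpus as an undirected signed graph. The
adjacency convention is: +1 observed positive interaction, −1 observed
negative interaction, 0 unknown, diagonal fixed at +1 (a node is
positively related to itself; input files may not declare self-loops).
Undirectedness is an assumption — the symmetric adjacency encodes it —
and weighted or directed corpora are out of scope.

The inductive bias is structural balance: a triangle is balanced when
its sign product is positive, and in observed signed networks balanced
triangles dominate. The signed accessibility recursion
`Mₖ = sgn(Mₖ₋₁ · A)` propagates signs along paths under exactly this
rule. For k ≥ 3 the recursion and global signed path counting disagree
(the nested `sgn` collapses path multiplicities order by order); the
recursion is taken as the definition because it is what the gating
mechanism consumes. Only k ≤ 2 has an unambiguous path-counting
interpretation, and the k = 2 case is verified against brute-force path
enumeration in the tests.

The three-gate recursion (update/memory/reset; see README for the
formulas) has two hyperparameters with disjoint roles:

| parameter | range | default | role |
|---|---|---|---|
| `alpha_mem` (α) | (0.5, 1) | 0.8 | memory weight; any α > 0.5 makes the memory gate sign-dominant, so the default only matters at entries where memory is zero |
| `beta_reset` (β) | (0, 1] | 0.2 | attention magnitude given to neighbors first reached at the next order; β = 1 flattens the order hierarchy |
| `order` (m) | ≥ 1 | 2 | neighborhood order; m = 1 disables gating entirely (the ungated signed-GAT ablation) |

The name `alpha_mem` avoids a symbol clash: α is conventionally also
the attention weight in the layer equations; here the two are distinct
objects.

Memory dominance is a theorem, not a tuning outcome: for α ∈ (0.5, 1),
`sgn((1−α)·g + α·s) = s` whenever s ∈ {−1, +1}, g ∈ {−1, 0, +1}. The
test suite checks all nine entry combinations exhaustively for several
α values.

## Attention layer

Per head: a shared linear map `W`, an attention vector split into
source and destination halves (equivalent to the usual concatenated
form `aᵀ[Whᵢ‖Whⱼ]`), LeakyReLU with negative slope 0.2 (the standard
graph-attention convention; the slope is otherwise unconstrained here),
softmax over `N(i)` implemented by masking non-neighbors before
normalization, then signed re-weighting by `M̃ₘ` with absolute-sum
normalization. The re-weighted coefficients satisfy
`Σⱼ |α(i,j)| = 1` and `sgn α(i,j) = sgn M̃ₘ(i,j)` by construction.

Defaults: two layers with output dims 128 and 32, heads 6 and 1,
activations elu and tanh. The six layer-1 heads are merged by
**averaging** (after the per-head activation): 128 is not divisible by
6, so concatenation cannot produce a 128-dim layer output; concat
remains available in the config for other dimension choices.

No dropout and no bias terms by default: the model is deliberately the
smallest faithful form, and all randomness is confined to the seeded
Glorot-uniform initialization. Forward passes and training are
bit-reproducible given the seed.

## Decoding, loss, and training protocol

Embeddings are decoded with the inner product `S = Z·Zᵀ` (symmetric by
construction; its diagonal `‖zᵢ‖²` is non-negative). Binary predictions
use `sign = +1 iff S(i,j) > threshold` with threshold 0; a score exactly
at the threshold maps to −1 so that every evaluated pair receives a
prediction, while the reconstructed matrix `A_r = sgn(S)` retains the
raw 0. The loss is mean binary cross-entropy with logits over the
*observed training edges only*, each undirected edge counted once; no
negative sampling of unknown pairs is performed because the intended
corpora are balanced 50/50 between positive and negative edges by
construction.

Transduction hygiene: held-out edges are set to 0 ("unknown") in the
training adjacency, and *everything* derived from the graph — the
gating matrices, the `M₂` feature table, the attention masks, the loss —
is computed from that censored adjacency. A sentinel-edge test asserts
that removing an edge from the test set (versus deleting it from the
graph entirely) changes nothing downstream. This is the only
leakage-free reading of the transductive protocol; published results on
the real corpora may or may not have censored features the same way,
which is one reason they are not re-derivable from this package alone.

Optimization: full-batch Adam, learning rate 0.002, 300 epochs by
default. Epoch count is a free choice (no early stopping is part of the
protocol). Divergence (non-finite loss) raises immediately with advice
to lower the learning rate.

## Evaluation

Accuracy, precision and recall follow the usual confusion-matrix
definitions with +1 as the positive class; a metric with a zero
denominator is reported as undefined (`None`), never silently as 0.
auPR is the average-precision summation `Σ (Rₙ−Rₙ₋₁)·Pₙ` over distinct
descending score thresholds; tests cross-check it against an exhaustive
threshold oracle and against scikit-learn's implementation.
Cross-validation is stratified by edge sign (scikit-learn
`StratifiedKFold` under the hood), k = 5 folds with 3 repeated training
runs per fold averaged, matching the protocol used for the reference
corpora.

Balance analysis: the census classifies each triangle by its sign
product using the trace identities `trace(|A₀|³)/6` and
`trace(A₀³)/6` (A₀ = adjacency with zeroed diagonal). The
balance-satisfaction fraction asks, for each predicted edge, whether its
sign matches the majority sign product over routes between its
endpoints. Route length defaults to 2 — the minimal unambiguous reading,
and the one matching the order-2 machinery — with length 3 available
(simple-path counts obtained from the walk count with endpoint-revisit
corrections). The diagonal is zeroed first so an edge never votes on
itself through self-loop routes, and edges with no routes or a tied vote
are excluded from the denominator rather than counted as violations.

## Synthetic data

The generator samples the f-faction balanced model: uniform faction
assignment, each pair an edge with probability p, sign + within and −
across factions, then independent sign flips with probability ε. At
ε = 0 every triangle is balanced, so a model whose bias is balance
theory should recover held-out signs perfectly — this is the canonical
recoverable ground truth, and the noise-free cross-validation accuracy
of ~1.0 confirms it. Study-condition defaults used throughout the tests:
n = 200 nodes, 2 factions, p = 0.1, ε ∈ {0, 0.05}, 5-fold CV with 3
repeats, 300 epochs.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real PPI networks, sequence- or localization-derived
node features, correlated (non-independent) annotation errors, and the
subcellular-localization rule used to construct negative pairs in real
corpora (documented here, not implemented: negatives are drawn by
randomly pairing proteins with different subcellular localizations).
Passing the synthetic recovery tests therefore demonstrates that the
machinery works and the balance bias is recoverable — not that real-data
headline numbers are reproduced.

Under ε = 0.05 the observed-label accuracy ceiling is ≈ 0.95 (flipped
test labels are unpredictable in principle), and long full-batch
training additionally memorizes flipped *training* edges through the
unregularized model, costing a few further points of held-out accuracy;
mean cross-validated accuracy sits near 0.90 under the default 300
epochs (higher when training is stopped earlier, e.g. ≈ 0.93 at 100
epochs on the same splits). Since the protocol has no early stopping,
this trade-off is reported rather than tuned away.

## Numerical choices

- Dense int64/float64 matrices throughout; the intended graphs are at
  most a few thousand nodes. Sparse representations would be an
  optimization, not a behavioral change.
- `sgn` rejects non-finite input rather than propagating NaN.
- Softmax is computed with row-max shifting; masked entries get
  probability exactly 0 (not a tiny float).
- The signed-attention denominator `Σ|coef·M̃|` is checked and a
  degenerate (all-zero) neighborhood raises; with m = 2 defaults this
  cannot occur because `M̃₂` is nonzero wherever `M′₂` is.
- Training seeds for repeated CV runs are derived as
  `seed + 1000·fold + repeat` (kept below 2³¹).
- The in-repo autodiff engine is validated against central finite
  differences for every operation and composite it supports.

## Limitations

- Real-corpus benchmarks require external downloads and a masking
  protocol that published work leaves unspecified; this package fixes
  the leakage-free variant and makes no claim of matching numbers
  obtained under laxer protocols.
- The accessibility recursion for k ≥ 3 is definitionally the nested
  sign, which discards path-multiplicity information; interpretation of
  high orders should be done with care (model quality is also known to
  degrade for m > 2).
- Single-machine, CPU, full-batch training only; no mini-batching or
  GPU path.
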