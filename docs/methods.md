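# Methods

## Problem setting

Supervised cell-type annotation: a reference scRNA-seq matrix X₀ (rows =
genes, columns = cells) with known labels y₀ over K ≥ 2 cell types, and a
test matrix X₁ whose cells must each receive one of those K labels. The
method assumes the test tissue contains no cell types absent from the
reference; detecting novel types is explicitly out of scope and should be
handled upstream.

## Preprocessing

Both matrices are library-size normalized per cell to a total of 10,000
followed by log(1 + x), then restricted to their shared genes (rows sorted
lexicographically so both matrices carry identical gene order). The
normalization target and transform are the de-facto standard of the
single-cell ecosystem; `none` is available for pre-normalized input. A cell
with zero total counts is an error rather than a silent drop, so cell
counts are conserved by contract. All downstream steps — profile
correlation, marker sensitivity, network training — consume these
normalized values; marker logic only uses positivity (x > 0), which the
monotone transform preserves, so it is insensitive to this choice.

## Strategy dispatch

Per-type mean profiles form the G × K matrix A; P = corr(A) is its Pearson
correlation matrix over types. If any off-diagonal p_ij ≥ τ the hierarchical
classifier is used, otherwise the flat one. The comparison is inclusive
(≥ τ) and τ defaults to 0.95; τ is exposed (`--tau`) and not auto-tuned —
smaller values force hierarchical mode for complicated type structures. A
constant profile column makes the correlation undefined and is treated as an
error: an annotator trained on a zero-variance profile is meaningless.

## Flat classifier

Dense feed-forward network, ReLU hidden layers, K-unit softmax head,
categorical cross-entropy L(Θ) = −(1/n) Σᵢ 1(yᵢ = k) log p̂ᵢₖ. Three size
presets fix the hidden widths: small (64), medium (64, 128), big
(64, 128, 256). Optimization is mini-batch RMSprop with framework-standard
defaults: batch 128, 30 epochs, learning rate 10⁻³, decay 0.9, ε = 10⁻⁷.
Weights are Glorot-uniform initialized from a seeded generator; two runs
with the same seed are bitwise identical. Batch normalization and dropout
are omitted deliberately — they do not change performance materially in
this regime and cost determinism headaches. No early stopping or schedule:
a fixed epoch budget keeps runs reproducible; the per-epoch loss trace is
recorded for inspection (an optional validation fraction can be held out
for monitoring only).

Numerical choices: softmax is computed with max-subtraction;
probabilities are clamped at 10⁻¹² inside both cross-entropies so a
confidently wrong prediction costs a large finite loss, never −inf. Argmax
ties break toward the lowest class index (sorted label order) —
deterministic and documented. At prediction, test rows are matched to the
training gene order by id; training genes absent from the test matrix are
zero-imputed with a logged warning (after the gene intersection this only
happens when a saved model meets new data); zero overlap is an error.

## Hierarchical classifier

**Lineage tree.** Complete-linkage agglomerative clustering of the columns
of A under Euclidean distance. Complete linkage is part of the method;
the metric is our choice of the common default. The merge order of the
linkage algorithm is deterministic; within a merge record the first-listed
cluster becomes the left child. The tree has exactly K leaves and K − 1
bifurcations and can be exported as Newick text.

**Marker sensitivity.** Sen_gk = Σ_c 1(X_gc > 0 ∧ y_c = k) / Σ_c 1(X_gc > 0):
the fraction of expressing cells that belong to type k. The sum is applied
to numerator and denominator — the only reading that keeps the score in
[0, 1]; for any expressed gene the scores sum to 1 over types, and a gene
expressed nowhere scores 0 everywhere. Genes with Sen_gk > 0.95 are type
k's exclusive markers. Types with strictly more than ν₁ = 10 markers are
eligible for direct assignment: a test cell expressing strictly more than
ν₂ = 3 markers of exactly one eligible type takes that label immediately. A
cell exceeding ν₂ for two or more types is deferred to the tree rather than
arbitrarily assigned. Both inequalities are strict, following the
"more than" phrasing of the rule.

**Per-bifurcation features.** Genes are ranked by |moderated t| between the
pooled left- and right-branch training cells and the top min(M, G) are kept
(M = 1000). The moderated t shrinks per-gene pooled variances toward a
common prior by empirical Bayes: with s²_g on d degrees of freedom, the
prior (d₀, s₀²) is fitted by moment-matching log s² against the scaled-F
model (trigamma inversion by Newton iteration), and the posterior variance
is (d₀s₀² + d s²_g)/(d₀ + d). When the observed variances show no excess
spread, d₀ = ∞ and the posterior is the mean variance. The implementation
is native Python — only the ranking is consumed, so no p-values are needed —
and a test cross-checks it against the reference R implementation to 10⁻⁸.
Ties rank by gene id; a branch with fewer than two cells falls back to an
unmoderated mean-difference ranking with a warning.

**Node networks and routing.** Each bifurcation trains the same dense stack
with a single sigmoid unit and binary cross-entropy, target 1 for the right
branch, using only training cells whose type belongs to the node's leaf
set, restricted to the node's features. Node seeds derive deterministically
from the run seed and the node's leaf set (CRC32), so node training is
reproducible and independent of traversal order. At prediction, deferred
cells descend from the root, going right iff p̂ ≥ 0.5 (ties right,
documented), and take the label of the leaf they reach — assignment is
therefore exhaustive, with no intermediate-node outcomes.

## Evaluation

Accurately assigned rate = fraction of exact label matches (supervised:
label names must match). Adjusted Rand index = chance-corrected
pair-counting agreement between the predicted and true partitions,
invariant to label renaming, hence comparable against unsupervised
baselines. Both are reported together with a true × predicted confusion
table.

## Synthetic data generator

The generator emulates the structural features the method keys on, not any
particular tissue:

- **Base profiles.** Per group, gene means are log-normal
  (log-mean −1, log-sd 1.6), spanning several orders of magnitude.
- **Correlated types.** Types sharing a `group` multiply the group profile
  by exp(σ·N(0,1)) with σ = `within_group_perturbation` (default 0.02),
  yielding mean-profile Pearson r ≈ 0.96–0.99 after normalization at a few
  hundred cells per type; distinct groups draw independent profiles and
  correlate near 0. The default marker level is deliberately moderate
  (below): strong exclusive markers would themselves decorrelate the
  profiles, contradicting the "highly correlated subtypes" scenario these
  fixtures exist to produce.
- **Markers.** Each type receives `n_markers_per_type` (default 12)
  exclusive genes, expressed at `marker_fold` (default 5) × the median base
  gene mean in their own type and exactly zero elsewhere — so with dropout
  off their sensitivity is 1 by construction.
- **Counts and dropout.** Negative binomial with var = μ + 0.3 μ², then
  independent Bernoulli zero-masking (default rate 0.2); overall sparsity
  at defaults is roughly 75–80% zeros. Dropout uses its own seeded
  substream, so raising only the rate zeroes a superset of entries.
- **Determinism.** One seed fans out to fixed substreams (profiles,
  markers, counts, dropout); identical configs are bitwise identical.

What the generator does *not* model: batch effects, doublets, ambient RNA,
gene-length bias, or the empirical mean–variance relationship of any real
platform. Passing tests on these fixtures demonstrates that the pipeline's
logic (dispatch, marker rules, tree routing, exhaustiveness, determinism)
is correct under the stated generative assumptions — not that a given real
tissue will be annotated at the same accuracy.

## Problem sizes used in the checks

The end-to-end regimes are sized for a desktop CPU: the flat ("easy")
regime uses four uncorrelated types at 500 cells each (training fraction
0.6, 800 test cells); the hierarchical ("hard") regime uses two grouped
plus two free types at 1250 cells each (training fraction 0.8 → 1000
training cells per type, 800 test cells); dispatch reliability uses 100
replicates per regime at 100 cells per type. All use the default 2000-gene
transcriptome and the small model preset.

## Known limitations

- No rejection option: a test cell of a type absent from the reference is
  still assigned the nearest training label.
- The marker pre-assignment is binary on positivity; expression magnitude
  is ignored at that stage.
- Hierarchical node classifiers reuse the user-selected model-size preset;
  no per-node capacity tuning.
- Dense in-memory matrices only; references far beyond ~10⁴ cells ×
  ~2×10⁴ genes will want a sparse backend.
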