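# Methods

## Model

A nested effects model over K perturbed S-genes and L observed E-genes
consists of a directed graph on the S-genes and an attachment `θ_l ∈
{1..K}` for each E-gene.  Perturbing `S_j` is predicted to affect `E_l`
iff `S_j` is upstream of (or equal to) the attachment `S_{θ_l}` in the
reflexive-transitive closure `Φ` of the graph.  Because any two graphs
with the same closure make identical predictions, the package represents
and enumerates topologies as closed matrices with a reflexive diagonal
(`φ_kk = 1`), i.e. as preorders; scoring an unclosed graph goes through
its closure, which makes score equivalence hold by construction.

The data are posterior probabilities `p_lk ∈ [0,1]` of differential
expression (one moderated test per gene and perturbation, computed
upstream of this package).  Conditional on `Φ` and `θ_l`, cell `(l,k)`
contributes `p_lk` where an effect is predicted and `1 − p_lk` where
not; cells are independent given the attachment.  The attachment is
integrated out under a prior `P(θ)` and the per-gene marginals multiply
across E-genes.

## Attachment prior

The default prior is uniform over the K S-genes with **no** unattached
state: the marginal likelihood is a plain average of the K product
terms.  Because part of the NEM literature includes a "null" E-gene
state, `AttachmentPrior("uniform_with_null", null_weight=w)` adds an
attachment that predicts no effects anywhere, with default
`w = 1/(K+1)`; it is an option, not the default, and every scoring
function accepts it.

## Class Bayes factor

A `FeatureSpec` predicate splits the enumerated space into `C_f` /
`C_f̄`.  Predicates are evaluated on the closure's off-diagonal entries,
so "edge from A to B" means strict reachability — anything finer than
the closure would not be identifiable anyway.  For the cross-group
feature the default direction mode counts an edge in either direction.
With uniform within-class topology priors the Bayes factor is the ratio
of class-averaged marginal likelihoods, reported as

    log B = log(N_f̄/N_f) + log Σ_{C_f} P(D|Φ) − log Σ_{C_f̄} P(D|Φ),

with both class sums done by log-sum-exp.  `log B` is in natural log
throughout the API; the CLI also prints base 10.  On completely
uninformative data (all `p_lk = 0.5`) every topology scores `(1/2)^{LK}`
and the penalty cancels the size advantage exactly, so `log B = 0` to
rounding — a useful null check.

## Numerical choices

- Probabilities are clamped into `[ε, 1−ε]` with `ε = 1e−6` at file
  load (count of clamped entries logged); scoring functions reject
  exact 0/1 entries with a message pointing at clamping.  `ε` trades a
  bounded per-cell log penalty (`|log ε| ≈ 13.8`) against fidelity to
  probabilities reported as exactly 1.
- All internal logarithms are natural; `log1p` is used for `1 − p`.
- Enumeration is a vectorized brute force: all `2^{K(K−1)}` off-diagonal
  edge sets are closed in one batched Warshall pass and deduplicated,
  capped at K = 5 (about 10^6 closures, ~2 s).  The method targets
  focused gene sets, so no scalable enumeration is attempted.
- Enumeration order is sorted by a canonical key (the packed bits of the
  closed adjacency), making partitions and result files reproducible.
- Batch scoring caches the per-row log likelihood of each distinct
  effect pattern (at most `2^K` columns), so scoring all 355 K=4
  topologies on thousands of genes is effectively instant.

## Stability sweep

Genes are scored by `max_k p_lk`; a cutoff `λ` includes genes scoring
**strictly** above `λ` (the boundary convention is explicit and
tested).  `auto` mode uses the distinct observed scores in descending
order as the cutoff grid — each grid point is the largest cutoff that
produces its subset, so every achievable subset appears exactly once —
followed by 0.0 so the least stringent point is the full matrix.  The
exported curve carries both the cutoff and the gene count; the gene
count is the natural x-axis because it is invariant to score
calibration.

## Synthetic data generator

`simulate_effect_matrix` runs the data model forward from a closed
ground truth: each gene is unattached noise with probability
`frac_noise_genes` (entries uniform on [0,1]), otherwise it draws an
attachment from the prior and its entries follow
`Beta(a_effect, b_effect)` where an effect is predicted and
`Beta(a_null, b_null)` elsewhere.  Defaults `(8, 2, 2, 8, 0.1)` give
bimodal probabilities with means 0.8/0.2 and a 10 % noise-gene
fraction — an informative but far-from-degenerate screen resembling the
probability heat maps of real K=4 knock-down data.  The generator
validates that the effect mean exceeds 0.5 and the null mean is below
it.  Draws use numpy's PCG64 generator, recorded in the dataset
metadata together with the seed.

What the generator does *not* emulate: replicate structure, correlated
noise between perturbations, miscalibrated posteriors, and effect
probabilities that depend on expression level.  Passing the recovery
tests therefore shows the statistic behaves correctly under the stated
model, not that any particular biological dataset will be as clean.

The default case-study template (`case_study_labels`,
`case_study_feature`) is the K=4 geometry of a Wnt-signalling screen:
secretion machinery {EVI_WLS, APC} versus transcriptional module
{CTNNB1, TCF7L2}, whose cross-group-edge feature splits the 355
topologies 339 / 16 (the featureless class factors as the 4 × 4 ordered
pairs of 2-node preorders).

## Problem sizes used in the checks

The Monte-Carlo recovery experiment uses 100 replicates per class at
L = 200 genes with the default noise model; the stability check uses
150 attached plus 50 noise genes.  These sizes make the experiments
reproducible in seconds while leaving the recovery bound (≥ 95 % correct
sign per class) non-trivial.

## Known limitations

- Exhaustive enumeration caps K at 5; larger pathways need a different
  (sampling or constraint-based) treatment that is out of scope here.
- One attachment per E-gene; no multi-attachment or time-resolved
  variants.
- The Bayes factor compares exactly two complementary classes; multiple
  simultaneous features are not supported.
- Estimating `p_lk` from raw counts is upstream of this package.
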