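# Methods

## Problem setting

The package scores, per cell, the activity of perturbation-derived gene
programs ("terms") in scRNA-seq count data. A term is a named gene set
extracted from one perturbation signature (compound × cell line × time ×
direction). Terms are first-class: they fix the latent dimensionality,
the decoder sparsity pattern, and the vocabulary of every downstream
report.

## Term construction

`extract_signature_terms` thresholds a genes × signatures matrix of
standardized differential-expression scores at ±2.0 (configurable),
emitting `<signature>_UP` and `<signature>_DOWN` terms, each capped at
500 genes by descending |score| and dropped below 5 genes. UP and DOWN
terms from one signature are kept separate: they describe opposite
transcriptional programs and merging them would average away direction.
Gene identifiers are matched exactly — no case folding, no alias tables.
Silent alias mapping is a reproducibility hazard; if two resources use
different id schemes, harmonize them explicitly before `align_terms`.
Ties at the gene cap break lexically by gene id so builds are
deterministic.

## Generative model and likelihood

Counts are modelled as negative binomial with gene-wise learned
inverse-dispersion θ_g (mean/inverse-dispersion parameterization). The
encoder input is library-size normalized to 10⁴ and log1p-transformed;
raw counts remain the reconstruction target. Conditions enter one-hot
into the encoder input and as per-condition decoder offsets — the model
is a conditional VAE, so condition-specific shifts are absorbed by the
offsets rather than leaking into term scores.

The decoder is linear with two weight matrices sharing the genes × terms
shape: `W`, constrained to the annotation mask, and `W_soft`, constrained
to its complement. The invariants (`W` zero off-mask, `W_soft` zero
on-mask) are enforced after every optimizer step, so a gene annotated to
a term is never re-weighted through a second path and every off-mask
contribution is attributable to the soft mask.

The attention-like gate is a per-cell sigmoid affine map from the last
encoder hidden layer, multiplied elementwise onto the latent sample. The
exact mechanism behind such gating is a design choice here: it is the
simplest map that (a) is bounded in (0,1), (b) can silence irrelevant
terms per cell, and (c) reduces exactly to the ungated model when
disabled (`use_attention=False` gives g ≡ 1, verified by an ablation
test).

## Objective and optimization

total = −NB log-likelihood (mean over cells, sum over genes)
      + α_KL · KL(q‖N(0,I)) + α · Σ_t √d_t ‖W[:,t]‖₂ + α_L1 ‖W_soft‖₁

Defaults: α_KL = 0.005, α = 0.95 (group lasso, with √d_t support
scaling), α_L1 = 0.5, hidden width 512, 4 encoder layers; the latent
dimension always equals the number of terms.

Numerical and optimization choices:

* **Proximal penalties.** The group lasso and L1 terms are handled by
  their proximal operators after each Adam step (column norm shrinkage by
  lr·α·√d_t; elementwise soft-thresholding by lr·α_L1) rather than by
  subgradients. Subgradients under Adam never drive column norms to the
  deactivation threshold — pruning would be cosmetic — and proximal
  steps give exact zeros and monotone deactivation in α.
* **Soft-mask warm-up.** `W_soft` is frozen at zero for the first 30% of
  epochs. Per gene, the L1 price (0.5) is lower than the group-lasso
  price of an annotated column (≈ 0.95·√10 for a 10-gene term), so with
  both active from step one a term's genes can be absorbed by *another*
  term's soft mask while its own column is pruned — annotation loses to
  enrichment. Letting annotated columns establish first removes that
  failure mode; afterwards the soft mask only competes for residual
  signal, which is its intended role.
* **KL warm-up** linearly anneals the KL weight over the first 10% of
  epochs (standard practice to avoid early posterior collapse in NB
  VAEs).
* Clipping: encoder log-variances to ±8, decoder log-means to
  [−30, 15]; clipped activations pass no gradient.
* Early stopping on a seeded 10% validation split, evaluated
  deterministically (z = gated posterior mean) at the full KL weight;
  best parameters are restored.
* Dispersions are learned as log θ_g (positivity by construction),
  initialized at θ = 1; gene biases start at each gene's overall
  frequency so z = 0 reconstructs the mean profile.
* All randomness (init, validation split, minibatch order, reparam
  noise) flows from one seeded generator: two runs with the same config
  and data are bitwise identical (tested at 1e-6).
* Term deactivation: a term is *inactive* when
  ‖W[:,t]‖₂ + ‖W_soft[:,t]‖₂ < 1e-3.

Whether the group norm should carry the √d_t support scaling is
genuinely open; scaled is the default (it prices a 500-gene column and a
5-gene column comparably per gene) and the unscaled variant is one
argument away in `group_lasso_penalty`.

## Influence scores and enrichment

Scores are the deterministic gated posterior means g ⊙ μ, not posterior
samples — reproducibility is worth more than posterior spread for a
screening readout, and a sampling path exists for sensitivity analysis.
Enrichment is one-vs-rest per group: p = P(score in group > score in
rest) over cross pairs (exhaustive when |pairs| ≤ 10⁶, else 10⁵ seeded
sampled pairs), log BF = ln((p+ε)/(1−p+ε)) with ε = 10⁻⁸ bounding
saturation at ±18.4. The 2.3 cutoff on |log BF| (≈ "strong evidence")
defines significance; no further multiple-testing correction is applied
by default, matching the convention this statistic comes from — the
permutation-null test below is the empirical check that the rule is
conservative here.

Exceedance is rank-based, so enrichment is invariant to any monotone
rescaling of a term's scores; strict inequality is used, which makes
log BF antisymmetric in the two groups when values are tie-free.

## Query mapping

A query is projected with the reference core (encoder body, decoder, θ,
reference condition embeddings) frozen; only embeddings for unseen
condition labels are added and fine-tuned (architecture-surgery style).
A SHA-256 hash over the core asserts immutability, and mapping a query
with only known conditions is bitwise identical to direct scoring.
Query genes are matched by id to the reference; missing genes are
zero-filled after normalization with a logged coverage fraction, and
mapping refuses to proceed below 90% coverage of the decoder's
term-support genes.

## Synthetic benchmark

The generator emulates the target data shape: NB counts (θ = 2), 400
genes, 30 disjoint 10-gene terms, 8 cell types × 500 cells, one active
term per type at log-fold ln 4, lognormal library factors (sd 0.3), and
two inert batch labels (conditions exist structurally even when they do
nothing, so the conditional machinery is always exercised). A model-free
oracle — per-type mean log-fold of in-term vs out-of-term genes above
half the configured effect — recovers the ground truth directly from the
counts, confirming the generator writes the signal it claims
independently of the model.

What the generator does *not* emulate: ambient RNA, doublets, CNV
structure, overlapping term programs at scale, or batch effects with
real magnitude (a `batch_log_offsets` hook and Poisson/zero-inflated
toggles exist for robustness experiments). Passing tests therefore show
the inference machinery is correct and calibrated under the model's own
assumptions — not that real tissue atlases will behave as cleanly.

Benchmark-scale training uses a 128-unit, 2-layer encoder for up to 120
epochs (≈ 15 s on one CPU), which reproduces the qualitative behaviour
of the full-size default on this 4,000-cell problem; learning rate stays
at the default 1e-3 — larger steps were observed to sporadically kill
latent dimensions before their columns could establish.

## Known limitations

* Terms sharing many genes are only softly identifiable; the benchmark
  uses disjoint terms, and correlated term collections will spread one
  signal over several latent dimensions.
* The Bayes factor tests exceedance of score distributions, not effect
  size; with very large groups, tiny shifts can pass 2.3.
* The NB likelihood has no zero-inflation component; heavily
  zero-inflated protocols may inflate dispersion estimates instead.
* Condition embeddings added at query time are fit from the query alone;
  very small queries give noisy embeddings (the fine-tune epoch count is
  the only guard).
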