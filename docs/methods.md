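# Methods

This note records the models and procedures the package implements, the
conventions chosen where the literature leaves room, and what the
synthetic test bench does and does not establish.

## The classifier contract

All attribution code consumes a `ClassifierAdapter`: class probabilities
for (optionally patch-masked) inputs, and optionally per-layer attention
matrices and input gradients. Probabilities must sum to 1 within 1e-6;
attention matrices are head-averaged and row-stochastic within 1e-5.
Masking replaces every pixel of a dropped patch with a fill value
(default 0, black) before prediction, so the fully masked image is the
black image and an all-ones mask reproduces the unmasked prediction
bit-for-bit.

Two reference models satisfy the contract without external weights:

- **Linear patch scorer.** `s = Σ_i w_i · mean_intensity(patch i) + b`,
  class-1 probability through an identity or sigmoid link. Under the
  identity link the induced coalition game is additive, so exact Shapley
  values, integrated gradients and RISE conditional means all have
  closed forms; this model is the analytic oracle for most tests. An
  optional attention view (one layer, cls row = softmax of the per-patch
  contributions over a temperature) turns it into an attention-pooled
  scorer so rollout can run on it; the attention then reflects exactly
  the quantity the model computes.
- **Tiny vision transformer.** A pre-norm transformer (patch embedding,
  cls token, learned positions, multi-head self-attention + GELU MLP
  blocks, final layernorm, linear head) written in NumPy with
  hand-derived backpropagation. Gradients are exact — the test suite
  checks them against central finite differences (h = 1e-4) at 1e-3
  relative tolerance and observes ~1e-7 — and forward passes cache the
  post-softmax attention matrices, head-averaged per layer. Parameters
  are randomly initialised from a seed; the model is a structural
  stand-in for a trained ViT, not a competitive classifier.

## Attribution methods

**Attention rollout.** Scores are the cls row of `A_n ⋯ A_1` with the
cls column dropped. Heads are collapsed by arithmetic mean before
multiplying (the rollout literature's default; the choice is
configurable at the adapter level). The residual variant uses the
row-renormalised `A_l + I`, which for row-stochastic `A_l` equals
`½A_l + ½I`; matrices stay row-stochastic, so without residuals the full
(d+1)-token score vector sums to 1. A path-enumeration oracle (sum of
edge-weight products over all layered paths into cls) is implemented
separately and must agree with the matrix product to 1e-10; it is
guarded to small stacks because the path count grows geometrically.

**Integrated gradients.** Straight-line path from a black baseline,
midpoint-rule Riemann sum by default (left rule available; midpoint
converges faster), default 64 steps. The gradient target is the
pre-softmax class logit: probability gradients vanish under softmax
saturation, which makes the method numerically fragile; probability
targeting remains available. Pixel attributions are aggregated to
patches by signed sum over the patch's pixels and channels. On linear
models the method is exact at any step count; on the tiny transformer
the completeness residual falls from ~0.5 to ~7e-4 (in logit units)
across an 8 → 64 → 512 step sweep. Convergence need not be monotone at
very small step counts — the integrand is rough near the black baseline,
where layernorm amplifies small inputs — so the diagnostic sweep uses
8/64/512.

**RISE.** Masks act at patch (token) resolution — no low-resolution
upsampling or random shifting, since the attribution unit here *is* the
transformer patch. Two mask laws: independent Bernoulli(p), p = 0.5 by
default, and uniform cardinality (k uniform on {0..d}, then a uniform
k-subset). Scores are normalised by the *empirical* inclusion counts
`Σ m_i`, the unbiased conditional-mean estimator; a patch that no
sampled mask includes is an error unless an explicit zero-score
fallback is enabled. Evaluation is chunked for memory, with per-mask
values collected and reduced once so results are bitwise independent of
the chunk size. Default budget 4000 masks per image; the exact `2^d`
enumeration is available for d ≤ 14 and anchors the Monte-Carlo tests
at 3 standard errors.

**Shapley.** The enumeration path is guarded to d ≤ 14 (2^d game
queries). The regression path solves the constrained weighted least
squares by closed-form KKT elimination rather than projected SGD — one
linear solve, no tuning — and raises on rank-deficient designs;
projected descent survives inside the explainer training loop, which
mirrors the amortised formulation: masks drawn from the Shapley kernel
each step, additive efficient normalisation applied inside every
forward pass (its Jacobian `I − 11ᵀ/d` is part of the gradient), Adam
updates, and a per-epoch loss trace. The packaged explainer is a
per-patch affine map over singleton coalition values `v(e_i)` — big
enough to recover additive games exactly, small enough to train in
seconds; full-scale explainer training is out of scope. The kernel and
the surrogate mask law are normalised with exact rational arithmetic;
both sum to 1 over the full mask space by construction (verified by
enumeration to d = 12). Masked evaluation uses fill-0 masking unless a
surrogate-style adapter is substituted.

## Metrics and statistics

Curves are evaluated at every step 0..d and integrated by the trapezoid
rule over the *normalised* patch fraction, so AUCs are comparable across
grid sizes. Rankings break score ties by ascending patch index
(deterministic, recorded). The insertion curve's first point and the
deletion curve's last point are the same fully-masked evaluation, and
conversely for the full image — asserted bitwise. Aggregation offers the
grand mean over patch AUCs and the mean of per-slide means (slides
equally weighted regardless of patch counts); the two differ exactly
when slides contribute unequal patch counts. Method populations are
compared with two-sided Welch (unequal-variance) t-tests, no
multiplicity correction; two zero-variance samples with equal means
report p = 1, with unequal means p = 0.

## Preprocessing

Tissue is located by the per-pixel colorization value
`c = |r−m| + |g−m| + |b−m|`, `m = (r+g+b)/3` — zero exactly on grey,
invariant to channel permutation and common shifts — followed by either
a fixed threshold (deterministic, used in tests) or a local-mean
adaptive threshold with window (odd, default 51) and offset *added to*
the local mean (default 0). The adaptive mode is meaningful when the
window is large relative to tissue features; on flat synthetic colour
fields it degenerates, which is why exact-recovery tests use the fixed
mode. Tiling is non-overlapping and row-major with partial edge tiles
dropped; a tile is kept when its tissue fraction reaches
`min_tissue_fraction` (default 0.1 — the acceptance rule for partially
filled tiles is a package convention, not an upstream claim). Inputs
are assumed to be at working magnification already.

## Synthetic data

The generator emulates one property of H&E slides that the methods
actually exercise: a chromatic contrast between stained tissue and
near-grey background, plus a planted set of "tumor" patches with a
distinct colour (purple-dominant, and darker in mean intensity than the
pink normal tissue, so an intensity-weighted model can genuinely prefer
them). Per-pixel Gaussian colour noise (σ = 0.02 by default) is small
enough that colorization separation holds with margin; zero-noise
slides separate exactly. It does **not** model nuclear morphology,
stain variation, texture, or inter-patch correlation — so passing tests
demonstrate the correctness of the attribution and metric machinery,
not performance on real histology.

The planted-signal benchmark explains an *idealised tumor-recognising
classifier*: a sigmoid-link patch scorer whose weights are large on
tumor patches (3.0), small on normal tissue (0.5) and zero on
background, with the sigmoid centred halfway between the empty and full
coalitions. Its true per-patch dependence is known by construction,
which is the point: attribution methods are scored on recovering it
(top-k precision over the planted patches, insertion/deletion against
a random-ranking baseline). The default benchmark grid is 3×4 (d = 12)
so the exact-Shapley reference stays inside its enumeration guard, with
a handful of slides/images per run — sizes chosen so the whole protocol,
including the 2^d enumerations, runs in seconds.

## Numerical conventions and edge cases

- All randomness flows through integer seeds into
  `numpy.random.default_rng`; per-image, per-method seeds in the
  pipeline are derived by hashing the identifiers so cells are
  independent yet reproducible.
- Heatmaps min-max normalise scores per image onto a blue→red diverging
  colormap at patch resolution and alpha-blend over the image; a
  constant map renders at the colormap midpoint, and affine (positive
  scale) score transforms render identically. Raw scores are always
  exported unnormalised.
- Identity-link scorers report `[1−s, s]` as "probabilities"; callers
  keep `s` in [0, 1] where probability semantics matter (the additive
  oracles rely on the identity link's exactness, not its calibration).
- Degenerate inputs raise typed errors: mismatched mask lengths and
  non-permutation rankings (`InputError`), missing adapter capabilities
  (`CapabilityError`), enumeration beyond the guard (`SizeError`),
  rank-deficient regression designs (`SolverError`), non-finite
  training losses (`TrainingError`).

## Known limitations

- The tiny transformer is randomly initialised; qualitative claims
  about what *trained* ViTs attend to cannot be read off it.
- Exact Shapley and exact RISE scale as 2^d and are guarded; beyond the
  guard only the regression/explainer and Monte-Carlo paths apply.
- The amortised explainer is per-patch affine and trained on additive
  games; it demonstrates the training objective and the normalisation
  constraint, not the capacity of a deep explainer.
- Insertion/deletion inherit the usual caveats of removal-based
  evaluation: they presuppose masking semantics, ignore inter-patch
  correlation, and depend on the model's robustness to masked inputs.
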