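# Methods

This note documents the model, the synthetic study conditions, and the
numerical and design choices behind `udil`, in enough detail to judge what
the package's tests do and do not establish.

## Model

**Evidential head.** The classifier maps a feature vector through a small
fully-connected extractor `F` (default d → 64 → 32, tanh on every layer,
including the output layer so embeddings live in the bounded cube) and a
linear head `C` (32 → K, K = 2). Raw scores become evidence through a
numerically stabilized softplus, `e = log(1 + exp(z))`: smooth, strictly
positive gradient everywhere (no dead zones). Dirichlet algebra:
`α = e + 1`, `S = Σα`, `p̂ = α/S`, `u = K/S`. Predicted label is the
arg-max of `p̂` with ties broken toward the control class h — a
deliberate, conservative screening convention.

The head is **zero-initialized** and trained with decoupled weight decay
(default 3.0 × learning rate per step, head weights only). Both choices
serve the same purpose: evidence-readout directions should exist only where
training data sustains them. With a randomly initialized or undecayed head,
embedding directions never visited by training data carry arbitrary frozen
readout weights, and strongly shifted inputs can receive large spurious
evidence; decay continuously prunes unsupported components, so unfamiliar
embeddings read out little evidence and `u` rises. This is what makes the
uncertainty usable for out-of-distribution detection at this scale.

**Losses.** The classification loss is the Dirichlet-expected
cross-entropy `Σ_k y_k [ψ(S) − ψ(α_k)]` plus the annealed KL regularizer
`λ_t KL(Dir(α̃) ‖ Dir(1))`, `λ_t = min(1, t/E)`, E = 10 epochs by default.
Two documented choices:

- *KL closed form.* The standard closed form
  `logΓ(S) − Σ logΓ(α_k) − logΓ(K) + Σ(α_k − 1)(ψ(α_k) − ψ(S))` is the
  default (`kl_form="standard"`); it is non-negative with a unique zero at
  α = 1. An alternative published rendering that omits the
  `−Σ logΓ(α_k)` term is retained behind `kl_form="as_printed"` for
  auditability; it is not guaranteed non-negative and is not used by
  default.
- *True-class masking.* By default the KL acts on
  `α̃ = y + (1 − y)⊙α` (`kl_mask_true_class=True`): only misleading
  evidence is shrunk, the convention of the original evidential-learning
  literature. The unmasked alternative has an analytically fixed
  equilibrium — the gradient of ACE + KL vanishes at `α_true = 2`
  regardless of the data, pinning in-distribution uncertainty at
  `u ≈ 2/3` for K = 2 — which removes the confidence contrast between
  familiar and unfamiliar inputs that the whole framework relies on. We
  verified both the algebra and the empirical behaviour; masking restores
  in-distribution uncertainty near 0.3 with the defaults.

All digamma/log-gamma/trigamma evaluations use the scipy special
functions. Analytic gradients (loss → α → softplus → both networks) are
verified against central finite differences at 1e−4 relative tolerance.

**Divergence and thresholds.** The per-sample divergence between current
and historical predictions is the symmetrized KL
`½[KL(p‖q) + KL(q‖p)]` on ε-clipped (ε = 1e−8), renormalized expected
probabilities; the bounded mixture-based Jensen–Shannon variant is
available (`divergence="js_mixture"`). Thresholds use the population
standard deviation; a class with fewer than two contributing records gets
σ = 0 (τ = μ), and a class with no *reliable* records falls back to all
its records. Reliability is `u` strictly below the class-wise 0.9 quantile
(or an absolute `u_max`). Sensitivity coefficients default to 0.5 per
class; a pooled global-threshold mode and fixed-τ mode exist for ablation.
Thresholds are recomputed at the start of every epoch on the full training
split in no-gradient mode; gradient steps within the epoch use that fixed
partition, avoiding intra-epoch feedback.

**Alignment.** The MMD² estimator is the V-statistic (self-pairs
included), non-negative for the Gaussian RBF kernel; the unbiased
U-statistic is available behind a flag. Bandwidth defaults to the median
heuristic (σ² = median nonzero pairwise squared distance / 2) computed per
call on the union of the two sets and treated as a constant in the
gradient (standard practice; finite-difference tests therefore use a
fixed-σ kernel). Degenerate partitions — either set below
`min_set_size = 2` — skip the term and log the skip.

Two alignment choices differ from the most literal reading of the
printed equations, both adopted after measuring the alternatives:

- *Class-wise alignment* (`classwise_mmd=True`, default): similar and
  dissimilar sets are aligned within each class and averaged. Aligning the
  pooled unions couples the class composition of the two sets; under
  imbalance the minority cluster is attracted toward the majority, which
  in our experiments *increased* forgetting beyond naive fine-tuning.
  The pooled form remains available (`classwise_mmd=False`).
- *Historical anchor* (`align_target="historical"`, default): the
  domain-similar set enters the MMD through the frozen snapshot's
  embeddings — they are precisely the surrogate for the prior domain's
  feature distribution — and only the dissimilar samples' current
  embeddings receive gradient. This pulls drifting samples back toward
  the historical representation. The symmetric current-vs-current form
  (`align_target="current"`) is retained; in our experiments it was
  approximately neutral for forgetting, while the anchor gives a
  consistent reduction.

**Trainer.** Adam (β = 0.9/0.999), learning rate 1e−3, batch size 32,
50 epochs per domain; the classifier is carried across domains (one
classifier serves the current and historical prediction paths); the
extractor continues from its previous state and its snapshot is immutable
for the stage. One global seed drives initialization, shuffling and data
generation; runs are bit-reproducible. Every step logs EDL, MMD, λ and
total, and the identity `total = EDL + λ·MMD` is asserted in tests.

## Synthetic study conditions

The generator emulates the *feature-space* structure of small clinical
screening corpora — nothing lexical. Each domain is a two-component
Gaussian: controls at `mean_shift`, cases at
`mean_shift + class_separation · v` (`v` a fixed unit discriminant,
optionally rotated per domain), isotropic covariance `scale · I`.

The default stream (`default_paper_like_stream`): four domains of 160
samples in d = 16, positive fractions (0.33, 0.30, 0.20, 0.35) — the
20–35 % minority prevalence of small depression corpora — class
separation 2.0 (overlapping classes; Bayes error ≈ 16 %), and translation
norms (0, 1.5, 3.0, 4.5) along rotating axis-pair directions. Escalating
translations orthogonal-ish to the discriminant produce forgetting of the
kind alignment can mitigate; we verified that translations *along* the
discriminant instead produce severity-calibration (bias) drift, which
feature alignment cannot counter and can worsen.

The held-out OOD domain models a strongly different acquisition
population, not extreme cases or controls: its translation (norm 13.5,
≥ 3× the largest training shift) is orthogonal to the discriminant, its
center projects onto the discriminant at the class midpoint, its
case/control axis is rotated into new feature directions, and its
covariance is much broader than a training domain's (σ ≈ 13.5). The broad
covariance matters: a compact far-shifted cluster maps to a single
saturated activation pattern whose evidence readout is an arbitrary
function of initialization, whereas a heterogeneous population samples
many off-manifold directions and its mean uncertainty reflects the
evidence surface rather than one lottery draw. The OOD domain is
evaluation-only and never split.

Per-domain seeds derive from `(master_seed, domain_index)`, so appending a
domain never changes earlier domains. Train/test splits are stratified by
label (test fraction 0.25).

**What the generator does not emulate:** real transcript embeddings are
not Gaussian, inter-corpus shift is not a pure translation, and corpus
size/prevalence co-vary with collection protocol in ways no four-knob
model captures. Passing tests therefore establish that the machinery
behaves as designed under controlled covariate shift — not that it will
reduce forgetting on any particular clinical corpus pair.

## What the tests establish

- Closed-form exactness of the losses (digamma recurrences; Monte-Carlo
  Dirichlet-KL oracle at 10⁶ draws), the threshold rule and the
  partitions; brute-force oracles for the RBF kernel, median bandwidth,
  MMD² (four-loop), AUROC (pairwise) and confusion metrics.
- Finite-difference gradient integrity of every trained path.
- Snapshot immutability, single-classifier sharing, loss-ledger identity,
  bit-reproducibility under a fixed seed.
- End-to-end, at the default conditions (ten seeds, 160 samples/domain,
  50 epochs/domain): median first-domain forgetting of the method is below
  naive sequential fine-tuning (≈ 11 vs ≈ 14 F1 percentage points), mean
  uncertainty is higher on the held-out population than on trained test
  sets in ≥ 9/10 seeds, and uncertainty-ranking AUROC exceeds 0.5 in every
  seed. These margins are real but modest; they are medians over seeds,
  not per-seed guarantees.

## Known limitations

- The trade-off curve in λ is flat-to-monotone at this scale: with the
  historical anchor, λ = 5 does not yet degrade final mean F1 relative to
  λ = 0.5 (the MMD term is bounded and its gradient vanishes as the sets
  converge), so the package does not claim an inverted-U in λ; λ = 0.5 is
  kept as the default trade-off.
- Out-of-distribution separation via `u = K/S` on a plain MLP is
  inherently fragile for inputs far outside the training envelope; the
  zero-init + weight-decay head mitigates but does not eliminate
  seed-level variance (one seed in ten typically shows no mean-uncertainty
  gap).
- Multiclass (K > 2) is supported structurally in the evidential algebra
  but not exercised by thresholds, alignment or the trainer.
- The transcript-encoder adapter is an interface contract only; the tested
  core consumes feature tables.
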