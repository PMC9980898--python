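# Methods

This package compares a connectome-specific convolutional network against
classical linear and kernel models for predicting phenotypes (sex, age, a
cognitive g-factor, a mental-health questionnaire factor) from weighted
structural connectomes. Because cohorts of this kind are access-restricted,
every stage is exercised end-to-end on synthetic cohorts with planted,
recoverable effect structure: the generator is first-class, tested code,
and the planted truth is the arbiter for every downstream claim.

## Synthetic cohorts (`synth`)

A cohort is a stack of per-subject, per-modality symmetric non-negative
adjacency matrices with zero diagonal, plus a phenotype table.

**Edge structure.** A deterministic, atlas-like template per node count
(`edge_template`) splits nodes into two hemisphere-like blocks and labels
each upper-triangle edge *core* (denser within blocks, per-subject presence
probability 0.95) or *peripheral* (presence probability uniform on a small
interval). The mixture is solved so the expected raw density matches the
target (default 0.68, the regime of tractography networks before
thresholding) while approximately the core fraction (~0.60) survives a
2/3-of-subjects proportional threshold. Planted sparse effects are placed
on core edges so that thresholding cannot erase them.

**Edge weights.** Subject-level weights are

```
w = base_template × subject_noise × exp(gain · β_scale · head_z)
      × exp(sex_eff · sex_c + age_eff · age_z + g_eff · g + p_eff · p)
```

masked by per-subject presence. The streamline-count (SC) base template is
log-normal (log-scale sd ≈ 1.0, giving pooled-edge skewness near 8, the
heavy-tail regime of streamline counts); the other weightings (FA, MD, OD,
ISOVF, ICVF) use truncated-normal templates within their physical ranges.
Multiplicative effects keep weights non-negative by construction. The
head-size confound is a global multiplicative scale, much stronger for SC
(`confound_gain` 1.0) than for the microstructural weightings (0.25),
mirroring the larger head-size susceptibility of streamline counts.

**Phenotypes.** Sex is Bernoulli(1/2); age uniform on 45–78.5 years;
head size log-normal. Latent g and p are standard normal and independent
unless an age-mediated confound is requested (`age_g_confound` c makes
g = −c·age_z + √(1−c²)·noise). Four task scores are `loading_j · g +
noise`; the default loadings follow the classic cognitive-battery sign
pattern (verbal reasoning +, reaction time −, pairs matching −, prospective
memory +) and the default noise sd of 1.6 puts the battery's first-PC
explained variance near 0.34 (analytic one-factor calculation with those
loadings). Fourteen binary questionnaire items follow a one-factor
threshold model with standardized loadings 0.7 (latent inter-item
correlation 0.49, hence first-PC explained variance ≈ 0.53) and random
per-item prevalences in 0.15–0.5; missingness is planted completely at
random (the mechanism is a modelling choice — real missingness mechanisms
are unknown).

**What the generator does not emulate**: spatial autocorrelation between
neighbouring edges, site/scanner batch effects, non-MCAR missingness,
heteroscedastic age effects, and any anatomical meaning of node labels.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the stated generative model, not performance claims
about real cohorts.

## Preprocessing (`preprocess`)

Pipeline order is fixed: symmetrize (`(A + Aᵀ)/2`, zero diagonal) → group
proportional threshold (keep edges with weight > 0 in ≥ 2/3 of subjects,
inclusive comparison; the mask is computed on training subjects only, a
conservative anti-leakage choice) → per-subject maximum-value
normalization (divide by the matrix's own maximum, removing global scale
and with it most of the head-size confound). Features are the strictly
upper-triangular entries in row-major order — the single canonical edge
order used by every linear model, beta map and gradient comparison.

## Latent factors (`factors`)

*g-factor*: first unrotated principal component of the covariance of
z-scored task scores; per-subject scores are the loading-weighted sum of
z-scored tasks, z-normalized on training statistics. Sign anchored so the
first (verbal-reasoning-like) task loads positively.

*MHQ-factor*: PCA of the pairwise polychoric correlation matrix of the
ordinal items. The polychoric estimator is two-step (thresholds from
inverse-normal marginal cumulative frequencies, then the latent correlation
by maximizing the bivariate-normal cell likelihood on [−0.999, 0.999]) —
standard, stable and testable, rather than joint maximum likelihood. A
non-PSD polychoric matrix is repaired by eigenvalue clipping with a
warning. Component scores from ordinal data are not uniquely defined; we
score linearly in z-scored numeric item codes, a documented approximation.
Sign anchored so the largest-|loading| item loads positively.

Subjects with ≥ 3 missing items are dropped (the inclusion rule retains
"fewer than three"); remaining holes are imputed by regularized iterative
PCA (2 components, tolerance 1e−6, up to 500 sweeps): alternate a shrunk
truncated-SVD reconstruction of the centered table with re-imputation of
only the missing cells. Retained singular values are shrunk by the mean
residual variance plus a small constant floor ((0.01·s₁)²); the floor
breaks ties among exact-fit completions of rank-deficient tables toward
the minimal-norm one, which plain EM-PCA does not do. Imputation precedes
the polychoric computation (the alternative order is not better
identified). All factor fitting touches training rows only; models
serialize to JSON with every normalization constant needed to score unseen
subjects.

## The connectome CNN (`dlmodel`)

Implemented in NumPy with explicit forward and backward passes (no
autodiff framework), which makes the input-space gradients consumed by the
attribution stage available in closed form and keeps training exactly
reproducible from a seed.

Layers: edge-to-edge (cross filter: output (i,j) is the weighted sum of
row i plus the weighted sum of column j, with independent learnt row and
column weight vectors per filter), edge-to-node (row filter only — the
column half adds nothing for symmetric inputs), node-to-graph (dense), then
an optional covariate concatenation and a dense head (2 logits for
classification, 1 unit for regression). Activations are leaky ReLU
(slope 0.33); dropout 0.5 after the edge-to-node activation. Default
filter counts (8 E2E, 16 E2N, 30 N2G units) are deliberately small —
larger nets overfit cohorts of this size — and are configuration, not a
claim.

Training: Adam with learning rate 1e−3, first- and second-moment decays
both 0.9, mini-batches of 128, up to 200 epochs. The validation metric
(accuracy for classification, Pearson correlation for regression) is
evaluated once per epoch and the best epoch's weights are kept; ties keep
the earlier epoch. Regression targets are z-scored on training-fold
statistics inside the harness and predictions mapped back. Covariates
(age, sex) are z-scored on training statistics before concatenation, for
scale parity with the node-to-graph activations. Determinism holds for a
fixed seed and thread configuration; cross-platform bit-equality is not
promised.

## Classical baselines (`linear`)

Ridge regression is solved exactly (primal or dual depending on n vs p;
intercept unpenalized via centering). Logistic ridge/lasso, the lasso, and
the linear SVMs are fitted by scikit-learn with the package's summed-loss
λ convention mapped onto the corresponding C/alpha parameters (documented
in the module). The support-vector regression tube is IQR(y)/13.49 — a
robust-sd/10 rule; the divisor is configurable since only "estimated from
the interquartile range" is specified. Kernel ridge regression is solved
in the dual, (K + λI)α = y, with K the Pearson correlation between
subjects' edge vectors; the standard dual predictor y′ = Σ αᵢK(xᵢ, x′) is
used. λ is chosen per CV fold by exhaustive evaluation of a 300-value
log-spaced grid (1e−6..1e−1) on the fold's validation split; ties favour
the larger λ (parsimony under equal validation performance).

## Attribution (`attribution`)

The saliency map is the mean over a subject set (the held-out test set by
default — it reflects what drives held-out predictions) of ∂(target
output)/∂(input edge weight), with the target being the positive-class
logit (not the probability; logit gradients are better scaled) or the
regression output. Because row and column filter weights are trained
independently, raw maps are asymmetric; each is summed with its transpose,
then maps are averaged across repetitions × folds. Node predictive power
is the signed sum of a node's edge gradients, node importance the absolute
sum (importance ≥ |power| by the triangle inequality). Edge-gradient
kurtosis is reported in the Pearson (non-excess) convention, normal = 3.

## Harness (`pipeline`)

Subjects are sorted by id; the first 15% are held out as the test set; the
remainder is permuted (seeded) into 5 folds reused verbatim across
modalities and models. Tasks with per-subject availability (the
questionnaire factor) partition within their own available subjects.
Anti-leakage: threshold masks, factor models, covariate z-scoring and λ
selection never see test subjects. Classical metrics reproduce bit-exactly
on re-run; deep metrics are seed-deterministic.

The reference benchmark conditions (`benchmark_cohort`/`benchmark_config`)
are 400 subjects × 16 nodes, sparse sex effects (0.8 log-units on 20 core
edges), sparse age effects (0.15 log-units — small enough that the
multiplicative model is within ~2% of its linear expansion, the regime in
which a linear model and the CNN face the same problem), a diffuse weak g
effect, an age-mediated confound on g (c = 0.6), 3 random initializations
× 5 folds at up to 150 epochs. These sizes keep a full run in minutes on
one CPU while leaving all planted structure comfortably recoverable; they
are the package's desk-scale stand-in for a cohort three orders of
magnitude larger.

## Known limitations

- The polychoric estimator assumes an underlying bivariate normal; heavy
  violation (or many empty contingency cells) degrades it, and a warning
  is raised in the empty-cell case.
- The CNN training loop is plain NumPy: fine at desk scale, not intended
  for 85-node × 10⁴-subject cohorts without a faster backend.
- Gradient maps at desk scale are noisier than betas across folds
  (cross-fold map correlations ~0.4–0.6 vs ~0.7+ for betas), consistent
  with the stochasticity of network training; averaging across runs is
  what makes them usable.
- No statistical significance testing between models is performed.
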