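# connectomepred

Phenotype prediction from weighted structural connectomes: a
connectome-specific convolutional network (BrainNetCNN-style) compared
head-to-head with classical linear and kernel models — ridge, LASSO,
linear SVM and Pearson-kernel ridge regression — under one shared
cross-validation plan, with gradient-attribution maps, node importance
scores and model-concordance analyses.

The package is aimed at researchers who want to (a) test whether
topology-aware deep models beat well-tuned linear baselines on
connectome-based prediction of sex, age, general cognitive ability
(g-factor) and a general mental-health factor, and (b) interrogate *what*
the models use, via saliency maps and their agreement with linear betas.
Because real cohorts of this kind are access-restricted, the package ships
a first-class synthetic-cohort generator that plants known edge effects,
latent-factor loadings and confounds — so every pipeline stage has a
recoverable ground truth.

## The models

**Connectome CNN.** Weighted adjacency matrices A (symmetric, zero
diagonal, max-normalized) pass through topology-aware layers:

- *edge-to-edge* (E2E): a cross-shaped filter,
  `out[i,j] = Σ_f ( A[f]_{i,·} · w_r^{f} + A[f]_{·,j} · w_c^{f} )`,
  with independently learnt row/column weight vectors per filter;
- *edge-to-node* (E2N): the row-filter half, collapsing each node's edges
  to a node feature;
- *node-to-graph* (N2G): a dense collapse to a graph representation,
  optionally concatenated with z-scored covariates (age, sex), then a
  dense head (2 logits or 1 unit).

Training: Adam (lr 1e−3, decays 0.9/0.9), batches of 128, up to 200
epochs, keeping the best-validation-epoch weights. Implemented in NumPy
with explicit backprop, so input-space gradients for attribution are exact.

**Classical baselines** on the vectorized upper triangle
(n(n−1)/2 edge features): ridge `min ‖y−Xβ‖² + λβᵀβ` (and the logistic
analogue), LASSO `…+ λ‖β‖₁`, linear SVM (hinge / ε-insensitive with
ε = IQR(y)/13.49), and kernel ridge regression in the dual,
`(K + λI)α = y`, with K the Pearson correlation between subjects' edge
vectors. λ is selected per CV fold from 300 log-spaced values in
[1e−6, 1e−1].

**Attribution.** Saliency maps `∂(output)/∂A_{ij}` averaged over test
subjects, symmetrized (G + Gᵀ) and averaged over repetitions × folds;
node *predictive power* (signed row sum) and *importance* (absolute row
sum); Spearman concordance with ridge betas and top-k node overlap.

## Worked example

```python
import connectomepred as cp

# 400 subjects, 16 nodes, planted sex/age/g effects + age->g confound
cohort = cp.pipeline.benchmark_cohort(seed=11)
config = cp.pipeline.benchmark_config(seed=0)   # CNN + ridge, 3 reps x 5 folds
result = cp.run_experiment(cohort, config)
print(result.metrics[["task", "model", "accuracy", "r"]])
print(result.consistency["gradient_beta_spearman"])
```

Output from this exact run:

```
  task        model   accuracy         r
0  sex  brainnetcnn  96.000000       NaN
1  sex        ridge  97.666667       NaN
2  age  brainnetcnn        NaN  0.746709
3  age        ridge        NaN  0.719331
4    g  brainnetcnn        NaN  0.608696
5    g        ridge        NaN  0.602703
...
{'sex/SC': 0.731, 'age/SC': 0.689, 'g/SC': 0.583, 'g/SC/cov': 0.627}
```

Reading it: with near-linear planted effects the CNN and ridge land within
~2 accuracy points / ~0.03 correlation of each other on every task — the
topology-aware network buys nothing over a linear model in a linear world,
which is the meaningful null for real-data comparisons. The Spearman
values say the CNN's averaged gradient map ranks edges much like the ridge
betas do (and `result.consistency["covariate_effect"]` shows that adding
age/sex covariates to the g model shrinks the correlation between its
gradient map and the age map — the planted age-mediated confound being
absorbed by the covariates instead of the connectome weights).

Generate a cohort on disk from the shell:

```bash
python -m connectomepred simulate --n-subjects 200 --n-nodes 16 \
    --modalities SC,FA --seed 1 --out cohort/
```

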