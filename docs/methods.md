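# Methods

## Model

`discell` fits a generative model of a cells × features expression matrix in
which each cell's identity is decomposed into latent codes for its *known*
attributes plus one code for everything else.

**Decomposed latent space.** Each categorical attribute owns an embedding
table with one row per category; a cell's code is its category's row, so the
code is shared exactly across cells with the same label. Each ordered
attribute (a numeric vector of fixed dimension — a dose, a precomputed
chemical or gene-ontology-derived perturbation embedding treated as an
opaque vector) owns an encoder MLP mapping the vector to a latent code, so
similarity structure in the features survives into the latent space. The
*unknown-attribute* code `z_u` is a per-cell free parameter optimized
directly by the training loop (latent optimization). There is no amortized
encoder from expression to `z_u` by design: a freshly initialized free code
carries no information about the known attributes, whereas an encoder output
would, and keeping unwanted information out of `z_u` is easier than removing
it later. `z_u` is initialized at zero to make "no information at step 0"
literal.

**Generator.** A decoder MLP consumes the concatenation of all codes and
emits the parameters of a per-feature distribution:

- `gaussian` — mean head plus a learned per-feature log-variance; intended
  for log-normalized input.
- `poisson` / `zinb` — the mean decomposes as observed library size ×
  softmax-normalized feature proportions; `zinb` adds a learned per-feature
  inverse-dispersion θ (shared across cells) and a per-entry zero-inflation
  logit head. Intended for raw counts. Whether dispersion should be
  per-feature or per-entry is an open choice; per-feature is the standard
  count-decoder convention and keeps the parameter count at M.

**Objective.**

```
L        = L_cmp + L_min              (+ L_cls when semi-supervised)
L_cmp    = NLL(x | G_theta) + tau * MSE(x, mu_theta)
L_min    = lambda * ||z_u||^2
```

The NLL is the exact per-cell log density summed over features. The MSE term
directly supervises the predicted means regardless of family; for count
families both sides are log1p-transformed before squaring (raw-scale MSE
would be dominated by the few highest-expressed features), for Gaussian data
raw values are compared, and the result is averaged over features. During
training, Gaussian noise `eta ~ N(0, sigma^2 I)` is added to `z_u` (only to
`z_u`, and never at inference or counterfactual time — the noise is a
regularizer, and generation conditions on the learned code).

## Parameters that matter

| parameter | default | meaning / why |
|---|---|---|
| `n_latent_attr` | 32 | latent dim per known attribute; stable at desk scale |
| `n_latent_u` | 32 | unknown-code dim; must cover nuisance structure |
| `encoder_depth/width` | 2 / 256 | ordered-attribute MLP size |
| `decoder_depth/width` | 2 / 256 | generator trunk size |
| `sigma` | 1.0 | unknown-code training-noise s.d.; a package choice — larger values push information out of `z_u` harder |
| `lambda_` | 0.1 | minimality weight; the sweep 0 → 10 shrinks median ‖z_u‖ monotonically |
| `tau` | 1.0 | MSE weight inside the completeness loss |
| `family` | `zinb` | likelihood; must match the declared layer kind |
| `lr` / `lr_embedding` | 1e-3 / 1e-2 | Adam rates; directly optimized embeddings converge too slowly at the network rate, so they get their own (higher) rate |

`sigma`, `tau` and the learning rates are deliberate package defaults, not
canonical values; all are exposed.

## Semi-supervised training

Attributes with missing labels get an auxiliary head on expression (log1p of
counts): a classifier for categorical attributes (cross-entropy on labeled
cells only) or a regressor for ordered ones (MSE on labeled cells only),
trained jointly with everything else. For an unlabeled cell the categorical
latent code is the classifier-probability-weighted mixture of category
embeddings. Soft mixing was chosen over hard argmax because it is
differentiable end-to-end and lets the generator's loss shape the classifier
through the mixture; hard completion is available behind
`completion="hard"`. The relative weight of `L_cls` defaults to 1 (an
unweighted sum), adjustable via `cls_weight`. Label imputation never
overwrites an observed label; ties break deterministically to the first
category in schema order.

## Downstream analyses

**Counterfactuals.** Reference cells keep their trained `z_u` and
unmanipulated codes bit-exactly; only manipulated attributes swap codes;
generation runs noise-free with the reference cells' observed library sizes.
An empty manipulation therefore reproduces the reconstruction exactly.
Unseen categorical targets are an error (generalization to unseen values is
only possible for ordered attributes, by construction). A composite ordered
manipulation (e.g. a two-gene perturbation when training saw one-gene
perturbations) is available as an additive mode: the predicted change is the
sum of the single-manipulation changes.

**Evaluation harness.** The default score is the coefficient of
determination r² between the *mean* predicted profile and the mean observed
profile over all features (the per-cell variant exists but is not the
default); NMSE is normalized by the error of predicting no perturbation
effect, so "no change" scores exactly 1. For count families both profiles
are log1p-transformed first — a package choice; the raw scale is available
via `log1p=False`.

**Feature–state association.** A dependent t test for paired samples per
feature, pairing each cell's observed expression with its own counterfactual
mean (deterministic, not a sampled draw), Benjamini–Hochberg adjusted across
features. Zero-variance difference vectors are flagged and assigned p = 1
rather than dropped, keeping the table aligned with the feature axis.

**k-NN uncertainty.** `u_i = H(C_{N_i}) * sum_{j in N_i} 1 / log d(i, j)`
with natural-log Shannon entropy over the covariate values of the k nearest
neighbors (self excluded). The entropy factor does not depend on j, so it is
implemented factored out of the sum. Three numerical completions are made
explicit and exposed as options: Euclidean distance, natural log, and a
distance clamp at `1 + 1e-6` (1/log d diverges or flips sign for d ≤ 1;
coincident points would otherwise produce infinities). Embeddings are
per-dimension z-scored before distances by default. The measure is *not*
normalized by k. Neighbor search uses exact pairwise distances with a stable
argsort so results match a brute-force implementation exactly.

## Synthetic data

The generator emulates what the model assumes: per-cell log-mean =
feature baseline (N(0,1)) + per-attribute additive effects on declared
target-feature blocks + low-rank Gaussian nuisance (rank 4 by default) that
no known attribute explains — precisely the structure `z_u` should absorb.
Categorical effects are random-sign patterns of a given magnitude per
non-reference class; ordered attributes act linearly in log-mean (a monotone
dose response), making generalization to unseen doses testable. Counts are
drawn per family after softmax normalization and log-normal library-size
scaling (ZINB: gamma–Poisson with per-dataset θ plus independent dropout).

Default conditions: 2,000 cells × 200 features; a 3-class cell type
(effect 1.0 natural-log units, first 20% of features), a 2-class status
(0.8, next 10%), a 1-D dose on the grid {0, 0.25, 0.5, 0.75, 1.0} (slope
0.6, next 10%); library ~ LogNormal(log 2000, 0.3); θ = 10, 5% zero
inflation. Effects of 0.5–1.0 log units are on the strong end of real
perturbation responses; what passing recovery tests show is that the
*mechanics* of disentanglement, counterfactual routing and imputation work,
not that the model would reach the same scores on real atlases, which have
correlated gene programs, batch structure and much weaker effects the
generator does not emulate.

## Study conditions used by the reported numbers

`scripts/acceptance.py` (and the acceptance tests) use: the default
conditions above with one (status=perturbed, dose=1.0) combination held out
of training (~10% of cells); 80 training epochs, batch 256; reference cells
are the control/dose-0 cells. The minimality sweep runs 600 × 80 at
λ ∈ {0, 10}; the semi-supervised run masks 50% of a separable 2-class
attribute on 1,000 × 100; association calibration uses 20 null replicates of
30 × 500 paired Gaussians. These sizes were chosen so a full reproduction
stays in the minutes range on one CPU while leaving the recovery margins
wide.

## Numerical choices and degenerate inputs

- Gradients come from a small reverse-mode autodiff core (`_autodiff.py`)
  over float64 numpy arrays, verified against central finite differences;
  Adam is the optimizer throughout.
- The ZINB log-pmf is computed in a softplus/lgamma form stable for extreme
  logits and means; the public `nll` evaluates the same graph the optimizer
  differentiates, so reported and optimized likelihoods cannot drift apart.
- Training is bit-reproducible for a fixed seed on a fixed platform: one
  seeded generator drives initialization, batching and noise.
- A missing `library_size` defaults to the observed per-cell count sum
  (deterministic and observable); `generate()` from a bare latent uses the
  mean training library.
- Non-finite losses abort with the epoch/batch; duplicate cell ids are
  rejected at load (ids key the per-cell embedding); categorical missing
  labels use a reserved sentinel, ordered missing values are all-NaN rows,
  and partially-NaN vectors are rejected rather than silently imputed.

## Known limitations

- No amortized inference: embedding an unseen cell requires an explicit
  optimization (`fit_new_cell_embedding`) with all networks frozen.
- Loss evaluation (`loss_components`) is defined over the training set;
  held-out likelihoods would require refitting `z_u` per held-out cell.
- The Gaussian family uses per-feature variance only; no mean–variance
  trend.
- CPU-only; at hundreds of thousands of cells the per-cell embedding table
  and full-batch epochs would need minibatched sparse updates this
  implementation does not attempt.
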