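# discell

Disentangled generative modeling of single-cell expression profiles for
counterfactual perturbation-response prediction.

Single-cell measurements confound many facets of cellular identity at once:
cell type, treatment and dose, infection status, spatial position, batch.
`discell` decomposes an expression matrix into one latent code per *known*
attribute plus a regularized per-cell code for everything the annotations do
not explain. Because the decomposition is additive in the latent space, a
trained model can answer counterfactual questions — *what would this control
cell's expression look like if it were infected? at a ten-fold higher dose?
under a drug it never saw in that context?* — and every predicted change is
attributable to the manipulated attribute.

## Model

Given a dataset $D = [(x_c, y_c)]_{c=1}^n$ of $M$-dimensional expression
profiles $x_c$ and $K$ known attribute values $y_c$:

* **categorical attributes** (cell line, infection status, spatial zone) are
  represented by an embedding table — the code $z_y$ is shared by all cells
  with the same label;
* **ordered attributes** (dosage, chemical or GO-derived perturbation
  features) pass through an encoder MLP (default depth 2, width 256), so
  similarity in the feature vector carries over to the latent space;
* **unknown attributes** get a per-cell code $z_u$ optimized directly as a
  parameter (*latent optimization* — there is deliberately no encoder from
  $x$ to $z_u$), initialized at zero so it literally starts with no
  information.

A decoder $G_\theta$ maps the concatenated codes to the parameters of a
per-feature expression distribution (Gaussian for log-normalized data,
zero-inflated negative binomial or Poisson for counts, with the mean
decomposed as library size × softmax-normalized proportions). Training
minimizes

$$\mathcal{L} \;=\; \underbrace{\mathrm{NLL}(x \mid G_\theta) + \tau\,
\mathrm{MSE}(x, \mu_\theta)}_{\text{completeness}\;\mathcal{L}_{cmp}}
\;+\; \underbrace{\lambda \lVert z_u \rVert^2}_{\text{minimality}\;\mathcal{L}_{min}}$$

with Gaussian noise $\eta \sim \mathcal{N}(0, \sigma^2 I)$ added to $z_u$
during training only. The noise and the activation penalty keep the unknown
code *minimal*, so known-attribute information routes through the attribute
codes instead of leaking into $z_u$ — the property that makes counterfactuals
meaningful.

With partially labeled attributes, a jointly trained classifier (or
regressor, for ordered attributes) on $x$ completes the latent
representation of unlabeled cells via a probability-weighted mixture of
category embeddings, adding a cross-entropy/MSE term
$\mathcal{L}_{cls}$ to the objective; after training it imputes the missing
labels.

Downstream utilities cover counterfactual prediction, an $r^2$/NMSE
evaluation harness against held-out conditions, per-feature paired
*t*-test association of features to a state (BH-adjusted, exportable as a
ranked table for enrichment tools), a k-NN uncertainty measure
$u_i = H(C_{\mathcal{N}_i}) \sum_{j\in\mathcal{N}_i} 1/\log d(i,j)$ over any
embedding, and latent-space export.

## Worked example

Simulate counts with planted effects, hold out one (status, dose)
combination entirely, train, and predict the held-out condition
counterfactually from control cells:

```python
import numpy as np
from discell import (SyntheticConfig, generate, DisentanglementModel, LatentSpec,
                     counterfactual_predict, evaluate_counterfactuals,
                     associate_features)

ds, gt = generate(SyntheticConfig(n=800, m=100, seed=0))
held_out = np.array([v == "perturbed" for v in ds.attribute_values["status"]]) \
    & (ds.attribute_values["dose"][:, 0] == 1.0)
train_ds, test_ds = ds.subset(~held_out), ds.subset(held_out)

spec = LatentSpec(n_latent_attr=16, n_latent_u=16, decoder_width=128)
results = DisentanglementModel(train_ds, spec).fit(epochs=80, batch_size=256,
                                                   seed=0)
print(results.summary())
```

```
Disentangled expression model
================================================================
cells: 722    features: 100    likelihood: zinb
latent dims: 16 per attribute, 16 unknown
sigma=1.0  lambda=0.1  tau=1.0  seed=0
----------------------------------------------------------------
attribute           kind          levels/dim
cell_type           categorical   3
status              categorical   2
dose                ordered       1
----------------------------------------------------------------
loss: epoch 0 total=483.5580 -> epoch 79 total=347.2774
final completeness=347.1672  minimality=0.1102
median ||z_u|| = 0.9865
```

```python
is_ref = np.array([v == "control" for v in train_ds.attribute_values["status"]]) \
    & (train_ds.attribute_values["dose"][:, 0] == 0.0)
reference = [c for c, m in zip(train_ds.cell_ids, is_ref) if m]
pred = counterfactual_predict(results, {"status": "perturbed", "dose": [1.0]},
                              reference=reference)
print(evaluate_counterfactuals(pred, test_ds, control=train_ds.subset(is_ref)))
```

```
{'n_pred': 80.0, 'n_truth': 78.0, 'r2': 0.971, 'r2_naive': 0.882, 'nmse': 0.247}
```

The model's counterfactual mean profile matches the held-out condition at
$r^2 = 0.97$, well above the naive control-profile baseline ($0.88$), and
its NMSE of 0.25 means it removes three quarters of the error a
"no perturbation effect" prediction would make. Pairing each control cell
with its own infected-state counterfactual and running the paired *t* test
ranks the truly perturbed features first:

```python
flip = counterfactual_predict(results, {"status": "perturbed"}, reference=reference)
table = associate_features(train_ds.subset(is_ref), flip)
print(table.sort_values("p_adjusted").head(3)[["feature", "statistic", "p_adjusted"]])
```

```
 feature  statistic   p_adjusted
gene0024  14.108464 2.727227e-21
gene0029  12.539774 8.807228e-19
gene0027  12.136322 3.250947e-18
```

All three are inside the planted target block (`gene0020`–`gene0029`).

A shell workflow with the same steps is available via the `discell` CLI
(`simulate`, `train`, `counterfactual`, `uncertainty`, `evaluate`); each
command writes a resolved config (seed included) alongside its artifacts.

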