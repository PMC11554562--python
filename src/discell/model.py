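"""Disentangled generative model of expression with latent optimization.

The model decomposes each cell's identity into one latent code per *known*
attribute (an embedding-table row for categorical attributes, an MLP encoding
for ordered attributes) plus a per-cell *unknown-attribute* code ``z_u`` that
is optimized directly as a parameter — latent optimization, no amortized
encoder.  A decoder network maps the concatenated codes to the parameters of
a per-feature expression distribution (Gaussian, Poisson or zero-inflated
negative binomial).

The training objective is

    L = L_cmp + L_min
    L_cmp = NLL(x | G_theta) + tau * MSE(x, mu_theta)
    L_min = lambda * ||z_u||^2

with additive Gaussian noise eta ~ N(0, sigma^2 I) injected into ``z_u``
during training only.  The noise and the activation penalty together keep the
unknown code minimal, so known-attribute information routes through the
attribute codes — the basis for counterfactual prediction.

Usage follows the statsmodels convention: construct a
:class:`DisentanglementModel` from a :class:`~discell.dataset.CellDataset`,
call :meth:`~DisentanglementModel.fit`, and work with the returned
:class:`DisentanglementResults`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._autodiff import MLP, Adam, Linear, Tensor, concat, logsumexp
from .dataset import RAW_COUNTS, CellDataset
from .likelihoods import (
    FAMILIES,
    GAUSSIAN,
    POISSON,
    ZINB,
    ExpressionDistribution,
    loglik_tensor,
)
from .schema import CATEGORICAL, ORDERED, AttributeSchema

__all__ = ["LatentSpec", "DecomposedLatent", "DisentanglementModel",
           "DisentanglementResults", "train"]


@dataclass
class LatentSpec:
    """Hyperparameters of the decomposed latent space and decoder.

    ``sigma`` is the standard deviation of the training-time noise added to
    the unknown code; ``lambda_`` weights the minimality penalty; ``tau``
    weights the auxiliary MSE on predicted means.  Encoder defaults follow
    the depth-2 / width-256 MLP convention; latent dimensions default to 32
    per attribute and 32 for the unknown code.
    """

    n_latent_attr: int = 32
    n_latent_u: int = 32
    encoder_depth: int = 2
    encoder_width: int = 256
    decoder_depth: int = 2
    decoder_width: int = 256
    sigma: float = 1.0
    lambda_: float = 0.1
    tau: float = 1.0
    family: str = ZINB

    def __post_init__(self):
        for name in ("n_latent_attr", "n_latent_u"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("encoder_depth", "decoder_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sigma", "lambda_", "tau"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")


@dataclass
class DecomposedLatent:
    """One latent code per known attribute plus the unknown-attribute code."""

    z_y: Dict[str, np.ndarray]
    z_u: np.ndarray
    noise_applied: bool = False

    def validate(self, schema: AttributeSchema):
        missing = [a.name for a in schema if a.name not in self.z_y]
        if missing:
            raise ValueError(f"latent is missing attribute codes for {missing}")
        extra = set(self.z_y) - set(schema.names)
        if extra:
            raise ValueError(f"latent has codes for undeclared attributes {sorted(extra)}")
        for name, z in self.z_y.items():
            if not np.all(np.isfinite(z)):
                raise ValueError(f"latent code for {name!r} is non-finite")
        if not np.all(np.isfinite(self.z_u)):
            raise ValueError("unknown-attribute code is non-finite")


class _Decoder:
    """Trunk of ReLU hidden layers plus family-specific heads."""

    def __init__(self, n_in: int, m: int, depth: int, width: int, family: str,
                 rng: np.random.Generator):
        self.family = family
        self.trunk: List[Linear] = []
        d = n_in
        for _ in range(depth):
            self.trunk.append(Linear(d, width, rng))
            d = width
        self.mean_head = Linear(d, m, rng)
        self.zi_head = Linear(d, m, rng) if family == ZINB else None
        # per-feature log inverse-dispersion (zinb) / log variance (gaussian)
        self.log_disp = Tensor(np.zeros(m), requires_grad=True) \
            if family in (ZINB, GAUSSIAN) else None

    def parameters(self):
        params = [p for layer in self.trunk for p in layer.parameters()]
        params += self.mean_head.parameters()
        if self.zi_head is not None:
            params += self.zi_head.parameters()
        if self.log_disp is not None:
            params.append(self.log_disp)
        return params

    def __call__(self, z: Tensor, library: Optional[Tensor]):
        h = z
        for layer in self.trunk:
            h = layer(h).relu()
        raw = self.mean_head(h)
        out = {}
        if self.family == GAUSSIAN:
            out["mu"] = raw
            out["var"] = self.log_disp.exp()
        else:
            # library-size x softmax-normalized feature proportions
            logp = raw - logsumexp(raw, axis=1, keepdims=True)
            out["mu"] = logp.exp() * library
            if self.family == ZINB:
                out["theta"] = self.log_disp.exp()
                out["zi"] = self.zi_head(h)
        return out


class DisentanglementModel:
    """Generative disentanglement model over a fully labeled dataset.

    Parameters
    ----------
    dataset
        Training cells; every known attribute must be fully labeled (use
        :class:`~discell.classify.SemiSupervisedDisentanglementModel` for
        partial labels).
    spec
        :class:`LatentSpec` hyperparameters (defaults used when omitted).
    """

    _allow_missing = False

    def __init__(self, dataset: CellDataset, spec: Optional[LatentSpec] = None):
        self.dataset = dataset
        self.schema = dataset.schema
        self.spec = spec if spec is not None else LatentSpec()
        if self.spec.family in (POISSON, ZINB):
            if dataset.layer_kind != RAW_COUNTS:
                raise ValueError(
                    f"{self.spec.family} expects a raw_counts layer; dataset "
                    f"declares {dataset.layer_kind!r}"
                )
            if np.any(dataset.x != np.round(dataset.x)):
                raise ValueError("count families require integer counts")
        if not self._allow_missing:
            for attr in self.schema:
                miss = dataset.is_missing(attr.name)
                if miss.any():
                    raise ValueError(
                        f"attribute {attr.name!r} has {int(miss.sum())} missing "
                        "labels; use SemiSupervisedDisentanglementModel"
                    )

    # -- construction helpers -------------------------------------------
    @classmethod
    def from_dataframe(cls, x: pd.DataFrame, attributes: pd.DataFrame,
                       schema: AttributeSchema, layer_kind: str = RAW_COUNTS,
                       spec: Optional[LatentSpec] = None) -> "DisentanglementModel":
        """Build from a features DataFrame (cells x features, index = cell id)
        and an attribute DataFrame aligned on the same index."""
        from .dataset import _parse_attribute_table

        cell_ids = list(map(str, x.index))
        vals = _parse_attribute_table(attributes, schema, cell_ids)
        ds = CellDataset(x=x.to_numpy(dtype=np.float64), schema=schema,
                         attribute_values=vals, cell_ids=cell_ids,
                         feature_names=list(map(str, x.columns)),
                         layer_kind=layer_kind)
        return cls(ds, spec=spec)

    def _init_params(self, rng: np.random.Generator):
        spec, ds = self.spec, self.dataset
        params = {}
        # categorical embedding tables: small-scale Gaussian init
        params["cat_tables"] = {
            a.name: Tensor(rng.normal(0.0, 0.1, size=(a.n_categories, spec.n_latent_attr)),
                           requires_grad=True)
            for a in self.schema if a.kind == CATEGORICAL
        }
        params["ord_encoders"] = {
            a.name: MLP(a.dim, spec.n_latent_attr, spec.encoder_depth,
                        spec.encoder_width, rng)
            for a in self.schema if a.kind == ORDERED
        }
        # latent optimization: zero init literally encodes "no information"
        params["u_table"] = Tensor(np.zeros((ds.n, spec.n_latent_u)), requires_grad=True)
        n_in = spec.n_latent_attr * self.schema.K + spec.n_latent_u
        params["decoder"] = _Decoder(n_in, ds.m, spec.decoder_depth,
                                     spec.decoder_width, spec.family, rng)
        return params

    def _mixture_weights(self, rng: Optional[np.random.Generator] = None
                         ) -> Dict[str, np.ndarray]:
        """Per categorical attribute: an (n, n_categories) row-stochastic
        matrix selecting (or mixing) category embeddings per cell.  Fully
        labeled data uses exact one-hot rows."""
        out = {}
        for attr in self.schema:
            if attr.kind != CATEGORICAL:
                continue
            codes = self.dataset.category_codes(attr.name)
            w = np.zeros((self.dataset.n, attr.n_categories))
            w[np.arange(self.dataset.n), codes] = 1.0
            out[attr.name] = w
        return out

    # hook: subclasses may contribute extra loss terms / parameters
    def _extra_parameters(self, params):
        return []

    def _extra_loss(self, params, idx, x_t):
        return None

    def _attribute_latents(self, params, idx, weights, x_t) -> List[Tensor]:
        """Latent code per known attribute for the batch ``idx`` (schema order)."""
        zs = []
        for attr in self.schema:
            if attr.kind == CATEGORICAL:
                w = Tensor(weights[attr.name][idx])
                zs.append(w @ params["cat_tables"][attr.name])
            else:
                feats = self.dataset.attribute_values[attr.name][idx]
                zs.append(params["ord_encoders"][attr.name](Tensor(feats)))
        return zs

    def fit(self, epochs: int = 200, batch_size: int = 256, seed: int = 0,
            lr: float = 1e-3, lr_embedding: float = 1e-2,
            verbose: bool = False) -> "DisentanglementResults":
        """Jointly optimize embeddings, encoders and decoder.

        Network weights and directly-optimized embeddings get separate Adam
        learning rates (latent optimization converges slowly at a shared
        rate).  Fully reproducible given ``seed``.
        """
        ds, spec = self.dataset, self.spec
        rng = np.random.default_rng(int(seed))
        params = self._init_params(rng)
        weights = self._mixture_weights()
        lib = ds.library_sizes().reshape(-1, 1)
        x = ds.x
        net_params = [p for enc in params["ord_encoders"].values()
                      for p in enc.parameters()]
        net_params += params["decoder"].parameters()
        net_params += self._extra_parameters(params)
        embed_params = list(params["cat_tables"].values()) + [params["u_table"]]
        opt = Adam([(net_params, lr), (embed_params, lr_embedding)])
        log_rows = []
        n = ds.n
        for epoch in range(epochs):
            order = rng.permutation(n)
            sums = np.zeros(4)  # total, cmp, min, extra (weighted by batch size)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                x_t = Tensor(x[idx])
                z_att = self._attribute_latents(params, idx, weights, x_t)
                z_u_clean = params["u_table"].take_rows(idx)
                if spec.sigma > 0:
                    eta = rng.normal(0.0, spec.sigma, size=(len(idx), spec.n_latent_u))
                    z_u = z_u_clean + Tensor(eta)
                else:
                    z_u = z_u_clean
                z = concat(z_att + [z_u], axis=1)
                library = Tensor(lib[idx]) if spec.family != GAUSSIAN else None
                out = params["decoder"](z, library)
                ll = loglik_tensor(x_t, spec.family, out["mu"],
                                   out.get("theta", out.get("var")), out.get("zi"))
                nll_cell = (-1.0) * ll.sum(axis=1)
                if spec.family == GAUSSIAN:
                    err = (x_t - out["mu"]) ** 2
                else:
                    err = ((x_t + 1.0).log() - (out["mu"] + 1.0).log()) ** 2
                cmp_loss = nll_cell.mean() + err.mean() * spec.tau
                min_loss = (z_u_clean**2).sum(axis=1).mean() * spec.lambda_
                total = cmp_loss + min_loss
                extra = self._extra_loss(params, idx, x_t)
                if extra is not None:
                    total = total + extra
                if not np.isfinite(total.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch starting {start}: "
                        f"cmp={cmp_loss.data}, min={min_loss.data}"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                b = len(idx)
                sums += b * np.array([
                    float(total.data), float(cmp_loss.data), float(min_loss.data),
                    float(extra.data) if extra is not None else 0.0,
                ])
            row = dict(epoch=epoch, total=sums[0] / n, completeness=sums[1] / n,
                       minimality=sums[2] / n)
            if self._allow_missing:
                row["classification"] = sums[3] / n
            log_rows.append(row)
            if verbose and (epoch % max(1, epochs // 10) == 0 or epoch == epochs - 1):
                print(f"epoch {epoch:4d}  total {row['total']:.4f}  "
                      f"cmp {row['completeness']:.4f}  min {row['minimality']:.4f}")
        return self._make_results(params, weights, pd.DataFrame(log_rows), seed)

    def _make_results(self, params, weights, log, seed):
        return DisentanglementResults(self, params, weights, log, int(seed))


def train(dataset: CellDataset, spec: Optional[LatentSpec] = None,
          **fit_kwargs) -> "DisentanglementResults":
    """Functional wrapper: ``DisentanglementModel(dataset, spec).fit(...)``."""
    return DisentanglementModel(dataset, spec=spec).fit(**fit_kwargs)


class DisentanglementResults:
    """Trained state: embeddings, encoder/decoder weights, training log.

    Provides latent access (:meth:`embed_categorical`, :meth:`embed_ordered`,
    :meth:`embed_unknown`, :meth:`decompose`), generation
    (:meth:`generate`, :meth:`predict`), single-cell latent refitting
    (:meth:`fit_new_cell_embedding`) and serialization (:meth:`save`).
    Downstream analyses live in :mod:`discell.downstream` and are also
    reachable as methods.
    """

    def __init__(self, model: DisentanglementModel, params, weights,
                 training_log: pd.DataFrame, seed: int):
        self.model = model
        self.schema = model.schema
        self.spec = model.spec
        self.dataset = model.dataset
        self._params = params
        self._weights = weights
        self.training_log = training_log
        self.seed = seed
        self._cell_row = {c: i for i, c in enumerate(self.dataset.cell_ids)}

    # -- latent access ---------------------------------------------------
    def embed_categorical(self, attribute: str, label: str) -> np.ndarray:
        """Embedding-table row for ``label``; shared by all cells with it."""
        attr = self.schema[attribute]
        if attr.kind != CATEGORICAL:
            raise ValueError(f"attribute {attribute!r} is not categorical")
        k = attr.category_index(label)
        return self._params["cat_tables"][attribute].data[k].copy()

    def embed_ordered(self, attribute: str, features) -> np.ndarray:
        attr = self.schema[attribute]
        if attr.kind != ORDERED:
            raise ValueError(f"attribute {attribute!r} is not ordered")
        feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if feats.shape[1] != attr.dim:
            raise ValueError(
                f"attribute {attribute!r} expects dim {attr.dim}, got {feats.shape[1]}"
            )
        if not np.all(np.isfinite(feats)):
            raise ValueError(
                f"attribute {attribute!r}: non-finite features; impute or mark "
                "missing upstream"
            )
        out = self._params["ord_encoders"][attribute](Tensor(feats)).data
        return out[0] if np.ndim(features) == 1 else out

    def embed_unknown(self, cell_id: str, training_mode: bool = False,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
        if cell_id not in self._cell_row:
            raise KeyError(
                f"cell {cell_id!r} is not in the training set; use "
                "fit_new_cell_embedding for unseen cells"
            )
        row = self._params["u_table"].data[self._cell_row[cell_id]].copy()
        if training_mode and self.spec.sigma > 0:
            if rng is None:
                rng = np.random.default_rng()
            row = row + rng.normal(0.0, self.spec.sigma, size=row.shape)
        return row

    def _rows_for(self, cell_ids: Optional[Sequence[str]]) -> np.ndarray:
        if cell_ids is None:
            return np.arange(self.dataset.n)
        missing = [c for c in cell_ids if c not in self._cell_row]
        if missing:
            raise KeyError(f"cells not in the training set: {missing[:5]}")
        return np.array([self._cell_row[c] for c in cell_ids], dtype=np.intp)

    def decompose(self, cell_ids: Optional[Sequence[str]] = None,
                  overrides: Optional[Dict[str, object]] = None) -> DecomposedLatent:
        """Decomposed latent codes for training cells, optionally overriding
        selected known attributes (the counterfactual manipulation)."""
        idx = self._rows_for(cell_ids)
        overrides = overrides or {}
        for name in overrides:
            self.schema[name]  # raises KeyError for unknown attributes
        z_y = {}
        for attr in self.schema:
            if attr.name in overrides:
                val = overrides[attr.name]
                if attr.kind == CATEGORICAL:
                    z = np.tile(self.embed_categorical(attr.name, val), (len(idx), 1))
                else:
                    vec = np.asarray(val, dtype=np.float64).reshape(-1)
                    z = np.tile(self.embed_ordered(attr.name, vec), (len(idx), 1))
            elif attr.kind == CATEGORICAL:
                w = self._weights[attr.name][idx]
                z = w @ self._params["cat_tables"][attr.name].data
            else:
                feats = self.dataset.attribute_values[attr.name][idx]
                if np.isnan(feats).any():
                    raise ValueError(
                        f"ordered attribute {attr.name!r} has missing values for "
                        "requested cells"
                    )
                z = self._params["ord_encoders"][attr.name](Tensor(feats)).data
            z_y[attr.name] = z
        z_u = self._params["u_table"].data[idx].copy()
        return DecomposedLatent(z_y=z_y, z_u=z_u, noise_applied=False)

    # -- generation --------------------------------------------------------
    def generate(self, latent: DecomposedLatent,
                 library_size: Optional[np.ndarray] = None) -> ExpressionDistribution:
        """Map a decomposed latent to expression-distribution parameters.

        For count families the mean decomposes as library size x
        softmax-normalized feature proportions; a missing ``library_size``
        defaults to the mean training library.
        """
        latent.validate(self.schema)
        zs = [np.atleast_2d(latent.z_y[a.name]) for a in self.schema]
        z_u = np.atleast_2d(latent.z_u)
        b = max([z.shape[0] for z in zs + [z_u]], default=z_u.shape[0])
        zs = [np.broadcast_to(z, (b, z.shape[1])) for z in zs]
        z_u = np.broadcast_to(z_u, (b, z_u.shape[1]))
        z = Tensor(np.concatenate(zs + [z_u], axis=1))
        library = None
        if self.spec.family != GAUSSIAN:
            if library_size is None:
                library_size = np.full(b, self.dataset.library_sizes().mean())
            library = Tensor(np.asarray(library_size, dtype=np.float64).reshape(-1, 1))
        out = self._params["decoder"](z, library)
        if self.spec.family == GAUSSIAN:
            return ExpressionDistribution(GAUSSIAN, out["mu"].data,
                                          dispersion=out["var"].data)
        if self.spec.family == POISSON:
            return ExpressionDistribution(POISSON, out["mu"].data)
        return ExpressionDistribution(ZINB, out["mu"].data,
                                      dispersion=out["theta"].data,
                                      zero_inflation_logit=out["zi"].data)

    def predict(self, cell_ids: Optional[Sequence[str]] = None,
                overrides: Optional[Dict[str, object]] = None
                ) -> ExpressionDistribution:
        """Reconstruction (or counterfactual, with ``overrides``) for training
        cells: stored codes, noise disabled, observed library sizes."""
        idx = self._rows_for(cell_ids)
        latent = self.decompose(cell_ids, overrides=overrides)
        library = None
        if self.spec.family != GAUSSIAN:
            library = self.dataset.library_sizes()[idx]
        return self.generate(latent, library_size=library)

    # -- losses ------------------------------------------------------------
    def loss_components(self, dataset: Optional[CellDataset] = None) -> Dict[str, float]:
        """Mean per-cell loss terms, noise disabled (deterministic)."""
        if dataset is not None and dataset is not self.dataset:
            raise NotImplementedError("loss evaluation is over the training set")
        from .likelihoods import nll as _nll

        dist = self.predict()
        x = self.dataset.x
        base = _nll(x, dist).mean()
        if self.spec.family == GAUSSIAN:
            mse = ((x - dist.mean) ** 2).mean()
        else:
            mse = ((np.log1p(x) - np.log1p(dist.mean)) ** 2).mean()
        cmp_loss = base + self.spec.tau * mse
        min_loss = self.spec.lambda_ * (self._params["u_table"].data ** 2).sum(axis=1).mean()
        return {"total": cmp_loss + min_loss, "completeness": cmp_loss,
                "minimality": min_loss}

    def unknown_norms(self) -> np.ndarray:
        """Euclidean norm of each training cell's unknown code."""
        return np.linalg.norm(self._params["u_table"].data, axis=1)

    # -- new-cell refit ------------------------------------------------------
    def fit_new_cell_embedding(self, x: np.ndarray, attribute_values: Dict[str, object],
                               steps: int = 800, lr: float = 0.05,
                               seed: int = 0) -> np.ndarray:
        """Optimize an unknown code for an unseen cell, all networks frozen.

        Minimizes ``L_cmp + L_min`` for the single cell from a zero
        initialization; deterministic (no training noise is applied).
        """
        x = np.asarray(x, dtype=np.float64).reshape(1, -1)
        if x.shape[1] != self.dataset.m:
            raise ValueError(f"expected {self.dataset.m} features, got {x.shape[1]}")
        zs = []
        for attr in self.schema:
            if attr.name not in attribute_values:
                raise ValueError(f"attribute {attr.name!r} value required")
            val = attribute_values[attr.name]
            if attr.kind == CATEGORICAL:
                zs.append(self.embed_categorical(attr.name, val).reshape(1, -1))
            else:
                zs.append(self.embed_ordered(
                    attr.name, np.asarray(val, dtype=np.float64).reshape(-1)
                ).reshape(1, -1))
        z_att = Tensor(np.concatenate(zs, axis=1))
        spec = self.spec
        library = None
        if spec.family != GAUSSIAN:
            library = Tensor(np.array([[x.sum()]]))
        x_t = Tensor(x)
        z_u = Tensor(np.zeros((1, spec.n_latent_u)), requires_grad=True)
        opt = Adam([([z_u], lr)])
        for _ in range(steps):
            z = concat([z_att, z_u], axis=1)
            out = self._params["decoder"](z, library)
            ll = loglik_tensor(x_t, spec.family, out["mu"],
                               out.get("theta", out.get("var")), out.get("zi"))
            if spec.family == GAUSSIAN:
                err = (x_t - out["mu"]) ** 2
            else:
                err = ((x_t + 1.0).log() - (out["mu"] + 1.0).log()) ** 2
            loss = (-1.0) * ll.sum() + err.mean() * spec.tau \
                + (z_u**2).sum() * spec.lambda_
            opt.zero_grad()
            loss.backward()
            opt.step()
        return z_u.data[0].copy()

    def cell_loss(self, x: np.ndarray, attribute_values: Dict[str, object],
                  z_u: np.ndarray) -> float:
        """``L_cmp + L_min`` for one cell at a given unknown code (noise off)."""
        from .likelihoods import completeness_loss as _cmp

        x = np.asarray(x, dtype=np.float64).reshape(1, -1)
        zs = {}
        for attr in self.schema:
            val = attribute_values[attr.name]
            if attr.kind == CATEGORICAL:
                zs[attr.name] = self.embed_categorical(attr.name, val)
            else:
                zs[attr.name] = self.embed_ordered(
                    attr.name, np.asarray(val, dtype=np.float64).reshape(-1))
        latent = DecomposedLatent(z_y=zs, z_u=np.asarray(z_u).reshape(1, -1))
        lib = np.array([x.sum()]) if self.spec.family != GAUSSIAN else None
        dist = self.generate(latent, library_size=lib)
        cmp_val = float(_cmp(x, dist, tau=self.spec.tau)[0])
        return cmp_val + self.spec.lambda_ * float(np.sum(np.asarray(z_u) ** 2))

    # -- downstream shortcuts ------------------------------------------------
    def counterfactual(self, manipulations: Dict[str, object],
                       reference: Optional[Sequence[str]] = None, **kw):
        from .downstream import counterfactual_predict

        return counterfactual_predict(self, manipulations, reference=reference, **kw)

    def export_latent(self, attribute: str, features: Optional[np.ndarray] = None):
        from .downstream import export_latent

        return export_latent(self, attribute, features=features)

    # -- reporting -------------------------------------------------------------
    def summary(self) -> str:
        spec, ds = self.spec, self.dataset
        lines = [
            "Disentangled expression model",
            "=" * 64,
            f"cells: {ds.n}    features: {ds.m}    likelihood: {spec.family}",
            f"latent dims: {spec.n_latent_attr} per attribute, "
            f"{spec.n_latent_u} unknown",
            f"sigma={spec.sigma}  lambda={spec.lambda_}  tau={spec.tau}  "
            f"seed={self.seed}",
            "-" * 64,
            f"{'attribute':<20}{'kind':<14}{'levels/dim':<12}",
        ]
        for a in self.schema:
            size = a.n_categories if a.kind == CATEGORICAL else a.dim
            lines.append(f"{a.name:<20}{a.kind:<14}{size:<12}")
        lines.append("-" * 64)
        if len(self.training_log):
            first, last = self.training_log.iloc[0], self.training_log.iloc[-1]
            lines.append(
                f"loss: epoch 0 total={first['total']:.4f} -> "
                f"epoch {int(last['epoch'])} total={last['total']:.4f}"
            )
            lines.append(
                f"final completeness={last['completeness']:.4f}  "
                f"minimality={last['minimality']:.4f}"
            )
            lines.append(f"median ||z_u|| = {np.median(self.unknown_norms()):.4f}")
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------------
    def _array_blobs(self) -> Dict[str, np.ndarray]:
        arrays = {"u_table": self._params["u_table"].data, "x": self.dataset.x}
        for name, t in self._params["cat_tables"].items():
            arrays[f"cat__{name}"] = t.data
        for name, enc in self._params["ord_encoders"].items():
            for i, layer in enumerate(enc.layers):
                arrays[f"enc__{name}__{i}__W"] = layer.W.data
                arrays[f"enc__{name}__{i}__b"] = layer.b.data
        dec = self._params["decoder"]
        for i, layer in enumerate(dec.trunk):
            arrays[f"dec__trunk__{i}__W"] = layer.W.data
            arrays[f"dec__trunk__{i}__b"] = layer.b.data
        arrays["dec__mean__W"] = dec.mean_head.W.data
        arrays["dec__mean__b"] = dec.mean_head.b.data
        if dec.zi_head is not None:
            arrays["dec__zi__W"] = dec.zi_head.W.data
            arrays["dec__zi__b"] = dec.zi_head.b.data
        if dec.log_disp is not None:
            arrays["dec__log_disp"] = dec.log_disp.data
        for name, w in self._weights.items():
            arrays[f"weights__{name}"] = w
        for attr in self.schema:
            if attr.kind == ORDERED:
                arrays[f"ordvals__{attr.name}"] = self.dataset.attribute_values[attr.name]
        return arrays

    def save(self, path) -> None:
        """Serialize to a single ``.npz`` archive; :meth:`load` restores
        bit-identical inference."""
        meta = {
            "schema": self.schema.to_dict(),
            "spec": asdict(self.spec),
            "seed": self.seed,
            "cell_ids": self.dataset.cell_ids,
            "feature_names": self.dataset.feature_names,
            "layer_kind": self.dataset.layer_kind,
            "training_log": self.training_log.to_dict(orient="list"),
            "cat_values": {
                a.name: ["" if v is None else v
                         for v in self.dataset.attribute_values[a.name]]
                for a in self.schema if a.kind == CATEGORICAL
            },
            "kind": type(self).__name__,
        }
        arrays = self._array_blobs()
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DisentanglementResults":
        with np.load(path, allow_pickle=False) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("__meta__")).decode())
        schema = AttributeSchema.from_dict(meta["schema"])
        spec = LatentSpec(**meta["spec"])
        vals = {}
        for a in schema:
            if a.kind == CATEGORICAL:
                vals[a.name] = np.array(
                    [v if v != "" else None for v in meta["cat_values"][a.name]],
                    dtype=object)
            else:
                vals[a.name] = arrays[f"ordvals__{a.name}"]
        ds = CellDataset(x=arrays["x"], schema=schema, attribute_values=vals,
                         cell_ids=meta["cell_ids"],
                         feature_names=meta["feature_names"],
                         layer_kind=meta["layer_kind"])
        if meta.get("kind") == "SemiSupervisedResults":
            from .classify import SemiSupervisedDisentanglementModel, SemiSupervisedResults

            model = SemiSupervisedDisentanglementModel(ds, spec=spec)
            params = model._init_params(np.random.default_rng(0))
            results_cls = SemiSupervisedResults
        else:
            model = DisentanglementModel(ds, spec=spec)
            params = model._init_params(np.random.default_rng(0))
            results_cls = DisentanglementResults
        _restore_params(params, arrays)
        weights = {k[len("weights__"):]: v for k, v in arrays.items()
                   if k.startswith("weights__")}
        log = pd.DataFrame(meta["training_log"])
        res = results_cls(model, params, weights, log, meta["seed"])
        return res


def _restore_params(params, arrays):
    params["u_table"].data = arrays["u_table"]
    for name, t in params["cat_tables"].items():
        t.data = arrays[f"cat__{name}"]
    for name, enc in params["ord_encoders"].items():
        for i, layer in enumerate(enc.layers):
            layer.W.data = arrays[f"enc__{name}__{i}__W"]
            layer.b.data = arrays[f"enc__{name}__{i}__b"]
    dec = params["decoder"]
    for i, layer in enumerate(dec.trunk):
        layer.W.data = arrays[f"dec__trunk__{i}__W"]
        layer.b.data = arrays[f"dec__trunk__{i}__b"]
    dec.mean_head.W.data = arrays["dec__mean__W"]
    dec.mean_head.b.data = arrays["dec__mean__b"]
    if dec.zi_head is not None:
        dec.zi_head.W.data = arrays["dec__zi__W"]
        dec.zi_head.b.data = arrays["dec__zi__b"]
    if dec.log_disp is not None:
        dec.log_disp.data = arrays["dec__log_disp"]
    if "cls" in params:
        from .classify import _restore_bank

        _restore_bank(params["cls"], arrays)
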