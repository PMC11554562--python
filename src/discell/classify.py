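"""Semi-supervised extension: joint per-attribute classifiers/regressors.

For each known attribute with partial labels, an auxiliary head maps the
measured expression to category probabilities (categorical attributes) or to
the attribute's feature vector (ordered attributes).  The heads are trained
jointly with the generative model through

    L = L_cmp + L_min + L_cls
    L_cls = sum_C H(Y_C^S, C(X^S)) + sum_R MSE(Y_R^S, R(X^S))

evaluated only over cells whose labels are observed.  For unlabeled cells
the head's output completes the decomposed latent representation: by default
the *soft* probability-weighted mixture of category embeddings (differentiable
end-to-end), optionally the hard argmax.  After training the heads impute the
missing labels themselves.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._autodiff import MLP, Tensor, concat, logsumexp
from .dataset import RAW_COUNTS, CellDataset
from .model import DisentanglementModel, DisentanglementResults, LatentSpec
from .schema import CATEGORICAL, ORDERED

__all__ = ["ClassifierBank", "SemiSupervisedDisentanglementModel",
           "SemiSupervisedResults", "train_semisupervised", "classification_loss",
           "impute_labels"]


class ClassifierBank:
    """One classifier per partially labeled categorical attribute and one
    regressor per partially labeled ordered attribute, all MLPs on the
    measured expression (log1p-transformed for count layers)."""

    def __init__(self, schema, m: int, supervised: Sequence[str],
                 depth: int, width: int, rng: np.random.Generator,
                 log1p_input: bool):
        self.supervised = list(supervised)
        self.log1p_input = log1p_input
        self.heads: Dict[str, MLP] = {}
        self.kinds: Dict[str, str] = {}
        for name in supervised:
            attr = schema[name]
            n_out = attr.n_categories if attr.kind == CATEGORICAL else attr.dim
            self.heads[name] = MLP(m, n_out, depth, width, rng)
            self.kinds[name] = attr.kind

    def _input(self, x: np.ndarray) -> np.ndarray:
        return np.log1p(x) if self.log1p_input else x

    def logits_tensor(self, name: str, x_t: Tensor) -> Tensor:
        return self.heads[name](x_t)

    def predict_proba(self, name: str, x: np.ndarray) -> np.ndarray:
        if self.kinds[name] != CATEGORICAL:
            raise ValueError(f"{name!r} has a regressor, not a classifier")
        logits = self.heads[name](Tensor(self._input(np.atleast_2d(x)))).data
        logits = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict_features(self, name: str, x: np.ndarray) -> np.ndarray:
        if self.kinds[name] != ORDERED:
            raise ValueError(f"{name!r} has a classifier, not a regressor")
        return self.heads[name](Tensor(self._input(np.atleast_2d(x)))).data

    def parameters(self):
        return [p for h in self.heads.values() for p in h.parameters()]


class SemiSupervisedDisentanglementModel(DisentanglementModel):
    """Disentanglement model accepting partially labeled attributes.

    Every attribute must either be fully labeled or have at least one
    labeled cell; attributes with any missing labels get an auxiliary
    classifier/regressor (additional names can be forced via
    ``supervised``).  ``completion`` chooses how an unlabeled cell's latent
    is assembled from classifier output: ``"soft"`` (probability-weighted
    embedding mixture, the default) or ``"hard"`` (argmax embedding).
    """

    _allow_missing = True

    def __init__(self, dataset: CellDataset, spec: Optional[LatentSpec] = None,
                 supervised: Optional[Sequence[str]] = None,
                 classifier_depth: int = 2, classifier_width: int = 128,
                 completion: str = "soft", cls_weight: float = 1.0):
        super().__init__(dataset, spec=spec)
        if completion not in ("soft", "hard"):
            raise ValueError("completion must be 'soft' or 'hard'")
        self.completion = completion
        self.cls_weight = float(cls_weight)
        self.classifier_depth = classifier_depth
        self.classifier_width = classifier_width
        auto = [a.name for a in self.schema if dataset.is_missing(a.name).any()]
        self.supervised = sorted(set(auto) | set(supervised or []),
                                 key=self.schema.names.index)
        for name in self.supervised:
            attr = self.schema[name]
            labeled = ~dataset.is_missing(name)
            if not labeled.any():
                raise ValueError(
                    f"attribute {name!r} has zero labeled cells; at least one "
                    "label is required"
                )
            if attr.kind == CATEGORICAL:
                seen = {v for v in dataset.attribute_values[name][labeled]}
                absent = [c for c in attr.categories if c not in seen]
                if absent:
                    warnings.warn(
                        f"attribute {name!r}: no labeled support for classes "
                        f"{absent}; they cannot be learned from labels"
                    )

    def _init_params(self, rng):
        params = super()._init_params(rng)
        params["cls"] = ClassifierBank(
            self.schema, self.dataset.m, self.supervised,
            self.classifier_depth, self.classifier_width, rng,
            log1p_input=self.dataset.layer_kind == RAW_COUNTS)
        return params

    def _mixture_weights(self, rng=None):
        out = {}
        for attr in self.schema:
            if attr.kind != CATEGORICAL:
                continue
            codes = self.dataset.category_codes(attr.name)
            w = np.zeros((self.dataset.n, attr.n_categories))
            labeled = codes >= 0
            w[np.flatnonzero(labeled), codes[labeled]] = 1.0
            out[attr.name] = w  # unlabeled rows filled from the classifier
        return out

    def _extra_parameters(self, params):
        return params["cls"].parameters()

    def _attribute_latents(self, params, idx, weights, x_t):
        bank: ClassifierBank = params["cls"]
        xin = Tensor(bank._input(self.dataset.x[idx]))
        zs = []
        for attr in self.schema:
            if attr.kind == CATEGORICAL:
                table = params["cat_tables"][attr.name]
                onehot = Tensor(weights[attr.name][idx])
                if attr.name in bank.heads:
                    miss = self.dataset.is_missing(attr.name)[idx]
                    if miss.any():
                        logits = bank.logits_tensor(attr.name, xin)
                        logp = logits - logsumexp(logits, axis=1, keepdims=True)
                        probs = logp.exp()
                        if self.completion == "hard":
                            hard = np.zeros_like(probs.data)
                            hard[np.arange(len(idx)), probs.data.argmax(axis=1)] = 1.0
                            probs = Tensor(hard)
                        mixed = onehot.mask(~miss[:, None]) + probs.mask(miss[:, None])
                        zs.append(mixed @ table)
                        continue
                zs.append(onehot @ table)
            else:
                feats = self.dataset.attribute_values[attr.name][idx]
                if attr.name in bank.heads:
                    miss = self.dataset.is_missing(attr.name)[idx]
                    if miss.any():
                        pred = bank.heads[attr.name](xin)
                        obs = Tensor(np.nan_to_num(feats))
                        feats_t = obs.mask(~miss[:, None]) + pred.mask(miss[:, None])
                        zs.append(params["ord_encoders"][attr.name](feats_t))
                        continue
                zs.append(params["ord_encoders"][attr.name](Tensor(feats)))
        return zs

    def _extra_loss(self, params, idx, x_t):
        bank: ClassifierBank = params["cls"]
        xin = Tensor(bank._input(self.dataset.x[idx]))
        terms = []
        for name in bank.supervised:
            attr = self.schema[name]
            labeled = ~self.dataset.is_missing(name)[idx]
            if not labeled.any():
                continue
            out = bank.logits_tensor(name, xin)
            if attr.kind == CATEGORICAL:
                codes = self.dataset.category_codes(name)[idx]
                onehot = np.zeros((len(idx), attr.n_categories))
                onehot[np.flatnonzero(labeled), codes[labeled]] = 1.0
                logp = out - logsumexp(out, axis=1, keepdims=True)
                ce = (-1.0) * (logp * Tensor(onehot)).sum(axis=1)
                terms.append(ce.mask(labeled).sum() * (1.0 / labeled.sum()))
            else:
                target = np.nan_to_num(self.dataset.attribute_values[name][idx])
                err = ((out - Tensor(target)) ** 2).mean(axis=1)
                terms.append(err.mask(labeled).sum() * (1.0 / labeled.sum()))
        if not terms:
            return None
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        return total * self.cls_weight

    def _make_results(self, params, weights, log, seed):
        # freeze the completion: fill unlabeled rows with final head output
        bank: ClassifierBank = params["cls"]
        for attr in self.schema:
            if attr.kind != CATEGORICAL or attr.name not in bank.heads:
                continue
            miss = self.dataset.is_missing(attr.name)
            if not miss.any():
                continue
            probs = bank.predict_proba(attr.name, self.dataset.x[miss])
            if self.completion == "hard":
                hard = np.zeros_like(probs)
                hard[np.arange(len(probs)), probs.argmax(axis=1)] = 1.0
                probs = hard
            weights[attr.name][miss] = probs
        return SemiSupervisedResults(self, params, weights, log, int(seed))


class SemiSupervisedResults(DisentanglementResults):
    """Results of semi-supervised training; adds the classifier bank and
    label imputation."""

    @property
    def bank(self) -> ClassifierBank:
        return self._params["cls"]

    def classification_loss(self, dataset: Optional[CellDataset] = None) -> float:
        ds = dataset if dataset is not None else self.dataset
        return classification_loss(self.bank, ds)

    def loss_components(self, dataset=None):
        out = super().loss_components(dataset)
        out["classification"] = self.cls_loss = self.classification_loss()
        out["total"] = out["total"] + out["classification"]
        return out

    def impute_labels(self, dataset: Optional[CellDataset] = None
                      ) -> Tuple[CellDataset, pd.DataFrame]:
        return impute_labels(self, self.bank, dataset)

    def _array_blobs(self):
        arrays = super()._array_blobs()
        for name, head in self.bank.heads.items():
            for i, layer in enumerate(head.layers):
                arrays[f"cls__{name}__{i}__W"] = layer.W.data
                arrays[f"cls__{name}__{i}__b"] = layer.b.data
        return arrays


def _restore_bank(bank: ClassifierBank, arrays):
    for name, head in bank.heads.items():
        for i, layer in enumerate(head.layers):
            layer.W.data = arrays[f"cls__{name}__{i}__W"]
            layer.b.data = arrays[f"cls__{name}__{i}__b"]


def classification_loss(bank: ClassifierBank, ds: CellDataset) -> float:
    """Cross-entropy (categorical) plus MSE (ordered) over labeled cells only,
    averaged per labeled cell within each supervised attribute and summed
    across attributes."""
    total = 0.0
    for name in bank.supervised:
        attr = ds.schema[name]
        labeled = ~ds.is_missing(name)
        if not labeled.any():
            raise ValueError(f"attribute {name!r} has zero labeled cells")
        x = ds.x[labeled]
        if attr.kind == CATEGORICAL:
            probs = bank.predict_proba(name, x)
            codes = ds.category_codes(name)[labeled]
            with np.errstate(divide="ignore"):
                logp = np.log(probs[np.arange(len(codes)), codes])
            total += float(-logp.mean())
        else:
            pred = bank.predict_features(name, x)
            target = ds.attribute_values[name][labeled]
            total += float(((pred - target) ** 2).mean(axis=1).mean())
    return total


def train_semisupervised(dataset: CellDataset, spec: Optional[LatentSpec] = None,
                         **kwargs) -> SemiSupervisedResults:
    """Functional wrapper around :class:`SemiSupervisedDisentanglementModel`.

    Keyword arguments are split between the model constructor and ``fit``.
    """
    model_keys = {"supervised", "classifier_depth", "classifier_width",
                  "completion", "cls_weight"}
    model_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in model_keys}
    model = SemiSupervisedDisentanglementModel(dataset, spec=spec, **model_kwargs)
    return model.fit(**kwargs)


def impute_labels(results: DisentanglementResults, bank: ClassifierBank,
                  dataset: Optional[CellDataset] = None
                  ) -> Tuple[CellDataset, pd.DataFrame]:
    """Fill missing labels with classifier argmax / regressor output.

    Observed labels are never overwritten (confidence 1, flag ``observed``).
    Categorical ties break deterministically to the first category in schema
    order.  Returns the completed dataset plus a per-cell record table
    (cell id, attribute, label, confidence, observed/imputed flag).
    """
    ds = dataset if dataset is not None else results.dataset
    out = ds.copy()
    rows = []
    for name in bank.supervised:
        attr = ds.schema[name]
        miss = ds.is_missing(name)
        if attr.kind == CATEGORICAL:
            probs = bank.predict_proba(name, ds.x)
            pred_idx = probs.argmax(axis=1)  # first max wins: schema-order tie-break
            conf = probs[np.arange(ds.n), pred_idx]
            for i, cid in enumerate(ds.cell_ids):
                if miss[i]:
                    label = attr.categories[pred_idx[i]]
                    out.attribute_values[name][i] = label
                    rows.append((cid, name, label, float(conf[i]), "imputed"))
                else:
                    rows.append((cid, name, ds.attribute_values[name][i], 1.0,
                                 "observed"))
        else:
            pred = bank.predict_features(name, ds.x)
            for i, cid in enumerate(ds.cell_ids):
                if miss[i]:
                    out.attribute_values[name][i] = pred[i]
                    rows.append((cid, name,
                                 ";".join(f"{v:g}" for v in pred[i]), np.nan,
                                 "imputed"))
                else:
                    rows.append((cid, name,
                                 ";".join(f"{v:g}" for v in
                                          ds.attribute_values[name][i]), 1.0,
                                 "observed"))
    table = pd.DataFrame(rows, columns=["cell_id", "attribute", "label",
                                        "confidence", "flag"])
    return out, table
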