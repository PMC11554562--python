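"""Downstream analyses over a trained model.

* counterfactual prediction: hold each reference cell's unknown code fixed,
  swap the embeddings of manipulated known attributes, regenerate;
* evaluation harness: mean-profile r^2 against ground-truth measurements,
  plus NMSE normalized by the "no perturb" prediction;
* feature-state association: per-feature paired t test between observed
  expression and its own counterfactual mean, Benjamini-Hochberg adjusted;
* k-NN uncertainty of an embedding given a covariate;
* latent-space export for external correlation/clustering tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import r2_score
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .dataset import CellDataset
from .likelihoods import GAUSSIAN, ExpressionDistribution
from .schema import CATEGORICAL, ORDERED

__all__ = [
    "CounterfactualResult",
    "UncertaintyResult",
    "counterfactual_predict",
    "evaluate_counterfactuals",
    "associate_features",
    "uncertainty",
    "export_latent",
]


@dataclass
class CounterfactualResult:
    """Paired original/predicted expression under manipulated attributes."""

    cell_ids: list
    original: Dict[str, np.ndarray]  # attribute values of the reference cells
    target: Dict[str, object]  # the manipulation applied
    mean: np.ndarray  # n_ref x M predicted means
    dist: ExpressionDistribution
    feature_names: list
    noise_applied: bool = False

    def __post_init__(self):
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("counterfactual means are non-finite")

    def to_anndata(self):
        import anndata as ad

        obs = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        for name, vals in self.original.items():
            obs[f"original_{name}"] = [str(v) for v in vals]
        adata = ad.AnnData(X=self.mean.copy(), obs=obs,
                           var=pd.DataFrame(index=pd.Index(self.feature_names)))
        adata.uns["manipulation"] = {k: str(v) for k, v in self.target.items()}
        adata.uns["noise_applied"] = self.noise_applied
        return adata


def counterfactual_predict(results, manipulations: Dict[str, object],
                           reference: Optional[Sequence[str]] = None,
                           additive: bool = False) -> CounterfactualResult:
    """Predict reference cells' expression under manipulated attributes.

    Unmanipulated attribute codes and the unknown code stay exactly at their
    trained values; generation runs with noise disabled, so every predicted
    change is attributable to the manipulation.  An empty manipulation
    reproduces the model's own reconstruction bit-exactly.

    ``additive=True`` handles a composite manipulation of one ordered
    attribute given as a *list* of target vectors (e.g. a two-gene
    perturbation from one-gene training): the predicted change is the sum of
    each single manipulation's change relative to the reconstruction.
    """
    schema = results.schema
    for name, val in manipulations.items():
        attr = schema[name]
        if attr.kind == CATEGORICAL and not additive:
            attr.category_index(val)  # raises for categories unseen in training
    cell_ids = list(reference) if reference is not None else list(results.dataset.cell_ids)
    idx = results._rows_for(cell_ids)

    if additive:
        if len(manipulations) != 1:
            raise ValueError("additive mode expects exactly one manipulated attribute")
        (name, values), = manipulations.items()
        if schema[name].kind != ORDERED:
            raise ValueError("additive composition is defined for ordered attributes")
        recon = results.predict(cell_ids).mean
        total = recon.copy()
        for vec in values:
            single = results.predict(cell_ids, overrides={name: vec}).mean
            total = total + (single - recon)
        dist = results.predict(cell_ids)  # family parameters from reconstruction
        mean = total
    else:
        dist = results.predict(cell_ids, overrides=manipulations)
        mean = dist.mean

    original = {a.name: results.dataset.attribute_values[a.name][idx]
                for a in schema}
    return CounterfactualResult(
        cell_ids=cell_ids, original=original, target=dict(manipulations),
        mean=mean, dist=dist, feature_names=list(results.dataset.feature_names),
        noise_applied=False)


def _mean_profile(x: np.ndarray, log1p: bool) -> np.ndarray:
    prof = np.asarray(x).mean(axis=0)
    return np.log1p(prof) if log1p else prof


def evaluate_counterfactuals(pred: CounterfactualResult, truth: CellDataset,
                             metric: str = "r2_mean_profile",
                             control: Optional[CellDataset] = None,
                             log1p: bool = True) -> Dict[str, float]:
    """Score counterfactual predictions against real target-condition cells.

    ``r2_mean_profile``: coefficient of determination between the mean
    predicted profile and the mean observed profile over all features.
    ``nmse``: mean squared error normalized by the error of the "no perturb"
    prediction (the control mean), so predicting no effect scores exactly 1.
    With ``control`` given, the naive control-vs-truth baseline r^2 is also
    reported.  For count data profiles are log1p-transformed first
    (``log1p=False`` compares raw scales).
    """
    if truth.n < 1:
        raise ValueError("need at least one truth cell")
    use_log = log1p and pred.dist.family != GAUSSIAN
    truth_prof = _mean_profile(truth.x, use_log)
    pred_prof = _mean_profile(pred.mean, use_log)
    out: Dict[str, float] = {"n_pred": float(len(pred.cell_ids)),
                             "n_truth": float(truth.n)}
    if np.var(truth_prof) == 0:
        out["r2"] = np.nan
        warnings.warn("zero-variance truth profile: r^2 undefined")
        return out
    if metric not in ("r2_mean_profile", "nmse"):
        raise ValueError(f"unknown metric {metric!r}")
    out["r2"] = float(r2_score(truth_prof, pred_prof))
    if control is not None:
        control_prof = _mean_profile(control.x, use_log)
        out["r2_naive"] = float(r2_score(truth_prof, control_prof))
        out["nmse"] = float(((pred_prof - truth_prof) ** 2).mean()
                            / ((control_prof - truth_prof) ** 2).mean())
    elif metric == "nmse":
        raise ValueError("nmse requires the control (no-perturb) dataset")
    return out


def per_cell_r2(pred: CounterfactualResult, truth: CellDataset,
                log1p: bool = True) -> np.ndarray:
    """Non-default per-cell variant: r^2 of each predicted cell against the
    mean observed profile."""
    use_log = log1p and pred.dist.family != GAUSSIAN
    truth_prof = _mean_profile(truth.x, use_log)
    p = np.log1p(pred.mean) if use_log else pred.mean
    return np.array([r2_score(truth_prof, row) for row in p])


def associate_features(original: CellDataset, counterfactual: CounterfactualResult,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Feature-state association: dependent t test for paired samples.

    Pairs each reference cell's observed expression with its own
    counterfactual mean, per feature; Benjamini-Hochberg adjustment across
    all features.  Zero-variance difference vectors are flagged and assigned
    p = 1.  The returned table (feature, statistic, p, p_adj, mean_diff,
    direction) is directly consumable as a ranked list by enrichment tools.
    """
    if original.cell_ids != counterfactual.cell_ids:
        idx = [original.cell_ids.index(c) for c in counterfactual.cell_ids]
        obs = original.x[idx]
    else:
        obs = original.x
    if obs.shape[0] < 2:
        raise ValueError("paired t test needs at least 2 reference cells")
    if obs.shape != counterfactual.mean.shape:
        raise ValueError("counterfactual rows must align one-to-one with cells")
    diff = counterfactual.mean - obs
    degenerate = diff.std(axis=0) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        tres = stats.ttest_rel(counterfactual.mean, obs, axis=0)
    stat = np.asarray(tres.statistic, dtype=np.float64)
    pval = np.asarray(tres.pvalue, dtype=np.float64)
    stat[degenerate] = np.nan
    pval[degenerate] = 1.0
    pval = np.nan_to_num(pval, nan=1.0)
    _, p_adj, _, _ = multipletests(pval, alpha=alpha, method="fdr_bh")
    mean_diff = diff.mean(axis=0)
    table = pd.DataFrame({
        "feature": counterfactual.feature_names,
        "statistic": stat,
        "p_value": pval,
        "p_adjusted": p_adj,
        "mean_diff": mean_diff,
        "direction": np.where(degenerate, "none",
                              np.where(mean_diff > 0, "up", "down")),
        "degenerate": degenerate,
    })
    table.attrs["alpha"] = alpha
    return table


def write_association_table(table: pd.DataFrame, path) -> None:
    cols = ["feature", "statistic", "p_value", "p_adjusted", "mean_diff", "direction"]
    table[cols].to_csv(path, sep="\t", index=False)


@dataclass
class UncertaintyResult:
    """Per-item k-NN uncertainty u_i >= 0 and the settings that produced it."""

    u: np.ndarray
    k: int
    metric: str
    covariate: np.ndarray
    neighbor_indices: np.ndarray = field(repr=False, default=None)


def uncertainty(embedding: np.ndarray, covariate: Sequence, k: int = 5,
                metric: str = "euclidean", standardize: bool = True,
                clamp: float = 1.0 + 1e-6) -> UncertaintyResult:
    """Inability to predict a covariate from the embedding's k-NN graph.

    For each item ``i`` with neighbor set N_i (self excluded),

        u_i = H(C_{N_i}) * sum_{j in N_i} 1 / log d(i, j)

    where H is the Shannon entropy (natural log) of the empirical covariate
    distribution among the k neighbors.  H is independent of j, so the sum
    factors out.  Distances are clamped below at ``clamp`` (> 1), which keeps
    1/log d positive and finite when points (near-)coincide; embeddings are
    per-dimension z-scored before distance computation by default.
    """
    emb = np.atleast_2d(np.asarray(embedding, dtype=np.float64))
    cov = np.asarray(covariate)
    n = emb.shape[0]
    if cov.shape[0] != n:
        raise ValueError("covariate length must match number of items")
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_items; got k={k}, n={n}")
    if standardize:
        sd = emb.std(axis=0)
        sd[sd == 0] = 1.0
        emb = (emb - emb.mean(axis=0)) / sd
    # exact pairwise distances (cdist avoids the quadratic-expansion rounding
    # of tree/BLAS neighbor searches); n is attribute-level, so O(n^2) is fine
    full = cdist(emb, emb, metric=metric)
    neigh = np.empty((n, k), dtype=np.intp)
    ndist = np.empty((n, k))
    for i in range(n):
        order = np.argsort(full[i], kind="stable")
        order = order[order != i][:k]
        neigh[i] = order
        ndist[i] = full[i][order]
    if np.any(ndist == 0):
        warnings.warn("duplicate points at distance 0; distances clamped")
    ndist = np.maximum(ndist, clamp)
    u = np.empty(n)
    for i in range(n):
        labels, counts = np.unique(cov[neigh[i]], return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log(p)).sum())
        u[i] = h * float((1.0 / np.log(ndist[i])).sum())
    return UncertaintyResult(u=u, k=k, metric=metric, covariate=cov,
                             neighbor_indices=neigh)


def export_latent(results, attribute: str,
                  features: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Labeled latent matrix for one attribute (or ``"unknown"``).

    Categorical: one row per category.  Ordered: the encoder applied to a
    caller-supplied feature set (rows labeled by position or by a features
    DataFrame index).  Unknown: one row per training cell, keyed by cell id.
    """
    spec = results.spec
    if attribute == "unknown":
        return pd.DataFrame(results._params["u_table"].data.copy(),
                            index=pd.Index(results.dataset.cell_ids, name="cell_id"),
                            columns=[f"z{j}" for j in range(spec.n_latent_u)])
    attr = results.schema[attribute]
    cols = [f"z{j}" for j in range(spec.n_latent_attr)]
    if attr.kind == CATEGORICAL:
        table = results._params["cat_tables"][attribute].data.copy()
        return pd.DataFrame(table, index=pd.Index(attr.categories, name=attribute),
                            columns=cols)
    if features is None:
        raise ValueError(
            f"ordered attribute {attribute!r} needs a feature set to encode")
    if isinstance(features, pd.DataFrame):
        index = features.index
        feats = features.to_numpy(dtype=np.float64)
    else:
        feats = np.atleast_2d(np.asarray(features, dtype=np.float64))
        index = pd.RangeIndex(len(feats))
    z = results.embed_ordered(attribute, feats)
    return pd.DataFrame(z, index=index, columns=cols)
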