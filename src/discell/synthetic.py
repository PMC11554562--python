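"""Synthetic single-cell-like data with known ground-truth attribute effects.

The generator emulates the structure the model assumes: per-cell log-mean
profiles built from a feature baseline plus additive per-attribute effects on
declared target-feature sets, plus low-rank cell-specific nuisance structure
that no known attribute explains (exactly what the unknown code should
capture).  Counts are drawn per likelihood family with log-normal library
sizes, overdispersion and zero inflation.  Every planted quantity is recorded
in a :class:`GroundTruth` so downstream recovery can be scored exactly.

Default conditions: 2,000 cells x 200 features, two categorical attributes
(3 and 2 classes) and one 1-D ordered dose, planted effects of 0.5-1.0
natural-log units, ZINB counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dataset import LOG_NORMALIZED, RAW_COUNTS, CellDataset
from .likelihoods import GAUSSIAN, POISSON, ZINB
from .schema import CATEGORICAL, ORDERED, Attribute, AttributeSchema

__all__ = ["AttributePlan", "SyntheticConfig", "GroundTruth", "generate",
           "mask_labels", "default_plan"]


@dataclass
class AttributePlan:
    """One planted attribute: its kind, levels, targets and effect size.

    ``effect_size`` is in natural-log-mean units.  Categorical attributes
    use the first category as the unaffected reference; each other category
    gets a random-sign pattern of magnitude ``effect_size`` on the target
    features.  Ordered attributes act linearly in the log-mean (a monotone
    dose response), with 1-D values drawn from ``levels``.
    """

    name: str
    kind: str
    target_features: Sequence[int]
    effect_size: float
    categories: Optional[Sequence[str]] = None
    dim: int = 1
    levels: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0)

    def to_attribute(self) -> Attribute:
        if self.kind == CATEGORICAL:
            return Attribute(self.name, CATEGORICAL, categories=tuple(self.categories))
        return Attribute(self.name, ORDERED, dim=self.dim)


def default_plan(m: int = 200) -> List[AttributePlan]:
    """Default attribute plan scaled to ``m`` features: a 3-class cell type
    on the first 20% of features, a 2-class status on the next 10%, and a
    1-D dose on the following 10%."""
    a, b, c = int(0.2 * m), int(0.3 * m), int(0.4 * m)
    return [
        AttributePlan("cell_type", CATEGORICAL, range(0, a), 1.0,
                      categories=("typeA", "typeB", "typeC")),
        AttributePlan("status", CATEGORICAL, range(a, b), 0.8,
                      categories=("control", "perturbed")),
        AttributePlan("dose", ORDERED, range(b, c), 0.6, dim=1),
    ]


@dataclass
class SyntheticConfig:
    n: int = 2000
    m: int = 200
    attributes: Optional[List[AttributePlan]] = None
    nuisance_dim: int = 4
    nuisance_scale: float = 0.3
    library_log_mean: float = float(np.log(2000.0))
    library_log_sd: float = 0.3
    family: str = ZINB
    dispersion: float = 10.0  # NB inverse-dispersion theta
    zero_inflation: float = 0.05
    gaussian_noise_sd: float = 0.3
    mask_attribute: Optional[str] = None
    mask_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValueError("need n >= 1 and m >= 1")
        if self.attributes is None:
            self.attributes = default_plan(self.m)
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must be in [0, 1)")
        for plan in self.attributes:
            if plan.kind == CATEGORICAL and not plan.categories:
                raise ValueError(f"attribute {plan.name!r}: zero categories")
            targets = np.asarray(list(plan.target_features))
            if targets.size and (targets.min() < 0 or targets.max() >= self.m):
                raise ValueError(f"attribute {plan.name!r}: targets outside 0..{self.m-1}")
            if not np.isfinite(plan.effect_size):
                raise ValueError(f"attribute {plan.name!r}: non-finite effect size")

    def schema(self) -> AttributeSchema:
        return AttributeSchema(tuple(p.to_attribute() for p in self.attributes))


@dataclass
class GroundTruth:
    """Everything planted: per-attribute effect vectors in log-mean space,
    the nuisance factors, true labels (including any later masked), and the
    baseline/library draws."""

    config: SyntheticConfig
    baseline_log: np.ndarray  # (M,)
    effects: Dict[str, Dict[str, np.ndarray]]  # categorical: category -> (M,)
    slopes: Dict[str, np.ndarray]  # ordered: (dim, M)
    labels: Dict[str, np.ndarray]  # true attribute values per cell
    nuisance: np.ndarray  # (n, nuisance_dim)
    nuisance_loadings: np.ndarray  # (nuisance_dim, M)
    library: np.ndarray  # (n,)
    log_mean: np.ndarray  # (n, M) planted log-mean (pre-softmax logits)

    def target_features(self, attribute: str) -> np.ndarray:
        for plan in self.config.attributes:
            if plan.name == attribute:
                return np.asarray(list(plan.target_features), dtype=int)
        raise KeyError(attribute)

    def condition_logits(self, assignment: Dict[str, object]) -> np.ndarray:
        """Planted log-mean profile of a condition, nuisance at zero."""
        logits = self.baseline_log.copy()
        for plan in self.config.attributes:
            val = assignment[plan.name]
            if plan.kind == CATEGORICAL:
                logits = logits + self.effects[plan.name][str(val)]
            else:
                vec = np.asarray(val, dtype=np.float64).reshape(-1)
                logits = logits + vec @ self.slopes[plan.name]
        return logits

    def to_json(self) -> str:
        payload = {
            "baseline_log": self.baseline_log.tolist(),
            "effects": {a: {c: v.tolist() for c, v in d.items()}
                        for a, d in self.effects.items()},
            "slopes": {a: v.tolist() for a, v in self.slopes.items()},
            "labels": {a: np.asarray(v).tolist() for a, v in self.labels.items()},
            "nuisance": self.nuisance.tolist(),
            "nuisance_loadings": self.nuisance_loadings.tolist(),
            "library": self.library.tolist(),
            "target_features": {p.name: [int(i) for i in p.target_features]
                                for p in self.config.attributes},
            "seed": self.config.seed,
        }
        return json.dumps(payload)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def generate(config: SyntheticConfig) -> Tuple[CellDataset, GroundTruth]:
    """Draw a dataset and its ground truth; bit-reproducible given the seed."""
    rng = np.random.default_rng(int(config.seed))
    n, m = config.n, config.m
    baseline = rng.normal(0.0, 1.0, size=m)
    logits = np.tile(baseline, (n, 1))

    effects: Dict[str, Dict[str, np.ndarray]] = {}
    slopes: Dict[str, np.ndarray] = {}
    labels: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for plan in config.attributes:
        targets = np.asarray(list(plan.target_features), dtype=int)
        if plan.kind == CATEGORICAL:
            cats = list(plan.categories)
            deltas = {cats[0]: np.zeros(m)}
            for cat in cats[1:]:
                delta = np.zeros(m)
                delta[targets] = plan.effect_size * rng.choice([-1.0, 1.0],
                                                               size=targets.size)
                deltas[cat] = delta
            effects[plan.name] = deltas
            lab = rng.integers(0, len(cats), size=n)
            labels[plan.name] = np.array([cats[i] for i in lab], dtype=object)
            values[plan.name] = labels[plan.name].copy()
            logits += np.stack([deltas[cats[i]] for i in lab])
        else:
            slope = np.zeros((plan.dim, m))
            for d in range(plan.dim):
                slope[d, targets] = plan.effect_size * rng.choice([-1.0, 1.0],
                                                                  size=targets.size)
            slopes[plan.name] = slope
            if plan.dim == 1:
                vals = rng.choice(np.asarray(plan.levels, dtype=np.float64),
                                  size=(n, 1))
            else:
                vals = rng.normal(0.0, 1.0, size=(n, plan.dim))
            labels[plan.name] = vals.copy()
            values[plan.name] = vals
            logits += vals @ slope

    loadings = rng.normal(0.0, 1.0, size=(config.nuisance_dim, m))
    nuisance = rng.normal(0.0, config.nuisance_scale, size=(n, config.nuisance_dim))
    logits += nuisance @ loadings
    library = np.exp(rng.normal(config.library_log_mean, config.library_log_sd,
                                size=n))

    if config.family == GAUSSIAN:
        x = logits + rng.normal(0.0, config.gaussian_noise_sd, size=(n, m))
        layer = LOG_NORMALIZED
    else:
        prop = np.exp(logits - logits.max(axis=1, keepdims=True))
        prop /= prop.sum(axis=1, keepdims=True)
        mu = library[:, None] * prop
        if config.family == POISSON:
            x = rng.poisson(mu).astype(np.float64)
        else:
            lam = rng.gamma(config.dispersion, mu / config.dispersion)
            x = rng.poisson(lam).astype(np.float64)
            drop = rng.random(size=(n, m)) < config.zero_inflation
            x[drop] = 0.0
        layer = RAW_COUNTS

    ds = CellDataset(x=x, schema=config.schema(), attribute_values=values,
                     cell_ids=[f"cell{i:05d}" for i in range(n)],
                     feature_names=[f"gene{j:04d}" for j in range(m)],
                     layer_kind=layer)
    gt = GroundTruth(config=config, baseline_log=baseline, effects=effects,
                     slopes=slopes, labels=labels, nuisance=nuisance,
                     nuisance_loadings=loadings, library=library, log_mean=logits)
    if config.mask_attribute is not None and config.mask_fraction > 0:
        ds, _ = mask_labels(ds, config.mask_attribute, config.mask_fraction,
                            seed=config.seed + 1)
    return ds, gt


def mask_labels(ds: CellDataset, attribute: str, fraction: float, seed: int = 0,
                stratified: bool = False) -> Tuple[CellDataset, np.ndarray]:
    """Replace exactly ``floor(fraction * n)`` labels with the missing marker.

    ``stratified`` preserves class proportions among the masked cells to
    within one cell per class (categorical attributes only).  Returns the
    masked dataset and the masked row indices, for accuracy scoring.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    attr = ds.schema[attribute]
    rng = np.random.default_rng(int(seed))
    n_mask = int(np.floor(fraction * ds.n))
    out = ds.copy()
    if n_mask == 0:
        return out, np.array([], dtype=int)
    if stratified and attr.kind == CATEGORICAL:
        codes = ds.category_codes(attribute)
        picks = []
        remainder = []
        for c in range(attr.n_categories):
            rows = np.flatnonzero(codes == c)
            rng.shuffle(rows)
            quota = fraction * rows.size
            take = int(np.floor(quota))
            picks.extend(rows[:take])
            remainder.append((quota - take, rows[take:]))
        # top up to the exact count from the largest fractional remainders
        remainder.sort(key=lambda t: -t[0])
        i = 0
        while len(picks) < n_mask and i < len(remainder):
            extra = remainder[i][1]
            if extra.size:
                picks.append(extra[0])
            i += 1
        mask_idx = np.sort(np.asarray(picks[:n_mask], dtype=int))
    else:
        mask_idx = np.sort(rng.choice(ds.n, size=n_mask, replace=False))
    if attr.kind == CATEGORICAL:
        for i in mask_idx:
            out.attribute_values[attribute][i] = None
    else:
        out.attribute_values[attribute][mask_idx] = np.nan
    return out, mask_idx
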