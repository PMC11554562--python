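"""Expression likelihood families: Gaussian, Poisson and zero-inflated
negative binomial (ZINB).

Each family parametrizes a per-cell, per-feature distribution of the
measured values.  The same graph-building code serves both training (with
gradients) and the public numpy-facing negative log-likelihood, so the
number the optimizer sees is by construction the number the API reports.

Conventions
-----------
* ZINB uses the mean/inverse-dispersion parametrization: a negative binomial
  with mean ``mu`` and shape ``theta`` (variance ``mu + mu^2/theta``), mixed
  with a point mass at zero whose mixing probability is
  ``sigmoid(zero_inflation_logit)``.
* The Gaussian ``dispersion`` field holds the variance.
* ``nll`` sums the exact log density over features, per cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._autodiff import Tensor

__all__ = [
    "GAUSSIAN",
    "POISSON",
    "ZINB",
    "FAMILIES",
    "ExpressionDistribution",
    "nll",
    "completeness_loss",
    "minimality_loss",
]

GAUSSIAN = "gaussian"
POISSON = "poisson"
ZINB = "zinb"
FAMILIES = (GAUSSIAN, ZINB, POISSON)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class ExpressionDistribution:
    """Per-cell, per-feature parametrization of the expression distribution.

    ``mean`` is n x M (strictly positive for count families).  ``dispersion``
    is the Gaussian variance or the ZINB inverse-dispersion ``theta``,
    broadcastable against ``mean`` (typically per-feature).
    ``zero_inflation_logit`` is ZINB-only.
    """

    family: str
    mean: np.ndarray
    dispersion: Optional[np.ndarray] = None
    zero_inflation_logit: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=np.float64))
        if not np.all(np.isfinite(self.mean)):
            raise ValueError("distribution means contain non-finite values")
        if self.family in (POISSON, ZINB) and np.any(self.mean <= 0):
            raise ValueError("count-family means must be strictly positive")
        if self.family in (GAUSSIAN, ZINB):
            if self.dispersion is None:
                raise ValueError(f"{self.family} requires a dispersion")
            self.dispersion = np.asarray(self.dispersion, dtype=np.float64)
            if np.any(self.dispersion <= 0) or not np.all(np.isfinite(self.dispersion)):
                raise ValueError("dispersion must be finite and strictly positive")
        if self.family == ZINB:
            if self.zero_inflation_logit is None:
                raise ValueError("zinb requires zero_inflation_logit")
            self.zero_inflation_logit = np.atleast_2d(
                np.asarray(self.zero_inflation_logit, dtype=np.float64)
            )
            if not np.all(np.isfinite(self.zero_inflation_logit)):
                raise ValueError("zero_inflation_logit contains non-finite values")

    @property
    def n(self) -> int:
        return self.mean.shape[0]

    @property
    def m(self) -> int:
        return self.mean.shape[1]

    def row(self, i: int) -> "ExpressionDistribution":
        disp = self.dispersion
        if disp is not None and disp.ndim == 2:
            disp = disp[i : i + 1]
        zil = self.zero_inflation_logit
        if zil is not None:
            zil = zil[i : i + 1]
        return ExpressionDistribution(self.family, self.mean[i : i + 1], disp, zil)


# ----------------------------------------------------------------------
# graph-building log-likelihoods (Tensor in, Tensor out)
# ----------------------------------------------------------------------


def gaussian_loglik(x: Tensor, mu: Tensor, var: Tensor) -> Tensor:
    resid = x - mu
    return (var.log() + Tensor(_LOG_2PI) + resid * resid / var) * (-0.5)


def poisson_loglik(x: Tensor, mu: Tensor) -> Tensor:
    return x * mu.log() - mu - (x + 1.0).lgamma()


def zinb_loglik(x: Tensor, mu: Tensor, theta: Tensor, zi_logit: Tensor) -> Tensor:
    """Stable ZINB log-pmf built from softplus/lgamma primitives.

    With mixing logit ``s`` (dropout probability ``sigmoid(s)``) and negative
    binomial ``NB(mu, theta)``::

        x = 0:  log( sigmoid(s) + (1-sigmoid(s)) * (theta/(theta+mu))^theta )
        x > 0:  log(1-sigmoid(s)) + log NB(x; mu, theta)
    """
    log_theta_mu = (theta + mu).log()
    t = theta * (theta.log() - log_theta_mu)  # log (theta/(theta+mu))^theta
    # log( sigmoid(s) + (1-sigmoid(s)) e^t ) = softplus(s - t) + t - softplus(s)
    case_zero = (zi_logit - t).softplus() + t - zi_logit.softplus()
    case_pos = (
        (-1.0) * zi_logit.softplus()
        + t
        + x * (mu.log() - log_theta_mu)
        + (x + theta).lgamma()
        - theta.lgamma()
        - (x + 1.0).lgamma()
    )
    zero_mask = (x.data == 0).astype(np.float64)
    return case_zero.mask(zero_mask) + case_pos.mask(1.0 - zero_mask)


def loglik_tensor(x: Tensor, family: str, mu: Tensor,
                  dispersion: Optional[Tensor] = None,
                  zi_logit: Optional[Tensor] = None) -> Tensor:
    if family == GAUSSIAN:
        return gaussian_loglik(x, mu, dispersion)
    if family == POISSON:
        return poisson_loglik(x, mu)
    if family == ZINB:
        return zinb_loglik(x, mu, dispersion, zi_logit)
    raise ValueError(f"unknown family {family!r}")


# ----------------------------------------------------------------------
# public numpy-facing losses
# ----------------------------------------------------------------------


def _check_support(x: np.ndarray, family: str):
    if not np.all(np.isfinite(x)):
        raise ValueError("observations contain non-finite values")
    if family in (POISSON, ZINB):
        if np.any(x < 0):
            raise ValueError(f"{family} observations must be non-negative counts")
        if np.any(x != np.round(x)):
            raise ValueError(f"{family} observations must be integer counts")


def nll(x: np.ndarray, dist: ExpressionDistribution, cell_index: Optional[int] = None
        ) -> np.ndarray:
    """Exact negative log density/pmf, summed over features, per cell.

    With ``cell_index`` given, ``x`` is a single observation vector scored
    against that row of ``dist`` and a scalar is returned; otherwise ``x``
    is n x M and an array of n per-cell values is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    scalar = cell_index is not None
    if scalar:
        dist = dist.row(cell_index)
        x = np.atleast_2d(x)
    else:
        x = np.atleast_2d(x)
    if x.shape != dist.mean.shape:
        raise ValueError(
            f"observation shape {x.shape} does not match distribution {dist.mean.shape}"
        )
    _check_support(x, dist.family)
    disp = None if dist.dispersion is None else Tensor(dist.dispersion)
    zil = None if dist.zero_inflation_logit is None else Tensor(dist.zero_inflation_logit)
    ll = loglik_tensor(Tensor(x), dist.family, Tensor(dist.mean), disp, zil)
    out = -ll.data.sum(axis=1)
    return float(out[0]) if scalar else out


def completeness_loss(x: np.ndarray, dist: ExpressionDistribution, tau: float = 1.0,
                      cell_index: Optional[int] = None):
    """NLL plus ``tau`` times the mean-squared error of the predicted means.

    The MSE is averaged over features; for count families both sides are
    log1p-transformed to keep the term commensurate across expression
    magnitudes, for Gaussian data raw values are compared.
    """
    base = nll(x, dist, cell_index=cell_index)
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    mu = dist.mean if cell_index is None else dist.mean[cell_index : cell_index + 1]
    if dist.family in (POISSON, ZINB):
        err = (np.log1p(x) - np.log1p(mu)) ** 2
    else:
        err = (x - mu) ** 2
    mse = err.mean(axis=1)
    out = base + tau * mse
    return float(out[0]) if cell_index is not None else out


def minimality_loss(z_u: np.ndarray, lam: float) -> float:
    """Activation penalty ``lambda * ||z_u||^2`` limiting the information the
    unknown-attribute code can carry."""
    z_u = np.asarray(z_u, dtype=np.float64)
    if not np.all(np.isfinite(z_u)):
        raise ValueError("z_u contains non-finite values")
    return float(lam * np.sum(z_u**2))
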