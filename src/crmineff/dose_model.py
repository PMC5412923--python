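"""One-parameter logistic dose-inefficacy model with a quadrature posterior.

The binary endpoint y_i ~ Bernoulli(p_i) is modelled through

    logit(p_i) = alpha - beta * d_i,        alpha fixed (default 5),

where d_i is the standardised dose (actual mg / 10) and beta > 0, so the
probability of inefficacy decreases monotonically with dose and is close
to 1 at dose zero.  The only unknown is the slope beta; its posterior is
one-dimensional and is computed exactly (up to discretisation) by midpoint
quadrature on a fixed grid, which makes every design decision in the
simulator deterministic given the data.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import expit, log_expit, logit

from .history import TrialHistory

__all__ = [
    "DoseGrid",
    "ModelSpec",
    "PosteriorSummary",
    "PosteriorUnderflowError",
    "inefficacy_probability",
    "backward_fit_standardised_dose",
    "log_likelihood",
    "posterior_update",
    "credible_interval",
]


class PosteriorUnderflowError(RuntimeError):
    """All posterior masses underflowed to zero (degenerate likelihood)."""


@dataclass(frozen=True)
class DoseGrid:
    """Available doses in mg, their standardised values, and the period-1 subset."""

    actual_mg: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80)
    standardised: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)
    period1_mg: tuple[int, ...] = (10, 20, 40, 80)

    def __post_init__(self) -> None:
        if len(self.actual_mg) != len(self.standardised):
            raise ValueError("actual_mg and standardised must have equal length")
        if any(b <= a for a, b in zip(self.actual_mg, self.actual_mg[1:])):
            raise ValueError("actual_mg must be strictly increasing")
        if any(b <= a for a, b in zip(self.standardised, self.standardised[1:])):
            raise ValueError("standardised must be strictly increasing")
        if not set(self.period1_mg) <= set(self.actual_mg):
            raise ValueError("period1_mg must be a subset of actual_mg")

    def standardised_of(self, dose_mg: int) -> float:
        try:
            return self.standardised[self.actual_mg.index(dose_mg)]
        except ValueError:
            raise ValueError(f"dose {dose_mg} mg not on the grid") from None


@dataclass(frozen=True)
class ModelSpec:
    """Fixed intercept, prior on the slope beta, and quadrature resolution.

    ``prior_name`` is one of ``uniform`` (params: lo, hi), ``exponential``
    (params: mean) or ``gamma`` (params: shape, scale).  The support is
    truncated to (0, beta_max]; at beta = beta_max even the lowest dose has
    inefficacy probability below 1%, so the truncation is immaterial for
    any realistic curve.  ``point_convention`` selects the per-dose point
    estimate used by decision rules: the plug-in curve at the posterior
    median of beta (default) or the posterior mean of each p_d.
    """

    intercept: float = 5.0
    prior_name: str = "uniform"
    prior_params: tuple[float, ...] = (0.0, 10.0)
    n_beta: int = 4001
    beta_max: float = 10.0
    point_convention: str = "plugin_median"

    def __post_init__(self) -> None:
        if self.prior_name not in ("uniform", "exponential", "gamma"):
            raise ValueError(f"unknown prior family {self.prior_name!r}")
        if self.point_convention not in ("plugin_median", "posterior_mean"):
            raise ValueError(f"unknown point convention {self.point_convention!r}")
        if self.n_beta < 2:
            raise ValueError("n_beta must be at least 2")

    def prior_logpdf(self, beta: np.ndarray) -> np.ndarray:
        if self.prior_name == "uniform":
            lo, hi = self.prior_params
            dist = stats.uniform(lo, hi - lo)
        elif self.prior_name == "exponential":
            (mean,) = self.prior_params
            dist = stats.expon(scale=mean)
        else:
            shape, scale = self.prior_params
            dist = stats.gamma(shape, scale=scale)
        return dist.logpdf(beta)

    def support_upper(self) -> float:
        if self.prior_name == "uniform":
            return min(self.beta_max, self.prior_params[1])
        return self.beta_max


def inefficacy_probability(beta: float | np.ndarray, d: float | np.ndarray, intercept: float = 5.0):
    """Probability of inefficacy at standardised dose d: expit(intercept - beta*d)."""
    if np.any(np.asarray(d) < 0):
        raise ValueError("standardised dose must be non-negative")
    return expit(intercept - np.asarray(beta) * np.asarray(d))


def backward_fit_standardised_dose(p: float, intercept: float = 5.0) -> float:
    """Standardise a dose from its anticipated inefficacy probability.

    Backward fitting at beta = 1 maps a probability p to the standardised
    dose intercept - logit(p); probabilities of exactly 0 or 1 have no
    finite image and are rejected.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be strictly between 0 and 1")
    return float(intercept - logit(p))


def log_likelihood(history: TrialHistory, beta: float, grid: DoseGrid, intercept: float = 5.0) -> float:
    """Bernoulli log-likelihood of the accumulated responses at slope beta."""
    n1, n0 = history.response_counts(grid.actual_mg)
    d = np.asarray(grid.standardised)
    eta = intercept - beta * d
    return float(n1 @ log_expit(eta) + n0 @ log_expit(-eta))


@dataclass
class PosteriorSummary:
    """Discretised posterior over beta and the induced per-dose summaries.

    Both point-estimate conventions are retained: ``p_plugin`` is the
    inefficacy curve evaluated at the posterior median of beta (the curve
    convention), ``p_mean`` is the posterior mean of each p_d.
    """

    beta_support: np.ndarray
    beta_weights: np.ndarray
    beta_median: float
    doses_mg: tuple[int, ...]
    standardised: tuple[float, ...]
    p_plugin: np.ndarray
    p_mean: np.ndarray
    ci_level: float
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    intercept: float = 5.0
    point_convention: str = "plugin_median"

    def point_estimates(self) -> np.ndarray:
        return self.p_plugin if self.point_convention == "plugin_median" else self.p_mean

    def estimate_at(self, dose_mg: int) -> float:
        return float(self.point_estimates()[self.doses_mg.index(dose_mg)])

    def to_dict(self) -> dict:
        return {
            "beta_median": self.beta_median,
            "ci_level": self.ci_level,
            "point_convention": self.point_convention,
            "per_dose": [
                {
                    "dose_mg": d,
                    "p_plugin": float(pp),
                    "p_mean": float(pm),
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                }
                for d, pp, pm, lo, hi in zip(
                    self.doses_mg, self.p_plugin, self.p_mean, self.ci_lo, self.ci_hi
                )
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _quantile(support: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Interpolated quantile of a piecewise-constant density on uniform cells.

    Treating each support point as the midpoint of a cell of equal width and
    interpolating linearly inside the cell makes quantiles vary smoothly as
    the grid is refined, instead of jumping by one cell width.
    """
    if len(support) == 1:
        return float(support[0])
    h = float(support[1] - support[0])
    cum = np.cumsum(weights)
    k = int(np.searchsorted(cum, q, side="left"))
    if k >= len(support):
        return float(support[-1] + h / 2)
    before = cum[k] - weights[k]
    frac = (q - before) / weights[k] if weights[k] > 0 else 0.0
    return float(support[k] - h / 2 + frac * h)


@lru_cache(maxsize=16)
def _quadrature_tables(spec: ModelSpec, grid: DoseGrid):
    """Cached beta support, log-prior and per-dose log-response matrices."""
    hi = spec.support_upper()
    edges = np.linspace(0.0, hi, spec.n_beta + 1)
    support = 0.5 * (edges[:-1] + edges[1:])
    log_prior = spec.prior_logpdf(support)
    d = np.asarray(grid.standardised)
    eta = spec.intercept - support[:, None] * d[None, :]
    return support, log_prior, log_expit(eta), log_expit(-eta)


def posterior_update(
    history: TrialHistory,
    spec: ModelSpec = ModelSpec(),
    grid: DoseGrid = DoseGrid(),
    ci_level: float = 0.90,
) -> PosteriorSummary:
    """Posterior over beta given the accumulated responses, with per-dose summaries.

    An empty history returns the (discretised) prior.  Masses are
    accumulated in log space with max-subtraction before exponentiation.
    """
    support, log_prior, l1, l0 = _quadrature_tables(spec, grid)
    n1, n0 = history.response_counts(grid.actual_mg)
    logpost = log_prior + l1 @ n1 + l0 @ n0
    m = np.max(logpost)
    if not np.isfinite(m):
        raise PosteriorUnderflowError("posterior masses all underflowed")
    w = np.exp(logpost - m)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise PosteriorUnderflowError("posterior masses all underflowed")
    w /= total

    med = _quantile(support, w, 0.5)
    d = np.asarray(grid.standardised)
    p_plugin = expit(spec.intercept - med * d)
    p_mean = w @ expit(spec.intercept - support[:, None] * d[None, :])
    b_lo = _quantile(support, w, (1 - ci_level) / 2)
    b_hi = _quantile(support, w, (1 + ci_level) / 2)
    # p is decreasing in beta, so the beta interval maps to a reversed p interval
    ci_lo = expit(spec.intercept - b_hi * d)
    ci_hi = expit(spec.intercept - b_lo * d)
    return PosteriorSummary(
        beta_support=support,
        beta_weights=w,
        beta_median=med,
        doses_mg=grid.actual_mg,
        standardised=grid.standardised,
        p_plugin=p_plugin,
        p_mean=p_mean,
        ci_level=ci_level,
        ci_lo=np.minimum(ci_lo, ci_hi),
        ci_hi=np.maximum(ci_lo, ci_hi),
        intercept=spec.intercept,
        point_convention=spec.point_convention,
    )


def credible_interval(post: PosteriorSummary, dose_mg: int, level: float) -> tuple[float, float]:
    """Central credible interval for the inefficacy probability at one dose.

    The interval is the image of the central beta interval under the
    monotone (decreasing) dose-inefficacy curve.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    d = post.standardised[post.doses_mg.index(dose_mg)]
    b_lo = _quantile(post.beta_support, post.beta_weights, (1 - level) / 2)
    b_hi = _quantile(post.beta_support, post.beta_weights, (1 + level) / 2)
    lo = float(expit(post.intercept - b_hi * d))
    hi = float(expit(post.intercept - b_lo * d))
    return (min(lo, hi), max(lo, hi))
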