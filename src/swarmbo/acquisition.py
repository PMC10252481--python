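"""Acquisition functions scoring candidate points from a GP posterior.

All four criteria map a :class:`~swarmbo.surrogate.Posterior` (predictive
mean μ(x) and standard deviation σ(x)) and the incumbent best observed value
f⁺ to a scalar score per point; the BO loop evaluates next wherever the
score is maximal.

* EI(x)  = (μ − f⁺ − ξ)·Φ(z) + σ·φ(z),  z = (μ − f⁺ − ξ)/σ  — expected
  positive exceedance of the incumbent; the BO default.
* PI(x)  = Φ(z) — probability of exceeding the incumbent.
* UCB(x) = μ + β·σ — optimistic bound; β > 0 trades exploitation for
  exploration.
* LCB(x) = −(μ − β·σ) — the negated pessimistic bound, maximized; with
  β > 0 this rewards uncertainty and low predicted mean, a deliberately
  exploration-heavy criterion.  A ``minimize_mu=False`` switch on the spec
  turns it into the conventional "maximize μ − β·σ" reading instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .surrogate import Posterior

__all__ = [
    "AcquisitionSpec",
    "expected_improvement",
    "probability_improvement",
    "upper_confidence_bound",
    "lower_confidence_bound",
    "score",
    "ACQUISITIONS",
]

ACQUISITIONS = ("EI", "PI", "UCB", "LCB")


@dataclass
class AcquisitionSpec:
    """Which criterion to use and its constants.

    beta is the confidence-bound trade-off (> 0), xi the EI/PI exploration
    jitter (≥ 0), f_best the incumbent objective value on the same scale as
    the posterior mean.  ``lcb_minimize_mu`` selects between the literal
    negated-bound LCB (default) and the conventional μ − β·σ form.
    """

    name: str
    beta: float = 1.96
    xi: float = 0.0
    f_best: float = 0.0
    lcb_minimize_mu: bool = True

    def __post_init__(self):
        if self.name not in ACQUISITIONS:
            raise ValueError(f"unknown acquisition {self.name!r}; "
                             f"choose from {ACQUISITIONS}")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.xi < 0:
            raise ValueError("xi must be >= 0")


def _improvement_terms(post: Posterior, spec: AcquisitionSpec):
    mu, sigma = post.mu, post.sigma
    delta = mu - spec.f_best - spec.xi
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, delta / np.where(sigma > 0, sigma, 1.0), 0.0)
    return delta, sigma, z


def expected_improvement(post: Posterior, spec: AcquisitionSpec) -> np.ndarray:
    """Closed-form EI under the Gaussian posterior; ≥ 0 elementwise."""
    delta, sigma, z = _improvement_terms(post, spec)
    ei = np.where(sigma > 0,
                  delta * norm.cdf(z) + sigma * norm.pdf(z),
                  np.maximum(delta, 0.0))
    return np.maximum(ei, 0.0)


def probability_improvement(post: Posterior, spec: AcquisitionSpec) -> np.ndarray:
    """P[f(x) > f⁺ + ξ] under the Gaussian posterior; in [0, 1]."""
    delta, sigma, z = _improvement_terms(post, spec)
    return np.where(sigma > 0, norm.cdf(z), (delta > 0).astype(float))


def upper_confidence_bound(post: Posterior, spec: AcquisitionSpec) -> np.ndarray:
    """μ + β·σ (maximization convention)."""
    return post.mu + spec.beta * post.sigma


def lower_confidence_bound(post: Posterior, spec: AcquisitionSpec) -> np.ndarray:
    """−(μ − β·σ) by default; μ − β·σ when ``lcb_minimize_mu`` is False."""
    if spec.lcb_minimize_mu:
        return -(post.mu - spec.beta * post.sigma)
    return post.mu - spec.beta * post.sigma


_DISPATCH = {
    "EI": expected_improvement,
    "PI": probability_improvement,
    "UCB": upper_confidence_bound,
    "LCB": lower_confidence_bound,
}


def score(post: Posterior, spec: AcquisitionSpec) -> np.ndarray:
    """Score a posterior batch under the criterion named in ``spec``."""
    return _DISPATCH[spec.name](post, spec)
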