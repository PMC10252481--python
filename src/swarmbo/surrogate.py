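"""Gaussian-process surrogate over the encoded unit cube.

The Bayesian-optimization loop models the objective (validation accuracy in
percent) with a GP regression on the ``[0, 1]^D`` encoding of the search
space.  The kernel is a constant amplitude times a Matérn ν=5/2 with a
single shared length-scale — smooth but not infinitely differentiable, the
de-facto default for hyperparameter surfaces — plus a small diagonal jitter
that also absorbs duplicate points with conflicting values.  Targets are
standardized internally (``normalize_y``), so accuracies spanning [15, 99]
pose no conditioning problem.  Kernel hyperparameters are set by maximum
marginal likelihood with a fixed number of seeded restarts, making refits
on identical data deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

__all__ = ["Observation", "Posterior", "SurrogateModel", "fit", "posterior"]

JITTER = 1e-6
SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class Observation:
    """One evaluated point: encoded location and objective value (percent)."""

    point: np.ndarray
    value: float

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if not np.isfinite(self.value):
            raise ValueError("observation value must be finite")


@dataclass(frozen=True)
class Posterior:
    """Predictive mean and standard deviation at a batch of query points."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if mu.shape != sigma.shape:
            raise ValueError("mu and sigma must have equal length")
        if sigma.size and sigma.min() < 0:
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    def __len__(self) -> int:
        return len(self.mu)


class SurrogateModel:
    """Fitted GP surrogate; query it through :func:`posterior`."""

    def __init__(self, gp: GaussianProcessRegressor, dim: int):
        self._gp = gp
        self.dim = dim

    def predict(self, X: np.ndarray) -> Posterior:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[0] == 0:
            return Posterior(np.empty(0), np.empty(0))
        if X.shape[1] != self.dim:
            raise ValueError(f"expected dimension {self.dim}, got {X.shape[1]}")
        mu, sigma = self._gp.predict(X, return_std=True)
        return Posterior(mu, np.maximum(sigma, SIGMA_FLOOR))


def fit(observations: Sequence[Observation], seed: int = 0,
        n_restarts: int = 3) -> SurrogateModel:
    """Fit the GP surrogate to a non-empty list of observations.

    Points are sorted into a canonical order before fitting so the result is
    invariant to permutations of the input list.
    """
    if len(observations) == 0:
        raise ValueError("need at least one observation")
    X = np.vstack([np.atleast_1d(o.point) for o in observations]).astype(float)
    y = np.array([o.value for o in observations], dtype=float)
    if X.ndim != 2 or len({row.shape for row in X}) > 1:
        raise ValueError("all points must share one dimension")
    order = np.lexsort(np.vstack([y, X.T[::-1]]))
    X, y = X[order], y[order]

    # length-scale bounds sized to the unit cube (diameter sqrt(D)): an
    # unconstrained ML fit on plateau-like data degenerates to "spike"
    # (l -> 0, acquisition flat) or "flat" (l -> inf, sigma constant),
    # either of which blinds the acquisition functions
    kernel = ConstantKernel(1.0, (1e-4, 1e2)) * Matern(
        length_scale=0.5, length_scale_bounds=(0.1, 3.0), nu=2.5)
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=JITTER,
        normalize_y=True,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
    )
    with warnings.catch_warnings():
        # length-scale bounds are intentionally finite; hitting one on a
        # near-constant plateau of observations is expected, not an error
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return SurrogateModel(gp, X.shape[1])


def posterior(model: SurrogateModel, points: Sequence) -> Posterior:
    """Predictive mean/σ of the fitted surrogate at ``points``."""
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return Posterior(np.empty(0), np.empty(0))
    return model.predict(pts)
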