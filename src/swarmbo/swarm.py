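"""Swarm metaheuristics maximizing a scalar function over the unit box.

Four population-based optimizers — particle swarm (PSO), artificial bee
colony (ABC), Harris hawks (HHO) and sailfish (SFO) — share one contract:
maximize ``f`` over ``[0, 1]^D``, where ``f`` accepts an ``(n, D)`` batch of
points and returns ``n`` values.  They serve both as standalone optimizers
and as the acquisition-surface maximizers inside the Bayesian-optimization
loop.  A multi-start random-search baseline completes the registry.

Shared conventions
------------------
* Out-of-box moves are clipped to ``[0, 1]`` (never reflected).
* Non-finite objective values are treated as −∞ and never selected.
* Ties in best selection break toward the lowest index.
* Everything is driven by one ``numpy.random.Generator``; identical
  parameters give bit-identical results.
* The best-so-far history is non-decreasing by construction and the total
  number of objective calls is bounded by ``population * (iterations + 1) * c``
  with c = 1 (PSO), 3 (ABC, counting scouts), 2 (HHO, counting rapid dives),
  2 (SFO, counting sardine respawns).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "SwarmParams",
    "SwarmResult",
    "pso_maximize",
    "abc_maximize",
    "hho_maximize",
    "sfo_maximize",
    "random_maximize",
    "maximize",
    "OPTIMIZERS",
]


@dataclass
class SwarmParams:
    """Population sizes, budgets and per-algorithm constants.

    PSO uses inertia ``w``, cognitive/social weights ``c1``/``c2`` and a
    velocity clamp (fraction of the box width).  ABC uses ``sn`` food
    sources and a stagnation ``limit`` (default ``sn * dim``) after which a
    source is abandoned to a scout.  HHO uses the Levy-flight exponent of
    its rapid dives.  SFO uses attack constant ``A``, decay ``epsilon`` and
    the sailfish fraction of the total population.
    """

    population: int = 30
    iterations: int = 50
    seed: int = 0
    # PSO
    w: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    clamp_fraction: float = 0.5
    # ABC
    sn: int = 15
    limit: Optional[int] = None
    # HHO
    levy_exponent: float = 1.5
    # SFO
    sfo_attack: float = 4.0
    sfo_decay: float = 0.001
    sailfish_fraction: float = 0.3
    # random baseline
    random_samples: int = 1000
    polish_steps: int = 50

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sn < 2:
            raise ValueError("sn must be >= 2")
        if self.limit is not None and self.limit < 1:
            raise ValueError("limit must be >= 1")


@dataclass
class SwarmResult:
    """Outcome of one metaheuristic run."""

    best_point: np.ndarray
    best_value: float
    history: np.ndarray          # best-so-far value after each iteration
    evaluations: int             # total objective calls
    final_population: np.ndarray  # last population, best-first order
    final_values: np.ndarray


class _Tracker:
    """Evaluates batches, sanitizes non-finite values, tracks the best."""

    def __init__(self, f: Callable[[np.ndarray], np.ndarray]):
        self.f = f
        self.evaluations = 0
        self.best_point: Optional[np.ndarray] = None
        self.best_value = -np.inf

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        y = np.asarray(self.f(X), dtype=float).ravel()
        y = np.where(np.isfinite(y), y, -np.inf)
        self.evaluations += X.shape[0]
        i = int(np.argmax(y))
        if y[i] > self.best_value:
            self.best_value = float(y[i])
            self.best_point = X[i].copy()
        return y

    def result(self, history, population, values) -> SwarmResult:
        order = np.argsort(-values, kind="stable")
        return SwarmResult(
            best_point=self.best_point.copy(),
            best_value=self.best_value,
            history=np.asarray(history, dtype=float),
            evaluations=self.evaluations,
            final_population=np.atleast_2d(population)[order],
            final_values=values[order],
        )


def _init_population(n: int, dim: int, rng: np.random.Generator,
                     init: Optional[np.ndarray]) -> np.ndarray:
    if init is not None:
        X = np.atleast_2d(np.asarray(init, dtype=float)).copy()
        if X.shape != (n, dim):
            raise ValueError(f"init must have shape {(n, dim)}")
        return np.clip(X, 0.0, 1.0)
    return rng.random((n, dim))


def pso_maximize(f, dim: int, params: SwarmParams,
                 init: Optional[np.ndarray] = None) -> SwarmResult:
    """Canonical inertia-weight particle swarm.

    v ← w·v + c1·r1∘(pbest − x) + c2·r2∘(gbest − x), velocities clamped to
    ±clamp_fraction, positions clipped to the box.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(params.seed)
    track = _Tracker(f)
    n = params.population
    X = _init_population(n, dim, rng, init)
    # canonical uniform velocity init; an explicit population starts at rest
    vmax0 = params.clamp_fraction
    V = (np.zeros((n, dim)) if init is not None
         else rng.uniform(-vmax0, vmax0, (n, dim)))
    y = track(X)
    pbest, pval = X.copy(), y.copy()
    g = int(np.argmax(pval))
    history = []
    vmax = params.clamp_fraction
    for _ in range(params.iterations):
        r1, r2 = rng.random((n, dim)), rng.random((n, dim))
        V = (params.w * V
             + params.c1 * r1 * (pbest - X)
             + params.c2 * r2 * (pbest[g] - X))
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, 0.0, 1.0)
        y = track(X)
        better = y > pval
        pbest[better], pval[better] = X[better], y[better]
        g = int(np.argmax(pval))
        history.append(track.best_value)
    return track.result(history, pbest, pval)


def abc_maximize(f, dim: int, params: SwarmParams,
                 init: Optional[np.ndarray] = None) -> SwarmResult:
    """Canonical artificial bee colony with employed/onlooker/scout phases.

    A food source stagnating longer than ``limit`` trials is abandoned and
    redrawn uniformly by a scout.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(params.seed)
    track = _Tracker(f)
    sn = params.sn
    limit = params.limit if params.limit is not None else sn * dim
    X = _init_population(sn, dim, rng, init)
    y = track(X)
    trials = np.zeros(sn, dtype=int)

    def neighbour(i: int) -> None:
        j = rng.integers(dim)
        k = rng.integers(sn - 1)
        k = k + 1 if k >= i else k
        phi = rng.uniform(-1.0, 1.0)
        v = X[i].copy()
        v[j] = np.clip(v[j] + phi * (v[j] - X[k, j]), 0.0, 1.0)
        fv = track(v[None, :])[0]
        if fv > y[i]:
            X[i], y[i] = v, fv
            trials[i] = 0
        else:
            trials[i] += 1

    history = []
    for _ in range(params.iterations):
        for i in range(sn):                      # employed phase
            neighbour(i)
        finite = np.isfinite(y)                  # onlooker phase
        if finite.any():
            w = np.where(finite, y - y[finite].min() + 1e-12, 0.0)
        else:
            w = np.ones(sn)
        p = w / w.sum() if w.sum() > 0 else np.full(sn, 1.0 / sn)
        for i in rng.choice(sn, size=sn, p=p):
            neighbour(int(i))
        worn = np.nonzero(trials > limit)[0]     # scout phase
        for i in worn:
            X[i] = rng.random(dim)
            y[i] = track(X[i][None, :])[0]
            trials[i] = 0
        history.append(track.best_value)
    return track.result(history, X, y)


def _levy_steps(rng: np.random.Generator, shape, beta: float) -> np.ndarray:
    """Mantegna's heavy-tailed Levy-flight step generator."""
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma_u = (num / den) ** (1 / beta)
    u = rng.normal(0.0, sigma_u, shape)
    v = rng.normal(0.0, 1.0, shape)
    return u / np.abs(v) ** (1 / beta)


def hho_maximize(f, dim: int, params: SwarmParams,
                 init: Optional[np.ndarray] = None) -> SwarmResult:
    """Canonical Harris hawks optimization with greedy acceptance.

    Escape energy E = 2·E0·(1 − t/T) gates exploration (|E| ≥ 1: perch on a
    random hawk or around the mean) against four besiege branches selected
    by |E| ≷ 0.5 and the prey's escape chance r ≷ 0.5; the rapid-dive
    branches take Levy-flight steps and keep the better of dive and current
    position (greedy), while the other branches move unconditionally — the
    population must keep drifting for the besiege steps, whose size shrinks
    with the hawk-to-prey distance, to refine the solution.  The returned
    best is tracked over every evaluation, so the history stays monotone.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(params.seed)
    track = _Tracker(f)
    n = params.population
    X = _init_population(n, dim, rng, init)
    y = track(X)
    T = params.iterations
    history = []

    def accept(i, cand):
        cand = np.clip(cand, 0.0, 1.0)
        fv = track(cand[None, :])[0]
        X[i], y[i] = cand, fv

    for t in range(1, T + 1):
        decay = 1.0 - t / T
        best = X[int(np.argmax(y))].copy()
        mean_pos = X.mean(axis=0)
        for i in range(n):
            E = 2.0 * rng.uniform(-1.0, 1.0) * decay
            J = 2.0 * (1.0 - rng.random())
            if abs(E) >= 1.0:                            # exploration
                if rng.random() >= 0.5:
                    Xr = X[rng.integers(n)]
                    cand = Xr - rng.random() * np.abs(Xr - 2 * rng.random() * X[i])
                else:
                    cand = (best - mean_pos) - rng.random() * rng.random(dim)
                accept(i, cand)
            elif rng.random() >= 0.5:                    # besiege, no dive
                if abs(E) >= 0.5:
                    cand = (best - X[i]) - E * np.abs(J * best - X[i])
                else:
                    cand = best - E * np.abs(best - X[i])
                accept(i, cand)
            else:                                        # rapid dives
                ref = X[i] if abs(E) >= 0.5 else mean_pos
                Y = np.clip(best - E * np.abs(J * best - ref), 0.0, 1.0)
                Z = np.clip(Y + rng.random(dim)
                            * _levy_steps(rng, dim, params.levy_exponent),
                            0.0, 1.0)
                fy, fz = track(np.vstack([Y, Z]))
                if fy >= fz and fy > y[i]:
                    X[i], y[i] = Y, fy
                elif fz > y[i]:
                    X[i], y[i] = Z, fz
        history.append(track.best_value)
    return track.result(history, X, y)


def sfo_maximize(f, dim: int, params: SwarmParams,
                 init: Optional[np.ndarray] = None) -> SwarmResult:
    """Canonical sailfish optimizer.

    Sailfish intensify around the elite sailfish / injured sardine with
    λ = 2·rand·PD − PD, PD = 1 − N_SF/(N_SF + N_S); sardines diversify under
    attack power AP = A·(1 − 2·t·ε) — all sardines and dimensions when
    AP ≥ 0.5, otherwise a random AP-sized subset of each.  Any sardine
    fitter than the worst sailfish is hunted (absorbed) and respawned.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(params.seed)
    track = _Tracker(f)
    n = params.population
    n_sf = min(max(1, round(params.sailfish_fraction * n)), n - 1)
    n_s = n - n_sf
    if init is not None:
        init = np.atleast_2d(np.asarray(init, dtype=float))
        SF = np.clip(init[:n_sf].copy(), 0.0, 1.0)
        S = np.clip(init[n_sf:n_sf + n_s].copy(), 0.0, 1.0)
    else:
        SF = rng.random((n_sf, dim))
        S = rng.random((n_s, dim))
    y_sf = track(SF)
    y_s = track(S)
    pd = 1.0 - n_sf / (n_sf + n_s)
    history = []
    for t in range(1, params.iterations + 1):
        elite = SF[int(np.argmax(y_sf))].copy()
        injured = S[int(np.argmax(y_s))].copy()
        lam = 2.0 * rng.random((n_sf, 1)) * pd - pd
        SF = np.clip(elite - lam * (rng.random((n_sf, 1))
                                    * (elite + injured) / 2.0 - SF), 0.0, 1.0)
        y_sf = track(SF)

        ap = params.sfo_attack * (1.0 - 2.0 * t * params.sfo_decay)
        if ap >= 0.5:
            S = np.clip(rng.random((n_s, dim)) * (elite - S + ap), 0.0, 1.0)
        else:
            alpha = max(1, int(round(abs(ap) * n_s)))
            beta = max(1, int(round(abs(ap) * dim)))
            rows = rng.choice(n_s, size=alpha, replace=False)
            for i in rows:
                cols = rng.choice(dim, size=beta, replace=False)
                S[i, cols] = np.clip(
                    rng.random(beta) * (elite - S[i] + ap)[cols], 0.0, 1.0)
        y_s = track(S)

        # hunt: absorb any sardine fitter than the worst sailfish
        for i in np.argsort(-y_s, kind="stable"):
            worst = int(np.argmin(y_sf))
            if y_s[i] > y_sf[worst]:
                SF[worst], y_sf[worst] = S[i].copy(), y_s[i]
                S[i] = rng.random(dim)
                y_s[i] = track(S[i][None, :])[0]
            else:
                break
        history.append(track.best_value)
    pop = np.vstack([SF, S])
    vals = np.concatenate([y_sf, y_s])
    return track.result(history, pop, vals)


def random_maximize(f, dim: int, params: SwarmParams,
                    init: Optional[np.ndarray] = None) -> SwarmResult:
    """Multi-start baseline: best of uniform samples plus coordinate polish.

    Draws ``random_samples`` uniform points, then refines the best with
    ``polish_steps`` single-coordinate Gaussian perturbations of shrinking
    width, accepting improvements.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = np.random.default_rng(params.seed)
    track = _Tracker(f)
    X = rng.random((params.random_samples, dim))
    if init is not None:
        X = np.vstack([np.clip(np.atleast_2d(init), 0.0, 1.0), X])
    y = track(X)
    best = X[int(np.argmax(y))].copy()
    fbest = float(np.max(y))
    history = [track.best_value]
    for step in range(params.polish_steps):
        j = step % dim
        width = 0.25 * (1.0 - step / max(params.polish_steps, 1)) + 0.01
        cand = best.copy()
        cand[j] = np.clip(cand[j] + rng.normal(0.0, width), 0.0, 1.0)
        fc = track(cand[None, :])[0]
        if fc > fbest:
            best, fbest = cand, float(fc)
        history.append(track.best_value)
    order = np.argsort(-y, kind="stable")[:min(len(y), 50)]
    return track.result(history, X[order], y[order])


OPTIMIZERS = {
    "pso": pso_maximize,
    "abc": abc_maximize,
    "hho": hho_maximize,
    "sfo": sfo_maximize,
    "random": random_maximize,
}


def maximize(name: str, f, dim: int, params: SwarmParams,
             init: Optional[np.ndarray] = None) -> SwarmResult:
    """Dispatch to a registered maximizer by name."""
    try:
        fn = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; "
                         f"choose from {sorted(OPTIMIZERS)}") from None
    return fn(f, dim, params, init=init)
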