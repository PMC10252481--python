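"""The Bayesian-optimization loop with metaheuristic acquisition maximization.

One run evaluates a fixed shared starting configuration, then repeatedly
(1) fits the Gaussian-process surrogate to all observations, (2) scores
candidate points with the chosen acquisition function, (3) maximizes that
acquisition surface over the encoded unit cube with a swarm metaheuristic
(or the random multi-start baseline), and (4) evaluates the decoded argmax,
until the evaluation budget ``n_iter`` is spent.  Proposals that duplicate
an already-evaluated configuration are replaced by the best unseen candidate
from the maximizer's final population, so no evaluation of the small budget
is wasted re-measuring a known point.
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from . import refdata
from .acquisition import AcquisitionSpec, score
from .space import Configuration, HyperparameterSpace
from .surrogate import Observation, SurrogateModel, fit
from .swarm import SwarmParams, SwarmResult, maximize

__all__ = ["BOSettings", "TrialRecord", "Trace", "propose_next", "run_bo",
           "default_initial_config", "read_trace_csv"]

log = logging.getLogger(__name__)

ACQ_OPTIMIZERS = ("random", "pso", "abc", "hho", "sfo")

#: Objective floor used when an objective returns a non-finite value.
VALUE_FLOOR = 0.0


def default_initial_config() -> Configuration:
    """The shared first-iteration configuration of the reference study."""
    return dict(refdata.INITIAL_CONFIG)


@dataclass
class BOSettings:
    """Everything one BO run needs besides the objective and the space."""

    n_iter: int = 11
    acquisition: AcquisitionSpec = field(
        default_factory=lambda: AcquisitionSpec("EI"))
    acq_optimizer: str = "random"
    swarm: SwarmParams = field(default_factory=SwarmParams)
    initial: Optional[Configuration] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_iter < 2:
            raise ValueError("n_iter must be >= 2")
        if self.acq_optimizer not in ACQ_OPTIMIZERS:
            raise ValueError(f"acq_optimizer must be one of {ACQ_OPTIMIZERS}")


@dataclass(frozen=True)
class TrialRecord:
    """One evaluated configuration and its objective value (percent)."""

    iteration: int
    config: Configuration
    value: float


@dataclass
class Trace:
    """A completed (or aborted) BO run."""

    records: list
    settings: BOSettings
    error: Optional[str] = None

    @property
    def values(self) -> np.ndarray:
        return np.array([r.value for r in self.records], dtype=float)

    @property
    def best_value(self) -> float:
        return float(self.values.max())

    @property
    def best_config(self) -> Configuration:
        return self.records[int(np.argmax(self.values))].config

    def incumbent_curve(self) -> np.ndarray:
        """Running maximum of the per-iteration values."""
        return np.maximum.accumulate(self.values)

    # -- writers -----------------------------------------------------------

    def to_csv(self, space: HyperparameterSpace) -> str:
        """Table-style CSV: Iteration, one column per parameter, accuracy."""
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["Iteration", *space.names, "Validation Accuracy (%)"])
        for r in self.records:
            writer.writerow([r.iteration,
                             *[r.config[n] for n in space.names],
                             f"{r.value:.2f}"])
        return buf.getvalue()

    def to_json(self) -> str:
        payload = {
            "settings": {
                "n_iter": self.settings.n_iter,
                "acquisition": asdict(self.settings.acquisition),
                "acq_optimizer": self.settings.acq_optimizer,
                "swarm": asdict(self.settings.swarm),
                "initial": self.settings.initial,
                "seed": self.settings.seed,
            },
            "error": self.error,
            "records": [
                {"iteration": r.iteration, "config": r.config, "value": r.value}
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=2)


def read_trace_csv(text: str, space: HyperparameterSpace) -> list:
    """Parse a trace CSV written by :meth:`Trace.to_csv` back into records."""
    rows = list(csv.reader(io.StringIO(text)))
    header, body = rows[0], rows[1:]
    expected = ["Iteration", *space.names, "Validation Accuracy (%)"]
    if header != expected:
        raise ValueError(f"unexpected trace header {header}")
    records = []
    for row in body:
        config = {}
        for p, cell in zip(space.params, row[1:-1]):
            if p.is_categorical:
                config[p.name] = cell
            elif p.kind == "integer":
                config[p.name] = int(cell)
            else:
                config[p.name] = float(cell)
        records.append(TrialRecord(int(row[0]), config, float(row[-1])))
    return records


def _config_key(space: HyperparameterSpace, config: Configuration) -> tuple:
    out = []
    for p in space:
        v = config[p.name]
        out.append(v if p.is_categorical or p.kind == "integer"
                   else round(float(v), 12))
    return tuple(out)


def propose_next(model: SurrogateModel, space: HyperparameterSpace,
                 spec: AcquisitionSpec, optimizer: str,
                 swarm_params: SwarmParams,
                 seen: Sequence[Configuration] = (),
                 rng: Optional[np.random.Generator] = None) -> Configuration:
    """Maximize the acquisition surface and decode the winning point.

    ``spec.f_best`` must already hold the incumbent maximum.  If the decoded
    argmax was already evaluated (``seen``), the best not-yet-evaluated
    candidate from the maximizer's final population is substituted; if every
    candidate is seen, an unseen uniform sample is drawn.
    """
    rng = rng if rng is not None else np.random.default_rng(swarm_params.seed)

    def surface(U: np.ndarray) -> np.ndarray:
        return score(model.predict(U), spec)

    result: SwarmResult = maximize(optimizer, surface, space.dimension,
                                   swarm_params)
    seen_keys = {_config_key(space, c) for c in seen}

    if not np.isfinite(result.best_value):
        log.warning("acquisition maximizer returned a non-finite best; "
                    "falling back to a uniform random proposal")
    else:
        for point in result.final_population:
            config = space.decode(np.clip(point, 0.0, 1.0))
            if _config_key(space, config) not in seen_keys:
                return config
    for _ in range(1000):
        config = space.decode(rng.random(space.dimension))
        if _config_key(space, config) not in seen_keys:
            return config
    return space.decode(rng.random(space.dimension))  # saturated tiny space


def run_bo(objective: Callable[[Configuration], float],
           space: HyperparameterSpace, settings: BOSettings) -> Trace:
    """Run one full BO loop and return its trace.

    Iteration 1 evaluates the fixed initial configuration; each later
    iteration refits the surrogate on all observations, sets the incumbent,
    proposes via :func:`propose_next` and evaluates.  Fully reproducible
    given ``settings.seed``.
    """
    initial = (dict(settings.initial) if settings.initial is not None
               else default_initial_config())
    space.validate(initial)
    rng = np.random.default_rng(settings.seed)
    records: list[TrialRecord] = []
    observations: list[Observation] = []
    error = None

    def evaluate(config: Configuration, iteration: int) -> None:
        value = float(objective(config))
        if not np.isfinite(value):
            log.warning("objective returned a non-finite value at iteration "
                        "%d; recording the domain floor %.2f",
                        iteration, VALUE_FLOOR)
            value = VALUE_FLOOR
        records.append(TrialRecord(iteration, dict(config), value))
        observations.append(Observation(space.encode(config), value))

    try:
        evaluate(initial, 1)
        for it in range(2, settings.n_iter + 1):
            model = fit(observations, seed=settings.seed,
                        n_restarts=3)
            spec = AcquisitionSpec(
                name=settings.acquisition.name,
                beta=settings.acquisition.beta,
                xi=settings.acquisition.xi,
                f_best=max(o.value for o in observations),
                lcb_minimize_mu=settings.acquisition.lcb_minimize_mu,
            )
            swarm_params = SwarmParams(**{
                **asdict(settings.swarm),
                "seed": int(rng.integers(2 ** 31 - 1)),
            })
            config = propose_next(model, space, spec, settings.acq_optimizer,
                                  swarm_params,
                                  seen=[r.config for r in records], rng=rng)
            evaluate(config, it)
    except Exception as exc:  # aborted trace keeps what was measured
        log.error("BO run aborted at iteration %d: %s", len(records) + 1, exc)
        error = f"{type(exc).__name__}: {exc}"

    return Trace(records=records, settings=settings, error=error)
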