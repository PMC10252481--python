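"""Shared fixtures: spaces, objectives, and the (expensive) BO variant suite."""

import warnings

import numpy as np
import pytest

from swarmbo.experiments import default_plateau_suite
from swarmbo.space import HyperparameterSpace, ParamSpec, define_vgg_space
from swarmbo.swarm import SwarmParams
from swarmbo.synthbench import PlateauObjective

# BO-suite study conditions: 11-evaluation budget as in the reference runs,
# 50 paired seeds, acquisition maximization at a 20x30 swarm budget.
SUITE_SEED = 1234
SUITE_REPEATS = 50
SUITE_SWARM = dict(population=20, iterations=30)


@pytest.fixture(scope="session")
def vgg_space():
    return define_vgg_space()


@pytest.fixture(scope="session")
def toy_space():
    """A fully enumerable 3-parameter space (2 x 3 x 4 = 24 configurations)."""
    return HyperparameterSpace((
        ParamSpec("act", "boolean"),
        ParamSpec("depth", "integer", 1, 3),
        ParamSpec("opt", "categorical",
                  categories=("SGD", "ADAM", "RMSprop", "Adadelta")),
    ))


@pytest.fixture(scope="session")
def plateau(vgg_space):
    return PlateauObjective(vgg_space)


@pytest.fixture(scope="session")
def bo_suite():
    """All eight acquisition variants plus the pure-random baseline.

    50 paired seeds on the default plateau objective; shared session-wide
    because it is by far the most expensive fixture.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        traces, baseline = default_plateau_suite(
            master_seed=SUITE_SEED, repeats=SUITE_REPEATS,
            swarm=SwarmParams(seed=SUITE_SEED, **SUITE_SWARM))
    return traces, baseline
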