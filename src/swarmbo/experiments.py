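"""Reproducible multi-variant experiment driver.

A *variant* names an acquisition strategy: plain EI/PI/UCB/LCB maximized by
the random multi-start baseline, or EI maximized by one of the four swarm
metaheuristics (EI-PSO, EI-ABC, EI-HHO, EI-SFO).  The driver runs every
requested variant for ``repeats`` paired repetitions on one objective:
repeat ``r`` of every variant derives its BO seed as ``master_seed + r`` and
its objective-noise seed as ``master_seed + NOISE_SEED_OFFSET + r``, so all
variants face identical noise streams and differences are attributable to
the acquisition strategy alone.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .acquisition import AcquisitionSpec
from .bo import BOSettings, Trace, run_bo
from .space import HyperparameterSpace, define_vgg_space
from .swarm import SwarmParams
from .synthbench import PlateauObjective, PlateauParams

__all__ = ["VARIANTS", "variant_settings", "run_variant_suite",
           "random_search_baseline", "NOISE_SEED_OFFSET"]

#: variant name -> (acquisition name, acquisition maximizer)
VARIANTS = {
    "EI": ("EI", "random"),
    "PI": ("PI", "random"),
    "UCB": ("UCB", "random"),
    "LCB": ("LCB", "random"),
    "EI-PSO": ("EI", "pso"),
    "EI-ABC": ("EI", "abc"),
    "EI-HHO": ("EI", "hho"),
    "EI-SFO": ("EI", "sfo"),
}

NOISE_SEED_OFFSET = 90_000


def variant_settings(variant: str, seed: int, n_iter: int = 11,
                     swarm: Optional[SwarmParams] = None,
                     beta: float = 1.96, xi: float = 0.0) -> BOSettings:
    """BOSettings for one named variant."""
    try:
        acq, optimizer = VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {sorted(VARIANTS)}") from None
    return BOSettings(
        n_iter=n_iter,
        acquisition=AcquisitionSpec(acq, beta=beta, xi=xi),
        acq_optimizer=optimizer,
        swarm=swarm if swarm is not None else SwarmParams(),
        seed=seed,
    )


def run_variant_suite(objective, space: HyperparameterSpace,
                      variants: Sequence[str], repeats: int, master_seed: int,
                      n_iter: int = 11,
                      swarm: Optional[SwarmParams] = None) -> dict:
    """Run every variant ``repeats`` times with paired seeds.

    ``objective`` is either a callable Configuration -> percent or a
    factory accepting no arguments; objects exposing ``reset_noise`` (such
    as :class:`~swarmbo.synthbench.PlateauObjective`) get their noise
    stream re-seeded identically for repeat r of every variant.
    """
    results: dict[str, list[Trace]] = {}
    for variant in variants:
        runs = []
        for r in range(repeats):
            if hasattr(objective, "reset_noise"):
                objective.reset_noise(master_seed + NOISE_SEED_OFFSET + r)
            settings = variant_settings(variant, seed=master_seed + r,
                                        n_iter=n_iter, swarm=swarm)
            runs.append(run_bo(objective, space, settings))
        results[variant] = runs
    return results


def random_search_baseline(objective, space: HyperparameterSpace,
                           repeats: int, master_seed: int,
                           n_iter: int = 11) -> list:
    """Pure-random design of the same budget, paired with the suite's seeds.

    Returns one array of ``n_iter`` objective values per repeat.
    """
    out = []
    for r in range(repeats):
        if hasattr(objective, "reset_noise"):
            objective.reset_noise(master_seed + NOISE_SEED_OFFSET + r)
        rng = np.random.default_rng(master_seed + r)
        configs = space.sample(n_iter, rng)
        out.append(np.array([float(objective(c)) for c in configs]))
    return out


def default_plateau_suite(master_seed: int, repeats: int,
                          variants: Sequence[str] = tuple(VARIANTS),
                          n_iter: int = 11,
                          swarm: Optional[SwarmParams] = None,
                          noise_sd: float = 0.0):
    """Convenience wrapper: the default plateau objective on the VGG space."""
    space = define_vgg_space()
    objective = PlateauObjective(space, PlateauParams(noise_sd=noise_sd))
    traces = run_variant_suite(objective, space, variants, repeats,
                               master_seed, n_iter=n_iter, swarm=swarm)
    baseline = random_search_baseline(objective, space, repeats, master_seed,
                                      n_iter=n_iter)
    return traces, baseline
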