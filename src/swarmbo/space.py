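"""Mixed hyperparameter search spaces and their unit-cube encoding.

A :class:`HyperparameterSpace` is an ordered list of typed parameters
(continuous, log-continuous, integer, categorical, boolean).  Every
configuration maps to a point in ``[0, 1]^D`` so that continuous optimizers
(the swarm metaheuristics, the Gaussian-process surrogate) can operate on a
single box domain regardless of parameter type:

* continuous kinds map affinely onto ``[0, 1]``;
* log-continuous kinds map affinely in ``log10``;
* integer value ``i`` with bounds ``[lo, hi]`` maps to the centre of its bin,
  ``(i - lo + 0.5) / (hi - lo + 1)``;
* category index ``c`` of ``k`` categories maps to ``(c + 0.5) / k``.

Centre-of-bin encoding gives every discrete cell equal measure under uniform
sampling on the cube; decoding floor-bins, with the top edge assigned to the
last bin, so ``decode(encode(c)) == c`` for every valid configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ParamSpec",
    "HyperparameterSpace",
    "Configuration",
    "define_vgg_space",
    "SpaceValidationError",
]

#: Configurations are plain dicts, name -> value, one entry per parameter.
Configuration = dict

KINDS = ("continuous", "log-continuous", "integer", "categorical", "boolean")

BOOL_CATEGORIES = ("FALSE", "TRUE")


class SpaceValidationError(ValueError):
    """A parameter spec, configuration or encoded point violates the space."""


@dataclass(frozen=True)
class ParamSpec:
    """One typed dimension of a search space.

    Parameters
    ----------
    name : str
        Unique identifier.
    kind : str
        One of ``continuous``, ``log-continuous``, ``integer``,
        ``categorical``, ``boolean``.
    lower, upper : float, optional
        Inclusive bounds (continuous / log-continuous / integer kinds).
    categories : tuple of str, optional
        Ordered labels (categorical kind).  A boolean parameter is a
        categorical with exactly ``("FALSE", "TRUE")``.
    """

    name: str
    kind: str
    lower: float | None = None
    upper: float | None = None
    categories: tuple = ()

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SpaceValidationError(f"unknown kind {self.kind!r}")
        if self.kind == "boolean":
            object.__setattr__(self, "categories", BOOL_CATEGORIES)
        if self.kind in ("continuous", "log-continuous", "integer"):
            if self.lower is None or self.upper is None:
                raise SpaceValidationError(f"{self.name}: bounds required")
            if not (self.lower < self.upper):
                raise SpaceValidationError(f"{self.name}: lower must be < upper")
            if self.kind == "log-continuous" and self.lower <= 0:
                raise SpaceValidationError(f"{self.name}: log scale needs lower > 0")
        elif self.kind == "categorical":
            if not self.categories:
                raise SpaceValidationError(f"{self.name}: categories required")
            if len(set(self.categories)) != len(self.categories):
                raise SpaceValidationError(f"{self.name}: duplicate categories")
            object.__setattr__(self, "categories", tuple(self.categories))

    # -- per-dimension transforms ------------------------------------------

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("categorical", "boolean")

    def validate_value(self, value) -> None:
        if self.is_categorical:
            if value not in self.categories:
                raise SpaceValidationError(
                    f"{self.name}: {value!r} not in {self.categories}")
        elif self.kind == "integer":
            if value != int(value):
                raise SpaceValidationError(f"{self.name}: {value!r} not an integer")
            if not (self.lower <= value <= self.upper):
                raise SpaceValidationError(
                    f"{self.name}: {value!r} outside [{self.lower}, {self.upper}]")
        else:
            if not (self.lower <= value <= self.upper):
                raise SpaceValidationError(
                    f"{self.name}: {value!r} outside [{self.lower}, {self.upper}]")

    def to_unit(self, value) -> float:
        self.validate_value(value)
        if self.is_categorical:
            c = self.categories.index(value)
            return (c + 0.5) / len(self.categories)
        if self.kind == "integer":
            return (int(value) - self.lower + 0.5) / (self.upper - self.lower + 1)
        if self.kind == "log-continuous":
            llo, lhi = math.log10(self.lower), math.log10(self.upper)
            return (math.log10(value) - llo) / (lhi - llo)
        return (value - self.lower) / (self.upper - self.lower)

    def from_unit(self, u: float):
        if not (0.0 <= u <= 1.0):
            raise SpaceValidationError(f"{self.name}: coordinate {u} outside [0, 1]")
        if self.is_categorical:
            k = len(self.categories)
            return self.categories[min(int(u * k), k - 1)]
        if self.kind == "integer":
            n = int(self.upper - self.lower + 1)
            return int(self.lower) + min(int(u * n), n - 1)
        if self.kind == "log-continuous":
            llo, lhi = math.log10(self.lower), math.log10(self.upper)
            return 10.0 ** (llo + u * (lhi - llo))
        return self.lower + u * (self.upper - self.lower)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"name": self.name, "kind": self.kind}
        if self.lower is not None:
            d["lower"] = self.lower
            d["upper"] = self.upper
        if self.kind == "categorical":
            d["categories"] = list(self.categories)
        return d


@dataclass(frozen=True)
class HyperparameterSpace:
    """An ordered collection of :class:`ParamSpec` defining the search domain."""

    params: tuple

    def __post_init__(self):
        object.__setattr__(self, "params", tuple(self.params))
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise SpaceValidationError("duplicate parameter names")

    def __len__(self) -> int:
        return len(self.params)

    def __iter__(self) -> Iterator[ParamSpec]:
        return iter(self.params)

    def __getitem__(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise SpaceValidationError(f"unknown parameter {name!r}")

    @property
    def names(self) -> tuple:
        return tuple(p.name for p in self.params)

    @property
    def dimension(self) -> int:
        return len(self.params)

    # -- configuration handling --------------------------------------------

    def validate(self, config: Mapping) -> None:
        """Raise :class:`SpaceValidationError` unless ``config`` is admissible."""
        unknown = set(config) - set(self.names)
        if unknown:
            raise SpaceValidationError(f"unknown parameter names {sorted(unknown)}")
        for p in self.params:
            if p.name not in config:
                raise SpaceValidationError(f"missing parameter {p.name!r}")
            p.validate_value(config[p.name])

    def encode(self, config: Mapping) -> np.ndarray:
        """Map a configuration to its point in the unit cube."""
        self.validate(config)
        return np.array([p.to_unit(config[p.name]) for p in self.params])

    def decode(self, point: Sequence[float]) -> Configuration:
        """Inverse of :meth:`encode`; coordinates must lie in ``[0, 1]``."""
        point = np.asarray(point, dtype=float)
        if point.shape != (self.dimension,):
            raise SpaceValidationError(
                f"expected {self.dimension} coordinates, got shape {point.shape}")
        return {p.name: p.from_unit(u) for p, u in zip(self.params, point)}

    def sample(self, n: int, rng: np.random.Generator) -> list:
        """Draw ``n`` uniform configurations (uniform on the cube, decoded)."""
        if n < 1:
            raise SpaceValidationError("n must be >= 1")
        U = rng.random((n, self.dimension))
        return [self.decode(u) for u in U]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> list:
        return [p.to_dict() for p in self.params]

    @classmethod
    def from_dict(cls, specs: Sequence[Mapping]) -> "HyperparameterSpace":
        params = []
        for s in specs:
            params.append(ParamSpec(
                name=s["name"], kind=s["kind"],
                lower=s.get("lower"), upper=s.get("upper"),
                categories=tuple(s.get("categories", ()))))
        return cls(tuple(params))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HyperparameterSpace":
        return cls.from_dict(json.loads(text))


def define_vgg_space() -> HyperparameterSpace:
    """The 11-dimensional VGG fine-tuning space.

    Eleven tunables: second-block feature-map count, filter size, activation,
    pooling window, optimizer, learning rate (log scale), batch size, epochs,
    dropout rate, and two booleans toggling fine-tuning of the upper and lower
    convolutional blocks.  Bounds are the tightest round ranges covering the
    values the tuning study explored.
    """
    return HyperparameterSpace((
        ParamSpec("feature_map", "integer", 16, 64),
        ParamSpec("filter_size", "integer", 1, 3),
        ParamSpec("activation", "categorical", categories=("ReLU", "Sigmoid")),
        ParamSpec("pool_size", "integer", 1, 2),
        ParamSpec("optimizer", "categorical",
                  categories=("SGD", "ADAM", "RMSprop", "Adadelta")),
        ParamSpec("learning_rate", "log-continuous", 1e-4, 1e-1),
        ParamSpec("batch_size", "integer", 1, 32),
        ParamSpec("epoch", "integer", 10, 200),
        ParamSpec("dropout_rate", "continuous", 0.1, 0.9),
        ParamSpec("upper_layer", "boolean"),
        ParamSpec("lower_layer", "boolean"),
    ))
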