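"""Synthetic benchmark objectives and data at desk scale.

Three ingredients let the whole optimization method run without external
data or GPU training:

* a *plateau objective* emulating the fine-tuning landscape the reference
  runs exhibit — almost every configuration scores an identical baseline
  accuracy (the failure mode of an over-parameterized model collapsing to
  the majority behaviour), with a few narrow Gaussian basins of high
  accuracy gated on categorical choices;
* a generator of Humphrey-perimetry-style visual-field images in six defect
  classes (central scotoma, hemianopia, quadrantanopia, tunnel vision,
  superior/inferior loss, normal), with the class mix of the pooled
  reference dataset and a stratified 80:10:10 split;
* a tiny-CNN tuning objective (see :mod:`swarmbo.tinycnn`) realizing the
  configuration→architecture mapping on those images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import refdata
from .space import Configuration, HyperparameterSpace, define_vgg_space

__all__ = [
    "Basin", "PlateauParams", "PlateauObjective", "plateau_objective",
    "VF_CLASSES", "VFImage", "VFDataset",
    "generate_vf_image", "generate_vf_dataset", "cnn_objective",
]

VF_CLASSES = ("central_scotoma", "hemianopia", "quadrantanopia",
              "tunnel", "superior_inferior", "normal")


# ---------------------------------------------------------------------------
# Plateau objective
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Basin:
    """One high-accuracy pocket: required categories plus a Gaussian centre.

    ``gates`` maps categorical parameter names to the category a
    configuration must hold to see the basin at all; ``center`` maps
    non-categorical parameter names to encoded (unit-cube) coordinates, and
    the Gaussian distance is taken over exactly those coordinates.
    """

    gates: Mapping[str, str]
    center: Mapping[str, float]


#: Three basins, all requiring ReLU plus one specific optimizer; centres sit
#: over the four training-schedule coordinates so each basin occupies a thin
#: slice of the space and the landscape stays overwhelmingly flat.  Integer
#: coordinates (epoch, batch_size) are bin centres — (v − lo + 0.5)/(hi − lo
#: + 1) — so an exactly-on-centre configuration exists for every basin.
DEFAULT_BASINS = (
    Basin(gates={"activation": "ReLU", "optimizer": "ADAM"},
          center={"learning_rate": 0.40, "dropout_rate": 0.55,
                  "epoch": 114.5 / 191, "batch_size": 14.5 / 32}),
    Basin(gates={"activation": "ReLU", "optimizer": "RMSprop"},
          center={"learning_rate": 0.55, "dropout_rate": 0.40,
                  "epoch": 67.5 / 191, "batch_size": 19.5 / 32}),
    Basin(gates={"activation": "ReLU", "optimizer": "SGD"},
          center={"learning_rate": 0.62, "dropout_rate": 0.62,
                  "epoch": 95.5 / 191, "batch_size": 12.5 / 32}),
)


@dataclass
class PlateauParams:
    """Baseline/peak accuracies (percent), basin width, basins, noise."""

    baseline: float = 20.55
    peak: float = 98.6
    length_scale: float = 0.15
    basins: tuple = DEFAULT_BASINS
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.baseline < self.peak:
            raise ValueError("baseline must be < peak")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be > 0")
        if len(self.basins) < 1:
            raise ValueError("need at least one basin")


class PlateauObjective:
    """Callable Configuration → percent implementing the plateau landscape.

    value = baseline + (peak − baseline) · max over basins of
    [gate-match × exp(−‖u − centre‖² / (2ℓ²))], plus optional seeded
    Gaussian noise.  Deterministic when ``noise_sd`` is 0; call
    :meth:`reset_noise` to re-pair noise streams across variants.
    """

    def __init__(self, space: Optional[HyperparameterSpace] = None,
                 params: Optional[PlateauParams] = None):
        self.space = space if space is not None else define_vgg_space()
        self.params = params if params is not None else PlateauParams()
        self._rng = np.random.default_rng(self.params.seed)

    def reset_noise(self, seed: Optional[int] = None) -> None:
        self._rng = np.random.default_rng(
            self.params.seed if seed is None else seed)

    def noiseless(self, config: Configuration) -> float:
        p = self.params
        peak_term = 0.0
        for basin in p.basins:
            if any(config[name] != cat for name, cat in basin.gates.items()):
                continue
            d2 = 0.0
            for name, c in basin.center.items():
                u = self.space[name].to_unit(config[name])
                d2 += (u - c) ** 2
            peak_term = max(peak_term,
                            float(np.exp(-d2 / (2.0 * p.length_scale ** 2))))
        return p.baseline + (p.peak - p.baseline) * peak_term

    def __call__(self, config: Configuration) -> float:
        value = self.noiseless(config)
        if self.params.noise_sd > 0:
            value += float(self._rng.normal(0.0, self.params.noise_sd))
            # keep noisy values inside the documented range
            value = float(np.clip(value,
                                  self.params.baseline - 4 * self.params.noise_sd,
                                  self.params.peak + 4 * self.params.noise_sd))
        return value


def plateau_objective(config: Configuration,
                      params: Optional[PlateauParams] = None,
                      space: Optional[HyperparameterSpace] = None) -> float:
    """One-shot functional form of :class:`PlateauObjective` (noiseless)."""
    return PlateauObjective(space, params).noiseless(config)


# ---------------------------------------------------------------------------
# Visual-field image generator
# ---------------------------------------------------------------------------

BACKGROUND_LEVEL = 0.8
DEFECT_LEVEL = 0.15
PIXEL_NOISE_SD = 0.05


@dataclass(frozen=True)
class VFImage:
    """One grayscale sensitivity grid in [0, 1] with its defect label."""

    grid: np.ndarray
    label: str

    def __post_init__(self):
        if self.label not in VF_CLASSES:
            raise ValueError(f"unknown label {self.label!r}")


def _defect_mask(label: str, size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of the depressed-sensitivity region for one image.

    The random geometry (scotoma radius, affected side/quadrant) is drawn
    from ``rng`` *before* any pixel noise, so a tunnel image and a central
    scotoma generated from identically seeded streams are exact complements.
    """
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    if label in ("central_scotoma", "tunnel"):
        radius = rng.uniform(0.12, 0.25) * size
        disk = r2 <= radius ** 2
        return disk if label == "central_scotoma" else ~disk
    if label == "hemianopia":
        left = rng.random() < 0.5
        return xx < size / 2 if left else xx >= size / 2
    if label == "quadrantanopia":
        q = rng.integers(4)
        top = q in (0, 1)
        left = q in (0, 2)
        return ((yy < size / 2) == top) & ((xx < size / 2) == left)
    if label == "superior_inferior":
        top = rng.random() < 0.5
        third = size // 3
        return yy < third if top else yy >= size - third
    if label == "normal":
        return np.zeros((size, size), dtype=bool)
    raise ValueError(f"unknown label {label!r}")


def generate_vf_image(label: str, size: int = 32,
                      rng: Optional[np.random.Generator] = None) -> VFImage:
    """Simulate one perimetry-style grid: bright field, dark defect region."""
    rng = rng if rng is not None else np.random.default_rng(0)
    mask = _defect_mask(label, size, rng)
    grid = BACKGROUND_LEVEL + rng.normal(0.0, PIXEL_NOISE_SD, (size, size))
    grid[mask] = DEFECT_LEVEL + rng.normal(0.0, PIXEL_NOISE_SD, int(mask.sum()))
    return VFImage(np.clip(grid, 0.0, 1.0), label)


@dataclass
class VFDataset:
    """Images, labels and a train/val/test assignment."""

    images: np.ndarray            # (n, size, size) float in [0, 1]
    labels: list
    split: list                   # "train" | "val" | "test" per image

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, part: str) -> "VFDataset":
        idx = [i for i, s in enumerate(self.split) if s == part]
        return VFDataset(self.images[idx],
                         [self.labels[i] for i in idx],
                         [part] * len(idx))

    def class_counts(self) -> dict:
        return {c: self.labels.count(c) for c in VF_CLASSES}

    # -- PNG + CSV round trip ----------------------------------------------

    def save(self, directory) -> None:
        """Write PNGs into class subdirectories plus a labels/split CSV."""
        from PIL import Image

        directory = Path(directory)
        rows = ["filename,label,split"]
        for i, (img, label, part) in enumerate(
                zip(self.images, self.labels, self.split)):
            sub = directory / label
            sub.mkdir(parents=True, exist_ok=True)
            name = f"{label}/vf_{i:05d}.png"
            arr = np.round(img * 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(directory / name)
            rows.append(f"{name},{label},{part}")
        (directory / "labels.csv").write_text("\n".join(rows) + "\n")

    @classmethod
    def load(cls, directory) -> "VFDataset":
        from PIL import Image

        directory = Path(directory)
        lines = (directory / "labels.csv").read_text().strip().splitlines()[1:]
        images, labels, split = [], [], []
        for line in lines:
            name, label, part = line.split(",")
            arr = np.asarray(Image.open(directory / name), dtype=float) / 255.0
            images.append(arr)
            labels.append(label)
            split.append(part)
        return cls(np.stack(images), labels, split)


def _largest_remainder_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    raw = n * proportions
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_vf_dataset(n: int = 1268,
                        proportions: Optional[Sequence[float]] = None,
                        size: int = 32,
                        rng: Optional[np.random.Generator] = None,
                        ) -> VFDataset:
    """Generate ``n`` images with the reference class mix, split 80:10:10.

    Per-class counts follow largest-remainder rounding of the proportions
    (default: the pooled study's class distribution); the split is
    stratified per class with val and test each taking round(10%) and the
    remainder training.
    """
    if n < 60:
        raise ValueError("n must be >= 60 so every class reaches each split")
    rng = rng if rng is not None else np.random.default_rng(0)
    if proportions is None:
        total = sum(refdata.VF_CLASS_COUNTS.values())
        proportions = np.array([refdata.VF_CLASS_COUNTS[c] for c in VF_CLASSES],
                               dtype=float) / total
    else:
        proportions = np.asarray(proportions, dtype=float)
        if abs(proportions.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
    counts = _largest_remainder_counts(n, proportions)

    images, labels, split = [], [], []
    for cls_name, m in zip(VF_CLASSES, counts):
        n_val = int(round(0.1 * m))
        n_test = int(round(0.1 * m))
        parts = (["val"] * n_val + ["test"] * n_test
                 + ["train"] * (m - n_val - n_test))
        parts = [parts[i] for i in rng.permutation(m)]
        for part in parts:
            images.append(generate_vf_image(cls_name, size, rng).grid)
            labels.append(cls_name)
            split.append(part)
    order = rng.permutation(len(labels))
    return VFDataset(np.stack(images)[order],
                     [labels[i] for i in order],
                     [split[i] for i in order])


def cnn_objective(config: Configuration, data: VFDataset,
                  budget_scale: float = 0.1, seed: int = 0,
                  pretrain_steps: int = 30) -> float:
    """Validation accuracy (%) of the tiny CNN the configuration describes.

    See :func:`swarmbo.tinycnn.train_and_score` for the architecture
    mapping and training procedure.
    """
    from .tinycnn import train_and_score

    return train_and_score(config, data, budget_scale=budget_scale,
                           seed=seed, pretrain_steps=pretrain_steps)
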