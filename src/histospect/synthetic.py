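"""Download-free synthetic inputs for every pipeline stage.

Two generators are provided:

* :func:`generate_texture_dataset` builds a small multi-class dataset of
  RGB texture tiles.  Each class is a sinusoidal grating with its own
  (orientation, frequency) pair plus additive Gaussian noise, rendered to
  8-bit RGB at the 150 x 150 tile geometry typical of public
  histopathology texture collections.  Gratings were chosen over random
  textures because spectral energy features separate them by construction,
  so the whole pipeline is exercisable on a laptop with no model weights.
* :func:`generate_feature_table` builds a samples x features matrix in
  which a known subset of columns carries a between-class mean shift of a
  chosen magnitude (in pooled-SD units) while the rest are pure noise,
  giving ground truth for selection-recovery tests.

Neither generator attempts realistic H&E stain appearance or nuclear
morphology; they emulate the *interfaces and statistics* the pipeline
consumes, not histology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import LabeledImageSet
from .features import FeatureMatrix

__all__ = ["TextureDatasetSpec", "FeatureTableSpec", "generate_texture_dataset",
           "generate_feature_table"]


@dataclass
class TextureDatasetSpec:
    """Synthetic grating-tile dataset description.

    ``orientations`` (radians) and ``frequencies`` (cycles per pixel) are
    per-class; defaults spread orientations evenly over [0, pi) and cycle
    through a small frequency ladder so every class gets a distinct
    (orientation, frequency) pair.  ``noise_sd`` is the Gaussian noise SD
    on the [0, 1] intensity scale.
    """

    n_classes: int = 4
    per_class: int = 60
    tile_size: int = 150
    orientations: list[float] | None = None
    frequencies: list[float] | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class < 2:
            raise ValueError("need at least 2 tiles per class")
        if self.orientations is None:
            self.orientations = [math.pi * k / self.n_classes
                                 for k in range(self.n_classes)]
        if self.frequencies is None:
            ladder = [0.06, 0.10, 0.16, 0.24, 0.32]
            self.frequencies = [ladder[k % len(ladder)] * (1 + k // len(ladder))
                                for k in range(self.n_classes)]
        if len(self.orientations) != self.n_classes or \
                len(self.frequencies) != self.n_classes:
            raise ValueError("need one (orientation, frequency) pair per class")
        pairs = list(zip(self.orientations, self.frequencies))
        if len(set(pairs)) != len(pairs):
            raise ValueError("class texture parameters must be distinct")


@dataclass
class FeatureTableSpec:
    """Feature table with a known informative-column subset."""

    n_samples: int = 300
    n_features: int = 200
    n_informative: int = 10
    effect_size: float = 2.0
    n_classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")


def _grating(size: int, orientation: float, frequency: float) -> np.ndarray:
    """Unit-amplitude sinusoidal grating on the [0, 1] intensity scale."""
    yy, xx = np.mgrid[0:size, 0:size]
    phase = 2 * math.pi * frequency * (xx * math.cos(orientation)
                                       + yy * math.sin(orientation))
    return 0.5 + 0.45 * np.sin(phase)


def generate_texture_dataset(
    spec: TextureDatasetSpec,
    out_dir: str | Path | None = None,
) -> LabeledImageSet:
    """Render the grating tiles; optionally write a class-per-folder layout.

    Byte-identical regeneration is guaranteed for a fixed seed; with
    ``noise_sd = 0`` all tiles of one class are identical.
    """
    rng = np.random.default_rng(spec.seed)
    images: list[np.ndarray] = []
    labels: list[int] = []
    class_names = [f"class_{k:02d}" for k in range(spec.n_classes)]
    for k in range(spec.n_classes):
        base = _grating(spec.tile_size, spec.orientations[k], spec.frequencies[k])
        for _ in range(spec.per_class):
            tile = base
            if spec.noise_sd > 0:
                tile = base + rng.normal(0.0, spec.noise_sd, base.shape)
            arr = np.clip(np.rint(tile * 255.0), 0, 255).astype(np.uint8)
            images.append(np.stack([arr] * 3, axis=-1))
            labels.append(k)
    imgset = LabeledImageSet(images, np.array(labels), class_names)

    if out_dir is not None:
        out = Path(out_dir)
        counters = [0] * spec.n_classes
        for img, lab in zip(imgset.images, imgset.labels):
            cdir = out / class_names[lab]
            cdir.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(cdir / f"tile_{counters[lab]:04d}.png")
            counters[lab] += 1
    return imgset


def generate_feature_table(
    spec: FeatureTableSpec,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Draw the noise table and plant class-informative columns.

    Uninformative columns are standard normal for all classes; each
    informative column ``j`` receives a per-class mean offset
    ``(g - (G-1)/2) * effect_size`` so adjacent classes differ by
    ``effect_size`` pooled SDs.  Returns the matrix and the sorted true
    informative index set.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, G = spec.n_samples, spec.n_features, spec.n_classes
    labels = np.arange(n) % G
    X = rng.standard_normal((n, d))
    informative = np.sort(rng.choice(d, size=spec.n_informative, replace=False))
    if spec.n_informative:
        offsets = (labels - (G - 1) / 2.0)[:, None] * spec.effect_size
        X[:, informative] += offsets
    fm = FeatureMatrix(X, labels, feature_origin="synthetic",
                       class_names=[f"class_{k:02d}" for k in range(G)],
                       meta={"n_informative": int(spec.n_informative),
                             "effect_size": float(spec.effect_size)})
    return fm, informative
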