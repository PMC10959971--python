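"""Deep-feature extraction contract for the three CNN backbones.

The pipeline taps a fixed layer of each architecture and exports its
activation as the deep-feature vector:

==============  ==================  =========
architecture    tap layer           width
==============  ==================  =========
alexnet         ``fc7``             4096
resnet50        ``final_avg_pool``  2048
densenet201     ``final_avg_pool``  1920
==============  ==================  =========

The architectures are defined in-repo as NumPy forward passes, so the
dimension contracts are verifiable with seeded random weights and no
downloads.  ``weights_mode="pretrained"`` is a declared mode that requires
externally supplied parameters and raises until they are provided.
Fine-tuning follows the frozen-extractor transfer-learning recipe: the
replacement classification head (``n_classes`` outputs) is trained with
SGD-with-momentum on the tapped features while the convolutional stack
stays fixed.

A non-CNN pseudo-backbone, ``dct_energy`` (hand-crafted low-frequency
spectral energies), is also registered for desk-scale end-to-end runs; see
:mod:`histospect.backbones._pseudo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import LabeledImageSet
from ..features import FeatureMatrix
from ._archs import (ARCH_INPUT_SIZE, ARCH_TAP_DIM, ARCH_TAP_LAYER,
                     build_alexnet, build_densenet201, build_resnet50)
from ._nn import he_fc
from ._pseudo import DCT_ENERGY_DEFAULT_DIM, dct_energy_features

__all__ = ["BackboneSpec", "TrainConfig", "BackboneHandle", "build_backbone",
           "finetune_backbone", "extract_features", "CNN_ARCHITECTURES"]

CNN_ARCHITECTURES = ("alexnet", "resnet50", "densenet201")
_BUILDERS = {"alexnet": build_alexnet, "resnet50": build_resnet50,
             "densenet201": build_densenet201}


@dataclass
class BackboneSpec:
    """Which architecture, which tap layer, which weights.

    ``expected_dim`` is fixed by the architecture (4096/2048/1920); for the
    ``dct_energy`` pseudo-backbone it is the number of spectral
    coefficients and defaults to 1024.
    """

    name: str
    weights_mode: str = "random"
    tap_layer: str | None = None
    expected_dim: int | None = None

    def __post_init__(self) -> None:
        if self.name in CNN_ARCHITECTURES:
            expected = ARCH_TAP_DIM[self.name]
            if self.expected_dim is None:
                self.expected_dim = expected
            elif self.expected_dim != expected:
                raise ValueError(
                    f"{self.name} tap width is {expected}, not {self.expected_dim}"
                )
            if self.tap_layer is None:
                self.tap_layer = ARCH_TAP_LAYER[self.name]
            elif self.tap_layer != ARCH_TAP_LAYER[self.name]:
                raise ValueError(
                    f"{self.name} taps {ARCH_TAP_LAYER[self.name]!r}, "
                    f"not {self.tap_layer!r}"
                )
        elif self.name == "dct_energy":
            if self.expected_dim is None:
                self.expected_dim = DCT_ENERGY_DEFAULT_DIM
            if self.tap_layer is None:
                self.tap_layer = "zigzag_dct"
        else:
            raise ValueError(
                f"unknown architecture {self.name!r}; "
                f"known: {CNN_ARCHITECTURES + ('dct_energy',)}"
            )
        if self.weights_mode not in ("random", "pretrained", "finetuned"):
            raise ValueError(f"unknown weights_mode {self.weights_mode!r}")


@dataclass
class TrainConfig:
    """Head-training hyperparameters (SGD with momentum)."""

    minibatch_size: int = 10
    learning_rate: float = 0.0001
    max_epochs: int = 20
    optimizer: str = "sgdm"
    momentum: float = 0.9
    validation_fraction: float = 0.1
    n_output_classes: int | None = None

    def __post_init__(self) -> None:
        if min(self.minibatch_size, self.max_epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("training hyperparameters must be positive")
        if self.optimizer != "sgdm":
            raise ValueError("optimizer is fixed to SGD with momentum ('sgdm')")


@dataclass
class BackboneHandle:
    """A built backbone: feature extractor plus replaceable class head."""

    spec: BackboneSpec
    n_classes: int
    params: dict | None
    forward: object  # callable (x, params) -> tap vector; None for pseudo
    head_w: np.ndarray
    head_b: np.ndarray
    loss_history: list[float] = field(default_factory=list)

    # ------------------------------------------------------------ features
    def _check_geometry(self, img: np.ndarray) -> None:
        if self.spec.name in CNN_ARCHITECTURES:
            h, w = ARCH_INPUT_SIZE[self.spec.name]
            if img.shape[:2] != (h, w):
                raise ValueError(
                    f"{self.spec.name} expects {h}x{w} input, got "
                    f"{img.shape[0]}x{img.shape[1]}; resize first"
                )

    def tap_features(self, img: np.ndarray) -> np.ndarray:
        """Deep-feature vector of one 8-bit RGB tile."""
        self._check_geometry(img)
        if self.spec.name == "dct_energy":
            return dct_energy_features(img, self.spec.expected_dim)
        x = (img.astype(np.float32) / 255.0 - 0.5) * 2.0
        x = np.ascontiguousarray(x.transpose(2, 0, 1))
        return np.asarray(self.forward(x, self.params), dtype=float)

    def features_matrix(self, imgset: LabeledImageSet) -> np.ndarray:
        return np.vstack([self.tap_features(img) for img in imgset.images])

    def head_scores(self, feats: np.ndarray) -> np.ndarray:
        return feats @ self.head_w.T + self.head_b


def build_backbone(spec: BackboneSpec, n_classes: int, seed: int = 0) -> BackboneHandle:
    """Instantiate the architecture with its output head replaced.

    The final classification layer always emits ``n_classes`` scores; the
    backbone body is seeded-random (``weights_mode="random"``) or must be
    supplied externally (``"pretrained"`` raises until then).
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if spec.weights_mode == "pretrained":
        raise NotImplementedError(
            "pretrained weights are not bundled with this package; build with "
            "weights_mode='random' or load externally exported parameters"
        )
    rng = np.random.default_rng(seed)
    if spec.name in CNN_ARCHITECTURES:
        params, forward, dim = _BUILDERS[spec.name](rng)
        assert dim == spec.expected_dim
    else:
        params, forward, dim = None, None, spec.expected_dim
    head_w, head_b = he_fc(rng, n_classes, dim)
    return BackboneHandle(spec=spec, n_classes=n_classes, params=params,
                          forward=forward, head_w=head_w, head_b=head_b)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def finetune_backbone(handle: BackboneHandle, train_images: LabeledImageSet,
                      cfg: TrainConfig | None = None, seed: int = 0) -> BackboneHandle:
    """Train the replacement head on the tapped features.

    Runs ``max_epochs`` passes of minibatch SGD with momentum on the
    softmax cross-entropy of the head; the mean loss of every epoch is
    appended to ``handle.loss_history``.  The seed fixes shuffling, so the
    run is reproducible.
    """
    cfg = cfg or TrainConfig()
    if cfg.n_output_classes is not None and cfg.n_output_classes != handle.n_classes:
        raise ValueError("n_output_classes disagrees with the built head")
    feats = handle.features_matrix(train_images).astype(np.float64)
    y = train_images.labels
    if y.max() >= handle.n_classes:
        raise ValueError("training labels exceed the head's class count")
    n = feats.shape[0]
    rng = np.random.default_rng(seed)
    w = handle.head_w.astype(np.float64)
    b = handle.head_b.astype(np.float64)
    vw = np.zeros_like(w)
    vb = np.zeros_like(b)
    onehot = np.eye(handle.n_classes)[y]
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start:start + cfg.minibatch_size]
            fb, yb = feats[idx], onehot[idx]
            probs = _softmax(fb @ w.T + b)
            losses.append(float(-np.mean(
                np.log(np.maximum((probs * yb).sum(axis=1), 1e-300)))))
            dz = (probs - yb) / idx.shape[0]
            gw = dz.T @ fb
            gb = dz.sum(axis=0)
            vw = cfg.momentum * vw - cfg.learning_rate * gw
            vb = cfg.momentum * vb - cfg.learning_rate * gb
            w += vw
            b += vb
        handle.loss_history.append(float(np.mean(losses)))
    handle.head_w = w
    handle.head_b = b
    handle.spec.weights_mode = "finetuned"
    return handle


def extract_features(handle: BackboneHandle, imgset: LabeledImageSet,
                     spec: BackboneSpec | None = None) -> FeatureMatrix:
    """Tap the backbone for every tile and assemble a feature matrix.

    Rows keep the input order; the width must equal the architecture's
    contracted dimension or a contract-violation error is raised.
    """
    spec = spec or handle.spec
    values = handle.features_matrix(imgset)
    if values.shape[1] != spec.expected_dim:
        raise RuntimeError(
            f"tap layer produced {values.shape[1]} features; contract says "
            f"{spec.expected_dim}"
        )
    return FeatureMatrix(
        values=values,
        labels=imgset.labels.copy(),
        feature_origin=spec.name,
        class_names=list(imgset.class_names),
        meta={"tap_layer": spec.tap_layer, "weights_mode": spec.weights_mode},
    )
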