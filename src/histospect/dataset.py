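"""Image dataset loading, resizing, stratified splitting and augmentation.

Datasets follow the class-per-subdirectory layout common to public
histopathology tile collections: every immediate subdirectory of the root is
one tissue class and contains the tiles of that class (TIFF/PNG/JPEG).
Labels are assigned by lexicographic subdirectory order, so they are
deterministic across filesystems.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "LabeledImageSet",
    "SplitSpec",
    "AugmentConfig",
    "load_image_dataset",
    "resize_for_backbone",
    "stratified_split",
    "augment_training_set",
    "export_split_csv",
    "BACKBONE_INPUT_SIZE",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

#: Input geometry (height, width) expected by each named backbone.
BACKBONE_INPUT_SIZE: dict[str, tuple[int, int]] = {
    "alexnet": (227, 227),
    "resnet50": (224, 224),
    "densenet201": (224, 224),
}


@dataclass
class LabeledImageSet:
    """RGB tiles with integer class labels.

    ``images[i]`` is an 8-bit ``H x W x 3`` array with label ``labels[i]``;
    ``class_names[k]`` names label ``k``.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    class_names: list[str]
    source_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.labels) and not (
            (self.labels >= 0) & (self.labels < len(self.class_names))
        ).all():
            raise ValueError("labels out of range for class_names")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class_names must be unique")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=int)
        return LabeledImageSet(
            images=[self.images[i] for i in indices],
            labels=self.labels[indices],
            class_names=list(self.class_names),
            source_paths=[self.source_paths[i] for i in indices]
            if self.source_paths
            else [],
        )


@dataclass
class SplitSpec:
    """Train/test split specification.

    ``train_fraction`` defaults to 0.70; 0.60 is the other standard preset.
    """

    train_fraction: float = 0.70
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class AugmentConfig:
    """Training-set augmentation: random flips and small rotations.

    Each augmented copy draws independent horizontal/vertical flip decisions
    and a rotation angle uniform in ``rotation_range_degrees`` (default
    -30..+30); rotation fills exposed corners by reflection.
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotation_range_degrees: tuple[float, float] = (-30.0, 30.0)
    copies_per_image: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.rotation_range_degrees
        if lo > hi:
            raise ValueError("rotation range min must be <= max")
        if self.copies_per_image < 0:
            raise ValueError("copies_per_image must be >= 0")


def _to_rgb8(arr: np.ndarray) -> np.ndarray:
    """Normalize a loaded raster to 8-bit H x W x 3."""
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return arr


def load_image_dataset(root_dir: str | Path) -> LabeledImageSet:
    """Read a class-per-subdirectory image dataset.

    Labels follow lexicographic subdirectory order; files within a class are
    read in lexicographic order, so the record order is deterministic.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"empty dataset: no class subdirectories under {root}")
    images: list[np.ndarray] = []
    labels: list[int] = []
    paths: list[str] = []
    class_names = [p.name for p in class_dirs]
    for label, cdir in enumerate(class_dirs):
        files = sorted(
            f for f in cdir.iterdir()
            if f.is_file() and f.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"empty dataset: class directory {cdir} has no images")
        for f in files:
            try:
                with Image.open(f) as im:
                    arr = np.asarray(im.convert("RGB"))
            except Exception as exc:  # noqa: BLE001 - report the offending file
                raise ValueError(f"unreadable image {f}: {exc}") from exc
            images.append(_to_rgb8(arr))
            labels.append(label)
            paths.append(str(f))
    return LabeledImageSet(images, np.array(labels), class_names, paths)


def resize_for_backbone(
    imgset: LabeledImageSet,
    backbone_name: str,
    size: tuple[int, int] | None = None,
) -> LabeledImageSet:
    """Bilinearly resize every tile to the backbone's input geometry.

    ResNet50/DenseNet201 take 224 x 224 x 3 and AlexNet 227 x 227 x 3; an
    explicit ``size=(H, W)`` overrides the lookup for other consumers.
    """
    if size is None:
        if backbone_name not in BACKBONE_INPUT_SIZE:
            raise ValueError(
                f"unknown backbone {backbone_name!r}; pass an explicit size=(H, W)"
            )
        size = BACKBONE_INPUT_SIZE[backbone_name]
    h, w = size
    out: list[np.ndarray] = []
    for img in imgset.images:
        if img.shape[0] == h and img.shape[1] == w:
            out.append(img.copy())
            continue
        pil = Image.fromarray(img)
        out.append(np.asarray(pil.resize((w, h), Image.BILINEAR)))
    return LabeledImageSet(out, imgset.labels.copy(), list(imgset.class_names),
                           list(imgset.source_paths))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    Per class the train count is ``round(train_fraction * class_size)``
    (half up); totals are then reconciled to ``round(train_fraction * n)``
    by +-1 adjustments of the currently largest class, so class proportions
    in train deviate from the global proportions by less than one sample.
    Returns ``(train_indices, test_indices)``, disjoint and exhaustive.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("empty label sequence")
    classes, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        bad = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 members; too small: {bad.tolist()}")

    if not spec.stratified:
        rng = np.random.default_rng(spec.seed)
        perm = rng.permutation(n)
        n_train = _round_half_up(spec.train_fraction * n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    take = {
        int(c): min(max(_round_half_up(spec.train_fraction * k), 1), k - 1)
        for c, k in zip(classes, counts)
    }
    target = _round_half_up(spec.train_fraction * n)
    target = min(max(target, len(classes)), n - len(classes))
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    # Reconcile the global total by nudging the class that is currently the
    # most over- (or under-) represented relative to its exact share, so no
    # class ends up more than one sample away from its proportion.
    while sum(take.values()) != target:
        delta = -1 if sum(take.values()) > target else 1

        def _priority(c):
            dev = take[c] - spec.train_fraction * count_of[c]
            return (delta * dev, -count_of[c], c)

        for c in sorted(take, key=_priority):
            if 1 <= take[c] + delta <= count_of[c] - 1:
                take[c] += delta
                break
        else:  # pragma: no cover - unreachable given the clamped target
            raise RuntimeError("could not reconcile split totals")

    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(labels == c)
        perm = rng.permutation(members.shape[0])
        k = take[int(c)]
        train_idx.extend(members[perm[:k]].tolist())
        test_idx.extend(members[perm[k:]].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def export_split_csv(path: str | Path, train_idx, test_idx) -> None:
    """Write split indices as CSV with columns ``index, partition``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "partition"])
        for i in np.asarray(train_idx, dtype=int):
            writer.writerow([int(i), "train"])
        for i in np.asarray(test_idx, dtype=int):
            writer.writerow([int(i), "test"])


def _augment_one(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.vertical_flip and rng.random() < 0.5:
        out = out[::-1, :]
    lo, hi = cfg.rotation_range_degrees
    angle = float(rng.uniform(lo, hi))
    if angle != 0.0:
        rot = _sk_rotate(out.astype(float), angle, resize=False, mode="reflect",
                         preserve_range=True)
        out = np.clip(np.rint(rot), 0, 255).astype(np.uint8)
    return np.ascontiguousarray(out)


def augment_training_set(imgset: LabeledImageSet, cfg: AugmentConfig) -> LabeledImageSet:
    """Append ``copies_per_image`` randomized copies of every training tile.

    Only meant for the training partition; labels are propagated unchanged
    and the output holds the originals followed by the copies.
    """
    rng = np.random.default_rng(cfg.seed)
    images = [img.copy() for img in imgset.images]
    labels = list(imgset.labels.tolist())
    paths = list(imgset.source_paths) if imgset.source_paths else []
    for i, img in enumerate(imgset.images):
        for _ in range(cfg.copies_per_image):
            images.append(_augment_one(img, cfg, rng))
            labels.append(int(imgset.labels[i]))
            if paths:
                paths.append(imgset.source_paths[i] + "#aug")
    return LabeledImageSet(images, np.array(labels), list(imgset.class_names), paths)
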