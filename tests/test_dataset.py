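"""Dataset loading, resizing, stratified splitting and augmentation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from PIL import Image

from histospect.dataset import (AugmentConfig, SplitSpec,
                                augment_training_set, load_image_dataset,
                                resize_for_backbone, stratified_split)
from histospect.synthetic import TextureDatasetSpec, generate_texture_dataset


def _write_dataset(root, layout):
    """layout: {class_name: n_images}; tiny random PNGs."""
    rng = np.random.default_rng(0)
    for cname, n in layout.items():
        d = root / cname
        d.mkdir(parents=True)
        for i in range(n):
            arr = rng.integers(0, 255, (20, 20, 3), dtype=np.uint8)
            Image.fromarray(arr).save(d / f"img_{i}.png")


class TestLoad:
    def test_labels_follow_lexicographic_class_order(self, tmp_path):
        _write_dataset(tmp_path, {"B": 3, "A": 2})
        ds = load_image_dataset(tmp_path)
        assert len(ds) == 5
        assert ds.class_names == ["A", "B"]
        assert ds.labels.tolist() == [0, 0, 1, 1, 1]

    def test_empty_class_directory_rejected(self, tmp_path):
        _write_dataset(tmp_path, {"A": 2})
        (tmp_path / "B").mkdir()
        with pytest.raises(ValueError, match="empty dataset"):
            load_image_dataset(tmp_path)

    def test_empty_root_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty dataset"):
            load_image_dataset(tmp_path)

    def test_unreadable_image_names_the_file(self, tmp_path):
        _write_dataset(tmp_path, {"A": 2})
        bad = tmp_path / "A" / "broken.png"
        bad.write_bytes(b"not a png")
        with pytest.raises(ValueError, match="broken.png"):
            load_image_dataset(tmp_path)

    def test_grayscale_is_promoted_to_rgb(self, tmp_path):
        d = tmp_path / "A"
        d.mkdir()
        Image.fromarray(np.zeros((10, 10), np.uint8)).save(d / "g.png")
        Image.fromarray(np.ones((10, 10), np.uint8)).save(d / "h.png")
        ds = load_image_dataset(tmp_path)
        assert ds.images[0].shape == (10, 10, 3)


class TestResize:
    @pytest.mark.parametrize("backbone,expect", [
        ("resnet50", (224, 224, 3)),
        ("densenet201", (224, 224, 3)),
        ("alexnet", (227, 227, 3)),
    ])
    def test_backbone_geometries(self, small_texture_set, backbone, expect):
        out = resize_for_backbone(small_texture_set.subset([0, 1]), backbone)
        assert out.images[0].shape == expect
        assert np.array_equal(out.labels, small_texture_set.labels[:2])

    def test_identity_resize_preserves_pixels(self, rng):
        from histospect.dataset import LabeledImageSet
        img = rng.integers(0, 255, (224, 224, 3), dtype=np.uint8)
        ds = LabeledImageSet([img], np.array([0]), ["A"])
        out = resize_for_backbone(ds, "resnet50")
        assert np.array_equal(out.images[0], img)

    def test_unknown_backbone_without_override(self, small_texture_set):
        with pytest.raises(ValueError, match="unknown backbone"):
            resize_for_backbone(small_texture_set, "vgg16")
        out = resize_for_backbone(small_texture_set.subset([0]), "vgg16",
                                  size=(100, 120))
        assert out.images[0].shape == (100, 120, 3)


class TestSplit:
    def test_70_30_on_four_balanced_classes(self):
        labels = np.repeat(np.arange(4), 25)
        tr, te = stratified_split(labels, SplitSpec(0.70, seed=3))
        assert len(tr) == 70 and len(te) == 30
        per_class = [np.isin(tr, np.flatnonzero(labels == c)).sum()
                     for c in range(4)]
        assert all(17 <= k <= 18 for k in per_class)

    def test_60_40_small(self):
        labels = np.array([0] * 5 + [1] * 5)
        tr, te = stratified_split(labels, SplitSpec(0.60, seed=0))
        assert len(tr) == 6 and len(te) == 4
        assert (labels[tr] == 0).sum() == 3 and (labels[tr] == 1).sum() == 3

    def test_deterministic_given_seed(self):
        labels = np.repeat([0, 1, 2], 10)
        a = stratified_split(labels, SplitSpec(0.7, seed=9))
        b = stratified_split(labels, SplitSpec(0.7, seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = stratified_split(labels, SplitSpec(0.7, seed=10))
        assert not np.array_equal(a[0], c[0])

    @given(fraction=st.floats(0.2, 0.8),
           sizes=st.lists(st.integers(3, 12), min_size=2, max_size=5),
           seed=st.integers(0, 100))
    def test_disjoint_exhaustive_and_proportional(self, fraction, sizes, seed):
        labels = np.concatenate([np.full(k, c) for c, k in enumerate(sizes)])
        tr, te = stratified_split(labels, SplitSpec(fraction, seed=seed))
        assert set(tr) | set(te) == set(range(len(labels)))
        assert set(tr) & set(te) == set()
        for c, k in enumerate(sizes):
            got = (labels[tr] == c).sum()
            assert abs(got - fraction * k) <= 1.0

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([0, 0, 1]), SplitSpec(0.7))


class TestAugment:
    def test_count_and_label_conservation(self, small_texture_set):
        cfg = AugmentConfig(copies_per_image=2, seed=1)
        out = augment_training_set(small_texture_set, cfg)
        n = len(small_texture_set)
        assert len(out) == 3 * n
        assert np.array_equal(out.labels[:n], small_texture_set.labels)
        # copies carry their source labels
        expected = np.concatenate(
            [small_texture_set.labels,
             np.repeat(small_texture_set.labels, 2)])
        assert sorted(out.labels.tolist()) == sorted(expected.tolist())

    def test_originals_are_untouched(self, small_texture_set):
        cfg = AugmentConfig(copies_per_image=1, seed=2)
        out = augment_training_set(small_texture_set, cfg)
        for i in range(len(small_texture_set)):
            assert np.array_equal(out.images[i], small_texture_set.images[i])

    def test_flips_without_rotation_are_involutive(self, rng):
        from histospect.dataset import LabeledImageSet
        img = rng.integers(0, 255, (16, 16, 3), dtype=np.uint8)
        ds = LabeledImageSet([img], np.array([0]), ["A"])
        cfg = AugmentConfig(rotation_range_degrees=(0.0, 0.0),
                            copies_per_image=8, seed=5)
        out = augment_training_set(ds, cfg)
        variants = {img.tobytes(), img[:, ::-1].tobytes(),
                    img[::-1, :].tobytes(), img[::-1, ::-1].tobytes()}
        for copy in out.images[1:]:
            assert copy.tobytes() in variants

    def test_negative_copies_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(copies_per_image=-1)

    def test_rotation_changes_interior_but_keeps_shape(self):
        spec = TextureDatasetSpec(n_classes=2, per_class=2, tile_size=32,
                                  noise_sd=0.0, seed=0)
        ds = generate_texture_dataset(spec)
        cfg = AugmentConfig(horizontal_flip=False, vertical_flip=False,
                            rotation_range_degrees=(10.0, 30.0),
                            copies_per_image=1, seed=3)
        out = augment_training_set(ds, cfg)
        rotated = out.images[len(ds)]
        assert rotated.shape == ds.images[0].shape
        assert not np.array_equal(rotated, ds.images[0])
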