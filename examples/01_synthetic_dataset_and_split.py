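"""Generate a synthetic texture-tile dataset and split it 70-30.

Builds a 4-class set of sinusoidal-grating tiles (a stand-in for H&E
texture tiles), writes it in the class-per-folder layout, reloads it, and
produces a stratified train/test split.
"""

import tempfile
from pathlib import Path

import numpy as np

from histospect import (SplitSpec, TextureDatasetSpec, generate_texture_dataset,
                        load_image_dataset, stratified_split)

with tempfile.TemporaryDirectory() as tmp:
    spec = TextureDatasetSpec(n_classes=4, per_class=30, tile_size=150, seed=0)
    generate_texture_dataset(spec, out_dir=tmp)
    ds = load_image_dataset(tmp)
    print(f"loaded {len(ds)} tiles, classes: {ds.class_names}")

    train_idx, test_idx = stratified_split(ds.labels, SplitSpec(0.70, seed=1))
    print(f"train {len(train_idx)} / test {len(test_idx)}")
    for c in range(4):
        in_train = np.isin(train_idx, np.flatnonzero(ds.labels == c)).sum()
        print(f"  class {c}: {in_train} of 30 tiles in train")

# The per-class train counts stay within one tile of 70% of each class,
# so train and test preserve the class balance of the full dataset.
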