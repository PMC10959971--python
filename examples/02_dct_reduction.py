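"""Shorten a feature matrix with the orthonormal DCT-II.

Shows energy compaction: a handful of low-frequency coefficients carries
almost all of the energy of a smooth feature vector, so truncation loses
very little.
"""

import numpy as np

from histospect import FeatureMatrix, SpectralConfig, reduce_features_dct

rng = np.random.default_rng(0)
# smooth rows: random walks, the regime where DCT compaction shines
rows = np.cumsum(rng.normal(size=(5, 512)), axis=1)
fm = FeatureMatrix(rows, np.zeros(5, int))

for keep in (512, 64, 16):
    out = reduce_features_dct(fm, SpectralConfig(n_coefficients=keep))
    kept_energy = (out.values**2).sum() / (fm.values**2).sum()
    print(f"keep {keep:4d} of 512 coefficients -> "
          f"{100 * kept_energy:6.2f}% of the energy retained")

# At full length the transform is orthonormal (100% energy, invertible);
# 16 coefficients (3% of the width) still hold >99% of the energy here.
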