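"""Spectral-energy pseudo-backbone (synthetic feature extractor).

``dct_energy`` is NOT one of the CNN backbones: it is a deliberately simple
hand-crafted extractor used for desk-scale end-to-end runs and tests.  It
computes the orthonormal 2-D DCT of the luminance of a tile and returns the
absolute values of the first ``dim`` coefficients in zigzag order —
low-frequency spectral energies.  Sinusoidal-grating textures are separable
in this representation by construction, so the downstream reduction,
fusion, selection and classification stages can be exercised end to end
without any learned weights.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.fft import dctn

from ..spectral import zigzag_order

__all__ = ["dct_energy_features", "DCT_ENERGY_DEFAULT_DIM"]

DCT_ENERGY_DEFAULT_DIM = 1024


def dct_energy_features(img: np.ndarray, dim: int = DCT_ENERGY_DEFAULT_DIM) -> np.ndarray:
    """Low-frequency 2-D DCT energy vector of one RGB tile.

    The tile's luminance (channel mean, [0, 1]) is transformed with the
    orthonormal 2-D DCT-II; the leading ``dim`` coefficient magnitudes in
    zigzag order form the feature vector.
    """
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 tile")
    gray = img.astype(float).mean(axis=2) / 255.0
    h, w = gray.shape
    if dim > h * w:
        raise ValueError(f"dim={dim} exceeds the {h * w} available coefficients")
    coeffs = dctn(gray, type=2, norm="ortho")
    zz = zigzag_order(h, w).flat_indices()[:dim]
    return np.abs(coeffs.reshape(-1)[zz])


def block_for_dim(dim: int) -> int:
    """Smallest square block holding ``dim`` zigzag coefficients."""
    return math.ceil(math.sqrt(dim))
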