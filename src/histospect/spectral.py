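"""Orthonormal DCT-II reduction, zigzag coefficient ordering and fusion.

The pipeline exploits the energy-compaction property of the type-II
discrete cosine transform: for a feature vector ``x`` of length ``N`` the
orthonormal DCT-II

    X_k = s_k * sum_{n=0}^{N-1} x_n cos(pi (2n+1) k / (2N)),
    s_0 = sqrt(1/N),  s_k = sqrt(2/N)  (k >= 1),

concentrates most of the signal energy in low-index coefficients, so a
feature vector can be shortened by keeping only the first ``N_keep``
coefficients while preserving the bulk of its energy (Parseval:
``sum x^2 == sum X^2``).  Features of several backbones are fused by
column-wise concatenation followed by the same reduction.

Two coefficient-selection modes are provided.  ``one_d`` transforms each
feature row directly and keeps the leading coefficients (zigzag on a
one-row grid degenerates to the natural order).  ``two_d`` reshapes the row
into a zero-padded rectangle, applies the separable 2-D DCT-II, and reads
coefficients in the JPEG zigzag (anti-diagonal) order before truncation.
Both are per-sample transforms with no fitted state, so they cannot leak
information between train and test partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct as _dct, dctn as _dctn, idct as _idct

from .features import FeatureMatrix

__all__ = [
    "SpectralConfig",
    "ZigzagOrder",
    "dct_forward_1d",
    "dct_inverse_1d",
    "zigzag_order",
    "reduce_features_dct",
    "fuse_features_dct",
]


@dataclass
class SpectralConfig:
    """How a feature block is transformed and truncated.

    Parameters
    ----------
    n_coefficients
        Number of leading (lowest-frequency) coefficients kept.
    mode
        ``"one_d"`` (default): DCT-II along the feature axis, keep the first
        ``n_coefficients``.  ``"two_d"``: reshape to ``reshape_rows x
        reshape_cols`` (zero-padded), 2-D DCT-II, zigzag read-out.
    input_length
        Expected feature count of the input; inferred when ``None``.
    reshape_rows, reshape_cols
        two_d grid; default ``rows = ceil(sqrt(N))``, ``cols = ceil(N/rows)``.
    """

    n_coefficients: int
    mode: str = "one_d"
    input_length: int | None = None
    reshape_rows: int | None = None
    reshape_cols: int | None = None
    normalization: str = field(default="orthonormal", repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("one_d", "two_d"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_coefficients < 1:
            raise ValueError("n_coefficients must be >= 1")
        if self.normalization != "orthonormal":
            raise ValueError("only orthonormal normalization is supported")

    def grid_for(self, n: int) -> tuple[int, int]:
        rows = self.reshape_rows or math.ceil(math.sqrt(n))
        cols = self.reshape_cols or math.ceil(n / rows)
        if rows * cols < n:
            raise ValueError(f"grid {rows}x{cols} cannot hold {n} features")
        return rows, cols


@dataclass
class ZigzagOrder:
    """JPEG-convention anti-diagonal traversal of a ``rows x cols`` grid."""

    grid_rows: int
    grid_cols: int
    order: list[tuple[int, int]]

    def flat_indices(self) -> np.ndarray:
        """Row-major flat index per traversal step."""
        return np.array([r * self.grid_cols + c for r, c in self.order])


def dct_forward_1d(x) -> np.ndarray:
    """Orthonormal DCT-II of a 1-D signal (energy-preserving)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    return _dct(x, type=2, norm="ortho")


def dct_inverse_1d(X) -> np.ndarray:
    """Inverse of :func:`dct_forward_1d` (orthonormal DCT-III)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 1 or X.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    return _idct(X, type=2, norm="ortho")


def zigzag_order(rows: int, cols: int) -> ZigzagOrder:
    """Enumerate grid positions along alternating anti-diagonals.

    Starts ``(0,0), (0,1), (1,0), (2,0), (1,1), (0,2), ...``; a single row
    or column degenerates to the natural order.
    """
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    order: list[tuple[int, int]] = []
    for s in range(rows + cols - 1):
        r_lo = max(0, s - cols + 1)
        r_hi = min(s, rows - 1)
        rng = range(r_lo, r_hi + 1) if s % 2 else range(r_hi, r_lo - 1, -1)
        order.extend((r, s - r) for r in rng)
    return ZigzagOrder(rows, cols, order)


def _reduce_rows(values: np.ndarray, cfg: SpectralConfig) -> np.ndarray:
    n = values.shape[1]
    if cfg.n_coefficients > n:
        raise ValueError(
            f"n_coefficients={cfg.n_coefficients} exceeds feature count {n}"
        )
    if cfg.mode == "one_d":
        coeffs = _dct(values, type=2, norm="ortho", axis=1)
        return coeffs[:, : cfg.n_coefficients]
    rows, cols = cfg.grid_for(n)
    padded = np.zeros((values.shape[0], rows * cols))
    padded[:, :n] = values
    grids = padded.reshape(values.shape[0], rows, cols)
    coeffs = _dctn(grids, type=2, norm="ortho", axes=(1, 2))
    flat = coeffs.reshape(values.shape[0], rows * cols)
    zz = zigzag_order(rows, cols).flat_indices()
    return flat[:, zz[: cfg.n_coefficients]]


def reduce_features_dct(F: FeatureMatrix, cfg: SpectralConfig) -> FeatureMatrix:
    """Shorten every feature row to its leading DCT coefficients.

    Applied row-wise with no state fitted on the data, so the same call is
    valid on train and test partitions alike.
    """
    if cfg.input_length is not None and cfg.input_length != F.n_features:
        raise ValueError(
            f"config expects {cfg.input_length} features, matrix has {F.n_features}"
        )
    reduced = _reduce_rows(F.values, cfg)
    return F.with_values(
        reduced,
        feature_origin="dct",
        spectral_mode=cfg.mode,
        n_coefficients=cfg.n_coefficients,
        source_origin=F.feature_origin,
    )


def fuse_features_dct(parts: list[FeatureMatrix], cfg: SpectralConfig) -> FeatureMatrix:
    """Concatenate several backbones' features column-wise, then DCT-reduce.

    All parts must agree on sample count, ordering and labels; the
    concatenation order of the parts is the order given (record it in
    metadata when it matters).
    """
    if not parts:
        raise ValueError("no feature matrices to fuse")
    first = parts[0]
    for p in parts[1:]:
        if p.n_samples != first.n_samples or not np.array_equal(p.labels, first.labels):
            raise ValueError("all parts must share sample count, order and labels")
    stacked = np.hstack([p.values for p in parts])
    if cfg.input_length is not None and cfg.input_length != stacked.shape[1]:
        raise ValueError(
            f"config expects {cfg.input_length} features, fusion yields {stacked.shape[1]}"
        )
    fused = _reduce_rows(stacked, cfg)
    return FeatureMatrix(
        values=fused,
        labels=first.labels.copy(),
        feature_origin="fused",
        class_names=first.class_names,
        meta={
            "part_order": [p.feature_origin for p in parts],
            "part_widths": [int(p.n_features) for p in parts],
            "spectral_mode": cfg.mode,
            "n_coefficients": cfg.n_coefficients,
        },
    )
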