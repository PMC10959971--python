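"""DCT-II, zigzag ordering, reduction and fusion against independent oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from histospect.features import FeatureMatrix
from histospect.spectral import (SpectralConfig, dct_forward_1d,
                                 dct_inverse_1d, fuse_features_dct,
                                 reduce_features_dct, zigzag_order)


def dct2_bruteforce(x):
    """Direct double-loop evaluation of the orthonormal DCT-II definition."""
    x = np.asarray(x, dtype=float)
    n = x.size
    out = np.empty(n)
    for k in range(n):
        s = np.sqrt(1.0 / n) if k == 0 else np.sqrt(2.0 / n)
        acc = 0.0
        for i in range(n):
            acc += x[i] * np.cos(np.pi * (2 * i + 1) * k / (2 * n))
        out[k] = s * acc
    return out


def zigzag_bruteforce(rows, cols):
    """Anti-diagonal enumeration with alternating direction."""
    out = []
    for s in range(rows + cols - 1):
        diag = [(r, s - r) for r in range(rows) if 0 <= s - r < cols]
        diag.sort()  # ascending row
        if s % 2 == 0:
            diag.reverse()
        out.extend(diag)
    return out


class TestDct1d:
    def test_matches_direct_summation_on_random_vectors(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 65))
            x = rng.normal(size=n)
            assert np.allclose(dct_forward_1d(x), dct2_bruteforce(x), atol=1e-12)

    def test_constant_signal_compacts_to_dc(self):
        n, c = 16, 3.5
        X = dct_forward_1d(np.full(n, c))
        assert X[0] == pytest.approx(c * np.sqrt(n), abs=1e-12)
        assert np.allclose(X[1:], 0.0, atol=1e-12)

    def test_length_one_is_identity(self):
        assert dct_forward_1d([5.0]) == pytest.approx([5.0])

    def test_example_1234(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(dct_forward_1d(x), dct2_bruteforce(x), atol=1e-12)

    def test_parseval_energy_conservation(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 200)))
            X = dct_forward_1d(x)
            assert np.sum(X**2) == pytest.approx(np.sum(x**2), rel=1e-9)

    def test_inverse_roundtrip(self, rng):
        x = rng.normal(size=129)
        assert np.allclose(dct_inverse_1d(dct_forward_1d(x)), x, atol=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dct_forward_1d(np.array([]))


class TestZigzag:
    def test_1x1(self):
        assert zigzag_order(1, 1).order == [(0, 0)]

    def test_single_row_degenerates_to_natural_order(self):
        assert zigzag_order(1, 7).order == [(0, j) for j in range(7)]

    def test_3x3_matches_antidiagonal_oracle(self):
        assert zigzag_order(3, 3).order == zigzag_bruteforce(3, 3)

    @given(rows=st.integers(1, 12), cols=st.integers(1, 12))
    def test_bijection_and_oracle_agreement(self, rows, cols):
        zz = zigzag_order(rows, cols)
        assert zz.order == zigzag_bruteforce(rows, cols)
        assert sorted(zz.order) == [(r, c) for r in range(rows)
                                    for c in range(cols)]
        assert zz.order[0] == (0, 0)
        # consecutive entries stay on the same or an adjacent anti-diagonal
        diags = [r + c for r, c in zz.order]
        assert all(0 <= b - a <= 1 for a, b in zip(diags, diags[1:]))

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            zigzag_order(0, 3)


def _fm(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = np.zeros(values.shape[0], int) if labels is None else labels
    return FeatureMatrix(values, labels)


class TestReduce:
    def test_output_width_and_labels(self, rng):
        fm = _fm(rng.normal(size=(5, 40)), labels=np.arange(5) % 2)
        out = reduce_features_dct(fm, SpectralConfig(n_coefficients=7))
        assert out.values.shape == (5, 7)
        assert np.array_equal(out.labels, fm.labels)
        assert out.feature_origin == "dct"

    def test_full_length_is_invertible(self, rng):
        fm = _fm(rng.normal(size=(4, 32)))
        out = reduce_features_dct(fm, SpectralConfig(n_coefficients=32))
        back = np.vstack([dct_inverse_1d(row) for row in out.values])
        assert np.allclose(back, fm.values, atol=1e-9)

    def test_constant_row_single_coefficient(self):
        n, c = 25, 2.0
        fm = _fm(np.full((1, n), c))
        out = reduce_features_dct(fm, SpectralConfig(n_coefficients=1))
        assert out.values[0, 0] == pytest.approx(c * np.sqrt(n))

    def test_truncation_error_monotone_in_n_keep(self, rng):
        row = rng.normal(size=(1, 256))
        errs = []
        for keep in range(1, 257, 16):
            out = reduce_features_dct(_fm(row), SpectralConfig(n_coefficients=keep))
            full = dct_forward_1d(row[0])
            recon = full.copy()
            recon[keep:] = 0.0
            errs.append(np.sum((dct_inverse_1d(recon) - row[0]) ** 2))
            assert out.values.shape[1] == keep
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_two_d_mode_zigzag_readout_is_lossless_permutation(self, rng):
        fm = _fm(rng.normal(size=(3, 36)))
        cfg = SpectralConfig(n_coefficients=36, mode="two_d",
                             reshape_rows=6, reshape_cols=6)
        out = reduce_features_dct(fm, cfg)
        # full-length zigzag read-out preserves total energy per row
        assert np.allclose((out.values**2).sum(axis=1),
                           (fm.values**2).sum(axis=1), rtol=1e-9)

    def test_row_permutation_equivariance(self, rng):
        fm = _fm(rng.normal(size=(6, 20)), labels=np.arange(6) % 3)
        cfg = SpectralConfig(n_coefficients=5)
        perm = np.array([3, 1, 5, 0, 4, 2])
        direct = reduce_features_dct(fm, cfg).values[perm]
        permuted = reduce_features_dct(
            FeatureMatrix(fm.values[perm], fm.labels[perm]), cfg).values
        assert np.array_equal(direct, permuted)

    def test_n_keep_too_large_rejected(self, rng):
        fm = _fm(rng.normal(size=(2, 10)))
        with pytest.raises(ValueError):
            reduce_features_dct(fm, SpectralConfig(n_coefficients=11))


class TestFuse:
    def test_widths_concatenate_then_truncate(self, rng):
        labels = np.arange(6) % 2
        parts = [_fm(rng.normal(size=(6, w)), labels) for w in (40, 20, 19)]
        out = fuse_features_dct(parts, SpectralConfig(n_coefficients=40))
        assert out.values.shape == (6, 40)
        assert out.feature_origin == "fused"
        assert out.meta["part_widths"] == [40, 20, 19]

    def test_half_width_ratio(self, rng):
        labels = np.zeros(4, int)
        parts = [_fm(rng.normal(size=(4, w)), labels) for w in (64, 32, 30)]
        keep = (64 + 32 + 30) // 2
        out = fuse_features_dct(parts, SpectralConfig(n_coefficients=keep))
        assert out.values.shape[1] / sum(p.n_features for p in parts) == \
            pytest.approx(0.5, abs=0.01)

    def test_single_part_equals_reduce(self, rng):
        fm = _fm(rng.normal(size=(5, 24)))
        cfg = SpectralConfig(n_coefficients=24)
        fused = fuse_features_dct([fm], cfg)
        assert np.allclose(fused.values, reduce_features_dct(fm, cfg).values)

    def test_label_mismatch_rejected(self, rng):
        a = _fm(rng.normal(size=(4, 8)), np.array([0, 0, 1, 1]))
        b = _fm(rng.normal(size=(4, 8)), np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            fuse_features_dct([a, b], SpectralConfig(n_coefficients=4))
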