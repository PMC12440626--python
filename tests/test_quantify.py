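"""Compartment measurement rules, top-k estimator, normalizations and
loess smoothing, each checked against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucflux import (estimate_background, loess_smooth, measure_cell,
                     minmax_normalize, nc_ratio, normalize_to_reference,
                     topk_mean, two_roi_cytoplasm)
from nucflux.quantify import CellMeasurement


def _disc(shape, center, r):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= r ** 2


class TestMeasureCell:
    def test_uniform_cell_equal_concentrations(self):
        img = np.full((40, 40), 5.0)
        cell = _disc(img.shape, (20, 20), 15)
        nuc = _disc(img.shape, (20, 20), 6)
        m = measure_cell(img, cell, nuc, background=0.0)
        assert m.c_nuc == pytest.approx(5.0)
        assert m.c_cyt == pytest.approx(5.0)
        assert m.c_cell == pytest.approx(5.0)

    def test_cytoplasm_by_subtraction_formula(self):
        """c_cyt = (I_cell - I_nuc) / (A_cell - A_nuc): 400/150 = 2.666..."""
        m = CellMeasurement(cell_id=0, t_min=0.0, area_cell=200.0,
                            area_nuc=50.0, i_cell=1000.0, i_nuc=600.0,
                            background=0.0)
        assert m.c_cyt == pytest.approx((1000 - 600) / (200 - 50))
        assert m.c_cyt == pytest.approx(2.666666666, rel=1e-8)

    def test_decomposition_identity_exact(self, rng):
        """I_cell = I_nuc + I_cyt and A_cell = A_nuc + A_cyt exactly."""
        for _ in range(20):
            img = rng.uniform(0, 100, size=(30, 30))
            cell = _disc(img.shape, (15, 15), 12)
            nuc = _disc(img.shape, (15, 15), 5)
            b = rng.uniform(0, 3)
            m = measure_cell(img, cell, nuc, b)
            # cytoplasm is defined by subtraction, so the identity is exact
            assert m.i_cyt == m.i_cell - m.i_nuc
            assert m.i_cell == pytest.approx(m.i_nuc + m.i_cyt, rel=1e-14)
            assert m.area_cell == m.area_nuc + m.area_cyt

    def test_negative_integral_clamped(self):
        img = np.zeros((20, 20))
        cell = _disc(img.shape, (10, 10), 8)
        m = measure_cell(img, cell, np.zeros_like(cell), background=5.0)
        assert m.i_cell == 0.0
        assert m.clamped

    def test_zero_cytoplasm_area_missing_not_error(self):
        img = np.full((20, 20), 3.0)
        cell = _disc(img.shape, (10, 10), 6)
        m = measure_cell(img, cell, cell, background=0.0)
        assert np.isnan(m.c_cyt)


class TestBackground:
    def test_constant_outside_cells(self):
        img = np.full((100, 100), 7.0)
        cells = np.zeros((100, 100), dtype=int)
        cells[40:60, 40:60] = 1
        img[cells > 0] = 50.0
        assert estimate_background(img, cells) == pytest.approx(7.0)

    def test_linearity_in_background(self):
        img = np.full((100, 100), 4.0)
        cells = np.zeros((100, 100), dtype=int)
        cells[10:30, 10:30] = 1
        b1 = estimate_background(img, cells)
        b2 = estimate_background(2 * img, cells)
        assert b2 == pytest.approx(2 * b1)

    def test_no_background_errors(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError):
            estimate_background(img, np.ones((20, 20), dtype=int))


class TestTopK:
    def test_k_equals_mask_size_is_mean(self, rng):
        img = rng.uniform(0, 10, size=(15, 15))
        mask = _disc(img.shape, (7, 7), 5)
        n = int(mask.sum())
        assert topk_mean(img, mask, n) == pytest.approx(img[mask].mean())

    def test_small_example(self):
        img = np.array([[9.0, 5.0, 5.0, 2.0, 1.0]])
        mask = np.ones_like(img, dtype=bool)
        assert topk_mean(img, mask, 3) == pytest.approx((9 + 5 + 5) / 3)

    @given(st.integers(min_value=1, max_value=60), st.integers(0, 2 ** 31))
    @settings(max_examples=30, deadline=None)
    def test_matches_full_sort_oracle(self, k, seed):
        r = np.random.default_rng(seed)
        img = r.normal(size=(12, 12))
        mask = r.random((12, 12)) < 0.7
        if mask.sum() < k:
            return
        top = np.sort(img[mask])[::-1][:k]
        got = topk_mean(img, mask, k)
        # same multiset of pixels; means may differ by summation order only
        np.testing.assert_array_equal(
            np.sort(np.partition(img[mask], img[mask].size - k)
                    [img[mask].size - k:]), np.sort(top))
        assert got == pytest.approx(float(top.mean()), rel=1e-12)

    def test_monotone_in_k(self, rng):
        img = rng.uniform(0, 5, size=(20, 20))
        mask = np.ones_like(img, dtype=bool)
        vals = [topk_mean(img, mask, k) for k in (400, 100, 40, 10, 1)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_too_few_pixels_errors(self):
        with pytest.raises(ValueError, match="fewer than k"):
            topk_mean(np.ones((3, 3)), np.ones((3, 3), bool), 40)


class TestTwoRoi:
    def _cell(self):
        shape = (40, 100)
        rr, cc = np.mgrid[0:40, 0:100]
        cell = (np.maximum(np.abs(cc - 50) - 30, 0) ** 2
                + (rr - 20) ** 2) <= 15 ** 2
        nuc = _disc(shape, (20, 50), 8)
        return cell, nuc

    def test_uniform_cytoplasm(self):
        cell, nuc = self._cell()
        img = np.where(cell, 4.0, 0.0)
        img[nuc] = 9.0
        assert two_roi_cytoplasm(img, cell, nuc) == pytest.approx(4.0)

    def test_recovers_gradient_mean_symmetrically(self):
        cell, nuc = self._cell()
        img = np.where(cell, 4.0, 0.0)
        # symmetric cell: flipping left-right leaves the estimate unchanged
        a = two_roi_cytoplasm(img, cell, nuc)
        b = two_roi_cytoplasm(img[:, ::-1], cell[:, ::-1], nuc[:, ::-1])
        assert a == pytest.approx(b)

    def test_impossible_placement_errors(self):
        shape = (30, 30)
        cell = _disc(shape, (15, 15), 9)
        nuc = _disc(shape, (15, 15), 8)   # nucleus nearly fills the cell
        img = np.ones(shape)
        with pytest.raises(ValueError):
            two_roi_cytoplasm(img, cell, nuc)


class TestRatios:
    def test_equal_concentrations_give_unity(self):
        m = CellMeasurement(0, 0.0, area_cell=100, area_nuc=20,
                            i_cell=500, i_nuc=100, background=0)
        assert nc_ratio(m) == pytest.approx(1.0)

    def test_self_normalization_mean_is_one(self, rng):
        ratios = rng.uniform(1, 4, size=50)
        out = normalize_to_reference(ratios, ratios)
        assert out.mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_cytoplasm_missing(self):
        m = CellMeasurement(0, 0.0, area_cell=100, area_nuc=20,
                            i_cell=100, i_nuc=100, background=0)
        assert np.isnan(nc_ratio(m))


class TestMinMax:
    def test_small_example(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0, 0.5, 1])

    def test_affine_invariance(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(minmax_normalize(x),
                                   minmax_normalize(3.7 * x - 11.0),
                                   atol=1e-12)

    def test_bounds_attained_on_random_traces(self, rng):
        for _ in range(1000):
            x = rng.normal(size=rng.integers(2, 40))
            y = minmax_normalize(x)
            assert y.min() == 0.0 and y.max() == 1.0

    def test_constant_trace_errors(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize(np.ones(10))


def _loess_oracle(t, y, span, degree=2):
    """Direct tricube-weighted local least squares, written independently."""
    n = len(t)
    q = min(max(int(np.ceil(span * n)), degree + 2), n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        keep = w > 0
        X = np.vander(t[idx][keep] - t[i], degree + 1, increasing=True)
        W = np.diag(w[keep])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx][keep])
        out[i] = beta[0]
    return out


class TestLoess:
    def test_reproduces_exact_quadratic(self):
        t = np.linspace(0, 10, 40)
        y = 2.0 - 0.5 * t + 0.15 * t ** 2
        for span in (0.2, 0.3, 0.8):
            np.testing.assert_allclose(loess_smooth(t, y, span), y, atol=1e-8)

    def test_constant_input(self):
        t = np.arange(20.0)
        np.testing.assert_allclose(loess_smooth(t, np.full(20, 3.3)),
                                   np.full(20, 3.3), atol=1e-10)

    def test_matches_direct_wls_oracle(self, rng):
        t = np.sort(rng.uniform(0, 12, size=60))
        y = np.sin(t) + 0.1 * rng.normal(size=60)
        ours = loess_smooth(t, y, span=0.3)
        oracle = _loess_oracle(t, y, 0.3)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            loess_smooth(np.arange(3.0), np.arange(3.0))
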