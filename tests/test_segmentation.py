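"""Otsu thresholding, cell/nucleus segmentation quality against generator
truth, nucleus-to-cell assignment, border filtering and tracking."""

import logging

import numpy as np
import pytest

from nucflux import (assign_nuclei, filter_border_cells, otsu_threshold,
                     segment_cells, segment_nuclei, track_cells)
from nucflux.pipeline import simulate_run

from conftest import tiny_run_config


def _brute_force_otsu(image, nbins=256):
    """Exhaustive search over all cut points for the between-class-variance
    maximizer, written independently of the implementation."""
    image = np.asarray(image, dtype=float).ravel()
    lo, hi = image.min(), image.max()
    hist, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    best_thr, best_var = None, -1.0
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    for cut in range(nbins - 1):
        w0 = hist[:cut + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut + 1] * centers[:cut + 1]).sum() / w0
        mu1 = (hist[cut + 1:] * centers[cut + 1:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9:
            best_var = var
            best_thr = edges[cut + 1]
    return best_thr


class TestOtsu:
    def test_matches_exhaustive_search_on_8bit(self, rng):
        """On 8-bit histograms the threshold equals brute-force search over
        all 255 cut points."""
        for _ in range(20):
            img = np.concatenate([
                rng.normal(60, 12, size=400),
                rng.normal(180, 20, size=150)])
            img = np.clip(img, 0, 255).astype(np.uint8)
            assert otsu_threshold(img) == pytest.approx(
                _brute_force_otsu(img), abs=1e-9)

    def test_tie_broken_toward_lower_threshold(self):
        # two separated clusters: every cut between them is equally good;
        # the lowest must be chosen
        img = np.array([0.0] * 50 + [1.0] * 50)
        thr = otsu_threshold(img)
        assert thr < 0.01

    def test_constant_image_raises(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 3.0))


class TestSegmentNuclei:
    def test_perfect_two_level_discs_exact(self):
        img = np.zeros((80, 80))
        rr, cc = np.mgrid[0:80, 0:80]
        d1 = (rr - 20) ** 2 + (cc - 20) ** 2 <= 64
        d2 = (rr - 55) ** 2 + (cc - 55) ** 2 <= 100
        img[d1] = 10.0
        img[d2] = 10.0
        labels = segment_nuclei(img, blur_sigma=0.0, min_area=10)
        assert labels.max() == 2
        np.testing.assert_array_equal(labels > 0, d1 | d2)

    def test_constant_image_warns_and_empty(self, caplog):
        with caplog.at_level(logging.WARNING):
            labels = segment_nuclei(np.full((30, 30), 2.0))
        assert labels.max() == 0
        assert any("constant" in r.message for r in caplog.records)

    def test_intensity_scale_invariance(self, tiny_movie):
        """Multiplying the marker channel by a constant changes the masks
        by < 1% of pixels."""
        _, movie = tiny_movie
        img = movie.channels["nls"][0]
        a = segment_nuclei(img) > 0
        b = segment_nuclei(3.0 * img) > 0
        assert np.mean(a != b) < 0.01


def _iou_per_truth_cell(pred, truth):
    ious = []
    for lab in np.unique(truth):
        if lab == 0:
            continue
        tmask = truth == lab
        vals, counts = np.unique(pred[tmask], return_counts=True)
        cand = vals[np.argmax(counts)]
        if cand == 0 and len(vals) > 1:
            cand = vals[np.argsort(counts)[-2]]
        pmask = pred == cand
        ious.append((tmask & pmask).sum() / (tmask | pmask).sum())
    return np.array(ious)


@pytest.fixture(scope="module")
def frame20():
    """One noisy rendered frame holding 20 cells."""
    cfg = tiny_run_config(n_cells=20, frame_interval_s=300.0,
                          field=(768, 512))
    cfg.movie_end_min = 0.0   # a single frame suffices
    movie = simulate_run(cfg)
    return cfg, movie


class TestSegmentationQuality:

    def test_two_disjoint_capsules_two_labels(self, tiny_movie_noisefree):
        _, movie = tiny_movie_noisefree
        labels = segment_cells(movie.channels["outline"][0])
        assert labels.max() == 2

    def test_cell_iou_against_truth(self, frame20):
        cfg, movie = frame20
        pred = segment_cells(movie.channels["outline"][0])
        ious = _iou_per_truth_cell(pred, movie.cell_labels[0])
        assert len(ious) == 20
        assert (ious >= 0.9).all()

    def test_nucleus_iou_against_truth(self, frame20):
        cfg, movie = frame20
        pred = segment_nuclei(movie.channels["nls"][0])
        ious = _iou_per_truth_cell(pred, movie.nucleus_labels[0])
        assert (ious >= 0.85).all()

    def test_empty_image_empty_map(self):
        assert segment_cells(np.zeros((20, 20))).max() == 0


class TestAssignNuclei:
    def test_contained_nucleus_assigned(self):
        cells = np.zeros((30, 30), dtype=int)
        cells[5:25, 5:25] = 3
        nucs = np.zeros_like(cells)
        nucs[10:15, 10:15] = 7
        mapping, dropped = assign_nuclei(cells, nucs)
        assert mapping == {7: 3}
        assert dropped == []

    def test_background_centroid_dropped(self):
        cells = np.zeros((30, 30), dtype=int)
        cells[0:5, 0:5] = 1
        nucs = np.zeros_like(cells)
        nucs[20:25, 20:25] = 2
        mapping, dropped = assign_nuclei(cells, nucs)
        assert mapping == {}
        assert dropped == [2]

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            assign_nuclei(np.zeros((5, 5), int), np.zeros((6, 6), int))

    def test_matches_overlap_oracle_on_random_frames(self, rng):
        """Centroid assignment agrees with maximal-pixel-overlap assignment
        whenever the nucleus overlaps its cell by >= 50%."""
        for _ in range(50):
            cells = np.zeros((64, 96), dtype=int)
            nucs = np.zeros_like(cells)
            # disjoint slots with jitter: nuclei stay convex, as in frames
            for lab in (1, 2, 3):
                r0 = int(rng.integers(2, 40))
                c0 = (lab - 1) * 32 + int(rng.integers(0, 10))
                cells[r0:r0 + 20, c0:c0 + 20] = lab
                nucs[r0 + 6:r0 + 12, c0 + 6:c0 + 12] = lab * 10
            mapping, _ = assign_nuclei(cells, nucs)
            for nuc in np.unique(nucs):
                if nuc == 0:
                    continue
                nmask = nucs == nuc
                vals, counts = np.unique(cells[nmask], return_counts=True)
                best = vals[np.argmax(counts)]
                frac = counts.max() / nmask.sum()
                if best != 0 and frac >= 0.5:
                    assert mapping.get(int(nuc)) == int(best)
            # the mapping is a function: one cell per nucleus by construction
            assert len(mapping) == len(set(mapping.keys()))


class TestBorderFilter:
    def test_interior_cells_unchanged(self):
        cells = np.zeros((20, 20), dtype=int)
        cells[5:10, 5:10] = 1
        out, excluded = filter_border_cells(cells)
        np.testing.assert_array_equal(out, cells)
        assert excluded == []

    def test_edge_spanning_cell_removed(self):
        cells = np.zeros((20, 20), dtype=int)
        cells[8:12, 0:6] = 2
        cells[5:10, 10:15] = 3
        out, excluded = filter_border_cells(cells)
        assert excluded == [2]
        assert set(np.unique(out)) == {0, 3}

    def test_matches_direct_set_oracle(self, rng):
        for _ in range(20):
            cells = rng.integers(0, 5, size=(16, 16))
            _, excluded = filter_border_cells(cells)
            oracle = {int(v) for v in np.concatenate(
                [cells[0], cells[-1], cells[:, 0], cells[:, -1]]) if v != 0}
            assert set(excluded) == oracle


class TestTracking:
    def test_static_cell_single_id(self):
        frame = np.zeros((20, 20), dtype=int)
        frame[5:15, 5:15] = 1
        res = track_cells([frame] * 10)
        ids = {m[1] for m in res.frame_maps}
        assert ids == {1}
        assert res.starts[1] == 0 and res.ends[1] == 9

    def test_division_spawns_two_children(self):
        before = np.zeros((20, 40), dtype=int)
        before[5:15, 5:35] = 1
        after = np.zeros_like(before)
        after[5:15, 5:18] = 1
        after[5:15, 22:35] = 2
        res = track_cells([before, before, after, after])
        parent = res.frame_maps[0][1]
        children = set(res.frame_maps[2].values())
        assert parent not in children
        assert len(children) == 2
        assert all(res.parents[c] == parent for c in children)
        assert res.ends[parent] == 1

    def test_links_agree_with_generator_truth(self, tiny_movie):
        """On truth label stacks every frame-wise link follows the truth."""
        _, movie = tiny_movie
        res = track_cells(list(movie.cell_labels))
        stacks = res.relabel(movie.cell_labels)
        agree = 0
        total = 0
        for k in range(1, movie.n_frames):
            for lab in np.unique(movie.cell_labels[k]):
                if lab == 0:
                    continue
                total += 1
                cur = stacks[k][movie.cell_labels[k] == lab]
                prev = stacks[k - 1][movie.cell_labels[k - 1] == lab]
                if cur.max() == prev.max():
                    agree += 1
        assert agree / total >= 0.99
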