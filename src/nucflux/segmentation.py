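"""Classical cell/nucleus segmentation and frame-to-frame tracking.

Nuclei are segmented by Gaussian blur followed by global Otsu thresholding
of the nuclear-marker channel; cells by the same operators on a uniform
cell-body proxy channel. Nuclei are assigned to cells by centroid position,
border-touching cells are excluded, and cells are linked across frames by
maximal pixel overlap. A truth-passthrough mode (at the pipeline level)
allows downstream quantification to be exercised independently of
segmentation quality.

Otsu here works on a 256-bin histogram of the min-max-scaled blurred image;
between equally good thresholds the lower one is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

log = logging.getLogger(__name__)

__all__ = [
    "otsu_threshold", "segment_cells", "segment_nuclei",
    "assign_nuclei", "filter_border_cells",
    "track_cells", "TrackResult", "LabelMaps",
]


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Global Otsu threshold maximizing between-class variance.

    The histogram is built over ``nbins`` equal bins spanning the image
    range; ties are broken toward the lower threshold. Returns a value in
    the image's own intensity scale; pixels strictly above it are
    foreground.
    """
    image = np.asarray(image, dtype=float).ravel()
    lo, hi = image.min(), image.max()
    if hi <= lo:
        raise ValueError("constant image has no Otsu threshold")
    hist, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)
    w1 = w0[-1] - w0
    m0 = np.cumsum(hist * centers)
    mtot = m0[-1]
    # candidate cuts after bin i (i = 0..nbins-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (mtot - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0)
    idx = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximum
    return float(edges[idx + 1])


def _threshold_label(image, blur_sigma, min_area):
    image = np.asarray(image, dtype=float)
    if image.max() <= image.min():
        log.warning("constant image: no threshold exists, returning empty map")
        return np.zeros(image.shape, dtype=np.int32)
    blurred = (ndimage.gaussian_filter(image, blur_sigma)
               if blur_sigma > 0 else image)
    if blurred.max() <= blurred.min():
        log.warning("image constant after blur, returning empty map")
        return np.zeros(image.shape, dtype=np.int32)
    thr = otsu_threshold(blurred)
    mask = blurred > thr
    mask = ndimage.binary_fill_holes(mask)
    lab = cc_label(mask).astype(np.int32)
    if min_area > 1 and lab.max() > 0:
        counts = np.bincount(lab.ravel())
        keep = counts >= min_area
        keep[0] = False
        lut = np.zeros(counts.size, dtype=np.int32)
        lut[keep] = np.arange(1, int(keep.sum()) + 1)
        lab = lut[lab]
    return lab


def segment_cells(outline_channel: np.ndarray, blur_sigma: float = 1.5,
                  min_area: int = 100,
                  split_area_px: int | None = None) -> np.ndarray:
    """Segment cells from the high-contrast cell-body proxy channel.

    Blur + Otsu + hole filling + small-object removal; optionally splits
    components larger than ``split_area_px`` by distance-transform
    watershed (for touching cells). An empty image yields an empty map.
    """
    labels = _threshold_label(outline_channel, blur_sigma, min_area)
    if split_area_px:
        labels = _split_large(labels, split_area_px)
    return labels


def _split_large(labels: np.ndarray, split_area_px: int) -> np.ndarray:
    out = labels.copy()
    next_label = labels.max() + 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        if mask.sum() <= split_area_px:
            continue
        dist = ndimage.distance_transform_edt(mask)
        # seeds: strong maxima of the distance map
        seeds_mask = dist > 0.7 * dist.max()
        seeds = cc_label(seeds_mask)
        if seeds.max() < 2:
            continue
        parts = watershed(-dist, seeds, mask=mask)
        for p in range(1, parts.max() + 1):
            out[parts == p] = next_label
            next_label += 1
    return out


def segment_nuclei(marker_channel: np.ndarray, blur_sigma: float = 1.5,
                   min_area: int = 30) -> np.ndarray:
    """Segment nuclei: Gaussian blur, global Otsu, hole filling, labeling.

    A constant image has no threshold; a warning is logged and an empty
    label map returned.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    return _threshold_label(marker_channel, blur_sigma, min_area)


def assign_nuclei(cells: np.ndarray, nuclei: np.ndarray
                  ) -> tuple[dict[int, int], list[int]]:
    """Assign each nucleus to the cell containing its centroid.

    Returns ``(mapping, dropped)``: nuclei whose centroid falls on
    background are dropped (and logged). A cell may carry two nuclei after
    anaphase. The mapping is a function — no nucleus maps to two cells.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    if cells.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: cells {cells.shape} vs "
                         f"nuclei {nuclei.shape}")
    mapping: dict[int, int] = {}
    dropped: list[int] = []
    nuc_ids = [int(v) for v in np.unique(nuclei) if v != 0]
    if not nuc_ids:
        return mapping, dropped
    centroids = ndimage.center_of_mass(np.ones_like(nuclei), nuclei, nuc_ids)
    for nuc_id, (cr, cc) in zip(nuc_ids, centroids):
        r = int(round(cr))
        c = int(round(cc))
        r = min(max(r, 0), cells.shape[0] - 1)
        c = min(max(c, 0), cells.shape[1] - 1)
        cell = int(cells[r, c])
        if cell == 0:
            dropped.append(nuc_id)
            log.info("nucleus %d dropped: centroid on background", nuc_id)
        else:
            mapping[nuc_id] = cell
    return mapping, dropped


def filter_border_cells(cells: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Remove cell labels touching any image edge; return them as a list."""
    cells = np.asarray(cells)
    border = np.concatenate([cells[0, :], cells[-1, :],
                             cells[:, 0], cells[:, -1]])
    excluded = sorted(int(v) for v in np.unique(border) if v != 0)
    out = cells.copy()
    if excluded:
        out[np.isin(out, excluded)] = 0
    return out, excluded


@dataclass
class TrackResult:
    """Stable cell identities across frames.

    ``frame_maps[k]`` maps the frame-``k`` label to a track id; tracks
    record their frame span and parent (for divisions).
    """

    frame_maps: list[dict[int, int]]
    parents: dict[int, int] = field(default_factory=dict)
    starts: dict[int, int] = field(default_factory=dict)
    ends: dict[int, int] = field(default_factory=dict)

    def relabel(self, label_stack: np.ndarray) -> np.ndarray:
        """Rewrite per-frame labels as stable track ids."""
        out = np.zeros_like(label_stack, dtype=np.int32)
        for k, m in enumerate(self.frame_maps):
            lut = np.zeros(int(label_stack[k].max()) + 1, dtype=np.int32)
            for lab, tid in m.items():
                lut[lab] = tid
            out[k] = lut[label_stack[k]]
        return out


def _overlap_matrix(prev: np.ndarray, cur: np.ndarray):
    """Pixel-overlap counts between labels of two frames."""
    both = (prev.ravel().astype(np.int64) * (int(cur.max()) + 1)
            + cur.ravel().astype(np.int64))
    counts = np.bincount(both[(prev.ravel() != 0) & (cur.ravel() != 0)])
    pairs = {}
    base = int(cur.max()) + 1
    for idx in np.nonzero(counts)[0]:
        pairs[(int(idx // base), int(idx % base))] = int(counts[idx])
    return pairs


def track_cells(label_stack: list[np.ndarray] | np.ndarray,
                min_overlap_frac: float = 0.3) -> TrackResult:
    """Greedy max-overlap linking of cell labels across frames.

    A track is born at first appearance. When two regions in the current
    frame both best-overlap the same previous region (a division), the
    parent track ends and both children start new ids with the parent
    recorded. Unlinked regions start new tracks.
    """
    stack = [np.asarray(f) for f in label_stack]
    if len(stack) == 0:
        raise ValueError("need at least one frame")
    next_id = 1
    frame_maps: list[dict[int, int]] = []
    parents: dict[int, int] = {}
    starts: dict[int, int] = {}
    ends: dict[int, int] = {}

    first = {}
    for lab in (int(v) for v in np.unique(stack[0]) if v != 0):
        first[lab] = next_id
        starts[next_id] = 0
        ends[next_id] = 0
        next_id += 1
    frame_maps.append(first)

    for k in range(1, len(stack)):
        prev, cur = stack[k - 1], stack[k]
        overlaps = _overlap_matrix(prev, cur)
        cur_areas = {int(v): int((cur == v).sum())
                     for v in np.unique(cur) if v != 0}
        # best previous label for each current label
        best_prev: dict[int, int] = {}
        for (p, c), cnt in overlaps.items():
            if cnt < min_overlap_frac * cur_areas[c]:
                continue
            if c not in best_prev or overlaps[(best_prev[c], c)] < cnt:
                best_prev[c] = p
        claimed: dict[int, list[int]] = {}
        for c, p in best_prev.items():
            claimed.setdefault(p, []).append(c)

        cur_map: dict[int, int] = {}
        for p, cs in claimed.items():
            ptid = frame_maps[k - 1].get(p)
            if ptid is None:
                cs_unlinked = cs
            elif len(cs) == 1:
                cur_map[cs[0]] = ptid
                ends[ptid] = k
                continue
            else:
                # division: parent ends, children start new ids
                cs_unlinked = cs
            for c in cs_unlinked:
                cur_map[c] = next_id
                if ptid is not None:
                    parents[next_id] = ptid
                starts[next_id] = k
                ends[next_id] = k
                next_id += 1
        for c in cur_areas:
            if c not in cur_map:
                cur_map[c] = next_id
                starts[next_id] = k
                ends[next_id] = k
                next_id += 1
        frame_maps.append(cur_map)
    return TrackResult(frame_maps=frame_maps, parents=parents,
                       starts=starts, ends=ends)


@dataclass
class LabelMaps:
    """Per-frame segmentation output with nucleus-to-cell assignments."""

    cell_labels: np.ndarray                 # (T, H, W), track-stable ids
    nucleus_labels: np.ndarray              # (T, H, W)
    nucleus_to_cell: list[dict[int, int]]
    excluded_border: list[list[int]]
    dropped_nuclei: list[list[int]] = field(default_factory=list)
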