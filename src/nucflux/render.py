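"""Render ground-truth populations into synthetic multi-channel movies.

Cells are rod-shaped capsules with a disc nucleus; the reporter is uniform
per compartment and SPB foci are sub-pixel points. Frames are already
projected 2-D images (the imaging they emulate uses a sum projection along
the optical axis), composed as

    expected counts = background + photon_scale * (amount map (*) Gaussian PSF)

with Poisson shot noise on the expected counts plus Gaussian read noise.
Per-compartment amounts are spread uniformly over the compartment's pixels,
so the integrated reporter signal equals the compartment amount exactly
before noise.

Channels: ``outline`` (a uniform cell-body proxy used for cell
segmentation), ``nls`` (nuclear marker; splits into two objects at
anaphase), ``reporter`` (the species' own fluorophore, including any SPB
focus). Coordinates are pixel-centred, row-major, origin top-left; masks
and images share this convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .config import OpticsConfig, load_config, save_config
from .kinetics import GroundTruthTrace

__all__ = [
    "CellPlacement", "PlacementError", "Movie",
    "plan_layout", "render_frame", "render_movie",
    "write_movie", "read_movie",
]

#: per-pixel amounts (a.u.) of the two structural proxy channels
OUTLINE_LEVEL = 0.04
NLS_LEVEL = 0.10

#: nuclear split geometry at anaphase (µm, µm/min): the two daughter nuclei
#: appear already resolved at the anaphase frame and then move apart, so the
#: truth event time coincides with the first frame showing two objects.
NUCLEAR_SPLIT_D0_UM = 3.0
NUCLEAR_SPLIT_SPEED = 1.0
#: SPB foci separation at spindle formation (µm, µm/min)
SPB_SPLIT_D0_UM = 1.2
SPB_SPLIT_SPEED = 0.25


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed in the field without overlap."""


@dataclass
class CellPlacement:
    cell_id: int
    center_rc: tuple[float, float]   # (row, col), px
    angle_rad: float                 # long-axis angle w.r.t. the column axis


def plan_layout(traces: list[GroundTruthTrace], optics: OpticsConfig,
                rng: np.random.Generator | None = None) -> list[CellPlacement]:
    """Assign non-overlapping grid slots (with small jitter and tilt).

    Deterministic given ``rng``; raises :class:`PlacementError` naming the
    cells that do not fit in the field.
    """
    if not traces:
        raise ValueError("empty population")
    if rng is None:
        rng = np.random.default_rng(0)
    h, w = optics.field_shape_px
    px = optics.pixel_size_um
    max_len = max(t.division_length_um for t in traces) / px
    width = max(t.kinetics.cell_width_um for t in traces) / px
    max_tilt = 0.12
    # extent of a tilted capsule: inner segment length (L - W) projected,
    # plus the full cap width, plus clearance
    inner = max(max_len - width, 0.0)
    slot_w = inner * math.cos(max_tilt) + width + 10
    slot_h = inner * math.sin(max_tilt) + width + 10
    ncols = max(1, int(w // slot_w))
    nrows = max(1, int(h // slot_h))
    capacity = ncols * nrows
    if len(traces) > capacity:
        bad = [t.cell_id for t in traces[capacity:]]
        raise PlacementError(
            f"field {h}x{w} px holds {capacity} cells of length {max_len:.0f} px; "
            f"cannot place cells {bad}")
    placements = []
    for i, tr in enumerate(traces):
        r_slot, c_slot = divmod(i, ncols)
        cr = (r_slot + 0.5) * slot_h + (h - nrows * slot_h) / 2
        cc = (c_slot + 0.5) * slot_w + (w - ncols * slot_w) / 2
        jr, jc = rng.uniform(-3, 3, size=2)
        angle = rng.uniform(-max_tilt, max_tilt)
        placements.append(CellPlacement(tr.cell_id, (cr + jr, cc + jc), angle))
    return placements


def _capsule_mask(shape, center_rc, angle, length_px, width_px):
    """Boolean mask of a capsule (segment dilated by width/2).

    Computed on a local bounding box for speed and scattered into the full
    field.
    """
    h, w = shape
    half = max(length_px / 2 - width_px / 2, 0.0)
    ur, uc = math.sin(angle), math.cos(angle)   # long-axis direction
    reach = length_px / 2 + width_px / 2 + 2
    r0 = max(int(center_rc[0] - reach), 0)
    r1 = min(int(center_rc[0] + reach) + 2, h)
    c0 = max(int(center_rc[1] - reach), 0)
    c1 = min(int(center_rc[1] + reach) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dr = rr - center_rc[0]
    dc = cc - center_rc[1]
    along = dr * ur + dc * uc
    perp = -dr * uc + dc * ur
    over = np.maximum(np.abs(along) - half, 0.0)
    local = over ** 2 + perp ** 2 <= (width_px / 2) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    return mask, (ur, uc)


def _disc_mask(shape, center_rc, radius_px):
    h, w = shape
    r0 = max(int(center_rc[0] - radius_px) - 1, 0)
    r1 = min(int(center_rc[0] + radius_px) + 2, h)
    c0 = max(int(center_rc[1] - radius_px) - 1, 0)
    c1 = min(int(center_rc[1] + radius_px) + 2, w)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    local = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 <= radius_px ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    return mask


def _splat_point(img: np.ndarray, r: float, c: float, amount: float) -> None:
    """Bilinear deposition of a point amount onto the 4 nearest pixels."""
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    fr, fc = r - r0, c - c0
    h, w = img.shape
    for dr, wr in ((0, 1 - fr), (1, fr)):
        for dc, wc in ((0, 1 - fc), (1, fc)):
            rr, cc = r0 + dr, c0 + dc
            if 0 <= rr < h and 0 <= cc < w:
                img[rr, cc] += amount * wr * wc


def _cell_geometry(tr: GroundTruthTrace, t: float, place: CellPlacement,
                   optics: OpticsConfig):
    """Pixel-space geometry of one cell at absolute time ``t``."""
    px = optics.pixel_size_um
    state = tr.at(t)
    length_px = float(state["cell_length_um"]) / px
    width_px = tr.kinetics.cell_width_um / px
    nuc_area_px = float(state["nuclear_area_um2"]) / optics.pixel_area_um2
    t_ana = tr.events["anaphase"]
    t_sep = tr.events["spb_separation"]
    cr, cc = place.center_rc
    ur, uc = math.sin(place.angle_rad), math.cos(place.angle_rad)

    def on_axis(offset_px):
        return (cr + ur * offset_px, cc + uc * offset_px)

    if t < t_ana:
        r_nuc = math.sqrt(nuc_area_px / math.pi)
        nuclei = [(place.center_rc, r_nuc)]
    else:
        r_nuc = math.sqrt(nuc_area_px / (2 * math.pi))
        d_um = NUCLEAR_SPLIT_D0_UM + NUCLEAR_SPLIT_SPEED * (t - t_ana)
        d = min(d_um / px, max(length_px - width_px, 0.0))
        nuclei = [(on_axis(-d / 2), r_nuc), (on_axis(d / 2), r_nuc)]

    if t < t_sep:
        foci = [on_axis(r_nuc)]
    else:
        if t < t_ana:
            d_um = SPB_SPLIT_D0_UM + SPB_SPLIT_SPEED * (t - t_sep)
            d = min(d_um / px, max(length_px - width_px, 0.0))
            foci = [on_axis(-d / 2), on_axis(d / 2)]
        else:
            d_um = NUCLEAR_SPLIT_D0_UM + NUCLEAR_SPLIT_SPEED * (t - t_ana)
            off = min(d_um / px, max(length_px - width_px, 0.0)) / 2 + r_nuc
            foci = [on_axis(-off), on_axis(off)]
    return length_px, width_px, nuclei, foci, state


def render_frame(
    traces: list[GroundTruthTrace],
    t: float,
    optics: OpticsConfig,
    seed: int | np.random.Generator | None = 0,
    layout: list[CellPlacement] | None = None,
    noise: bool | None = None,
):
    """Render all channels and truth masks for one frame at time ``t`` (min).

    Returns ``(channels, cell_labels, nucleus_labels, nucleus_to_cell)``.
    Cells whose lifetime does not include ``t`` are absent from the frame.
    Deterministic given ``seed``.
    """
    if layout is None:
        layout = plan_layout(traces, optics)
    if noise is None:
        noise = optics.shot_noise
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = optics.field_shape_px
    maps = {name: np.zeros(shape) for name in ("outline", "nls", "reporter")}
    cell_labels = np.zeros(shape, dtype=np.uint16)
    nucleus_labels = np.zeros(shape, dtype=np.uint16)
    nuc2cell: dict[int, int] = {}
    place_by_id = {p.cell_id: p for p in layout}

    for tr in traces:
        if not tr.alive_at(t):
            continue
        place = place_by_id[tr.cell_id]
        length_px, width_px, nuclei, foci, state = _cell_geometry(
            tr, t, place, optics)
        cell_mask, _ = _capsule_mask(shape, place.center_rc, place.angle_rad,
                                     length_px, width_px)
        label = tr.cell_id + 1
        if np.any(cell_labels[cell_mask] != 0):
            raise PlacementError(f"cell {tr.cell_id} overlaps a previously "
                                 "placed cell")
        cell_labels[cell_mask] = label

        nuc_mask_total = np.zeros(shape, dtype=bool)
        for k, (center, radius) in enumerate(nuclei):
            m = _disc_mask(shape, center, radius) & cell_mask
            nuc_label = 2 * label - 1 + k
            nucleus_labels[m] = nuc_label
            if m.any():
                nuc2cell[nuc_label] = label
            nuc_mask_total |= m
        cyto_mask = cell_mask & ~nuc_mask_total

        maps["outline"][cell_mask] += OUTLINE_LEVEL
        maps["nls"][nuc_mask_total] += NLS_LEVEL
        n_nuc = int(nuc_mask_total.sum())
        n_cyt = int(cyto_mask.sum())
        if n_nuc:
            maps["reporter"][nuc_mask_total] += float(state["nuclear_amount"]) / n_nuc
        if n_cyt:
            maps["reporter"][cyto_mask] += float(state["cytoplasmic_amount"]) / n_cyt
        s_amt = float(state["spb_amount"])
        if s_amt > 0 and foci:
            per = s_amt / len(foci)
            for (fr, fc) in foci:
                _splat_point(maps["reporter"], fr, fc, per)

    channels = {}
    for name, amount_map in maps.items():
        if optics.psf_sigma_px > 0:
            blurred = gaussian_filter(amount_map, optics.psf_sigma_px,
                                      mode="constant")
        else:
            blurred = amount_map
        expected = optics.background_level + optics.photon_scale * blurred
        if noise:
            img = rng.poisson(expected).astype(float)
            if optics.read_noise_sd > 0:
                img += rng.normal(0.0, optics.read_noise_sd, size=shape)
            channels[name] = img
        else:
            channels[name] = expected
    return channels, cell_labels, nucleus_labels, nuc2cell


@dataclass
class Movie:
    """A rendered time-lapse with its ground truth."""

    times_min: np.ndarray
    channels: dict[str, np.ndarray]       # name -> (T, H, W)
    optics: OpticsConfig
    cell_labels: np.ndarray               # (T, H, W) uint16
    nucleus_labels: np.ndarray
    nucleus_to_cell: list[dict[int, int]]
    events: pd.DataFrame                  # per-cell truth event times
    layout: list[CellPlacement] = field(default_factory=list)
    traces: list[GroundTruthTrace] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.times_min)

    def truth_table(self) -> pd.DataFrame:
        """Per-cell, per-frame truth amounts interpolated to frame times."""
        rows = []
        for tr in self.traces:
            for t in self.times_min:
                if not tr.alive_at(t):
                    continue
                state = tr.at(t)
                rows.append({"cell_id": tr.cell_id, "species": tr.species,
                             "t_min": t, **{k: float(v) for k, v in state.items()}})
        return pd.DataFrame(rows)


def render_movie(
    population: list[GroundTruthTrace],
    optics: OpticsConfig,
    seed: int = 0,
    t_start_min: float = 0.0,
    t_end_min: float | None = None,
) -> Movie:
    """Render frames at multiples of the frame interval over a window.

    Frame ``k`` uses the counter-derived substream ``SeedSequence([seed, k])``
    so renders are reproducible and frame-order independent.
    """
    if not population:
        raise ValueError("empty population")
    if t_end_min is None:
        t_end_min = max(tr.events["division"] for tr in population)
    dt = optics.frame_interval_min
    n_frames = int(math.floor((t_end_min - t_start_min) / dt + 1e-9)) + 1
    times = t_start_min + dt * np.arange(n_frames)
    layout_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 999983]))
    layout = plan_layout(population, optics, layout_rng)

    shape = optics.field_shape_px
    channels = {n: np.empty((n_frames, *shape), dtype=np.float64)
                for n in ("outline", "nls", "reporter")}
    cell_l = np.empty((n_frames, *shape), dtype=np.uint16)
    nuc_l = np.empty_like(cell_l)
    nuc2cell = []
    for k, t in enumerate(times):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        ch, cl, nl, n2c = render_frame(population, float(t), optics, rng, layout)
        for name in channels:
            channels[name][k] = ch[name]
        cell_l[k] = cl
        nuc_l[k] = nl
        nuc2cell.append(n2c)

    events = pd.DataFrame([{"cell_id": tr.cell_id, "species": tr.species,
                            **tr.events} for tr in population])
    return Movie(times_min=times, channels=channels, optics=optics,
                 cell_labels=cell_l, nucleus_labels=nuc_l,
                 nucleus_to_cell=nuc2cell, events=events,
                 layout=layout, traces=population)


# ---------------------------------------------------------------------------
# disk round-trip: multi-page TIFF per channel + JSON sidecar + truth CSVs


def write_movie(movie: Movie, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, stack in movie.channels.items():
        tifffile.imwrite(outdir / f"channel_{name}.tif",
                         stack.astype(np.float32))
    tifffile.imwrite(outdir / "truth_cell_labels.tif", movie.cell_labels)
    tifffile.imwrite(outdir / "truth_nucleus_labels.tif", movie.nucleus_labels)
    movie.events.to_csv(outdir / "truth_events.csv", index=False)
    movie.truth_table().to_csv(outdir / "truth_table.csv", index=False)
    save_config(movie.optics, outdir / "optics.yaml")
    sidecar = {
        "times_min": [float(t) for t in movie.times_min],
        "channel_order": sorted(movie.channels),
        "nucleus_to_cell": [{str(k): int(v) for k, v in d.items()}
                            for d in movie.nucleus_to_cell],
    }
    (outdir / "movie.json").write_text(json.dumps(sidecar, indent=2))


def read_movie(indir: str | Path) -> Movie:
    indir = Path(indir)
    sidecar = json.loads((indir / "movie.json").read_text())
    optics = load_config(indir / "optics.yaml", OpticsConfig)
    channels = {}
    for path in sorted(indir.glob("channel_*.tif")):
        name = path.stem.removeprefix("channel_")
        channels[name] = tifffile.imread(path).astype(np.float64)
    cell_l = tifffile.imread(indir / "truth_cell_labels.tif")
    nuc_l = tifffile.imread(indir / "truth_nucleus_labels.tif")
    events = pd.read_csv(indir / "truth_events.csv")
    return Movie(
        times_min=np.asarray(sidecar["times_min"], dtype=float),
        channels=channels, optics=optics,
        cell_labels=cell_l, nucleus_labels=nuc_l,
        nucleus_to_cell=[{int(k): v for k, v in d.items()}
                         for d in sidecar["nucleus_to_cell"]],
        events=events)
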