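"""End-to-end pipeline: simulate -> segment -> quantify -> events ->
change-points, with a trace-only entry point that skips the imaging stages.

All stages are deterministic given the run config's seed (analysis itself
uses no randomness), so re-running a stage reproduces its tables exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import events as ev
from . import quantify as qt
from .changepoint import estimate_export_window, transition_width
from .config import RunConfig, save_config, _to_dict
from .kinetics import sample_population
from .render import Movie, render_movie, write_movie
from .segmentation import (LabelMaps, assign_nuclei, filter_border_cells,
                           segment_cells, segment_nuclei, track_cells)

log = logging.getLogger(__name__)

__all__ = [
    "config_hash", "simulate_run", "segment_movie", "measure_movie",
    "detect_events", "export_window_table", "analyze_movie",
    "analyze_traces",
]


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def simulate_run(config: RunConfig, outdir: str | Path | None = None) -> Movie:
    """Generate a population and render its movie; optionally write to disk."""
    if config.n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    population = sample_population(
        config.timeline, config.n_cells, seed=config.seed,
        species=config.species,
        anaphase_time_min=config.anaphase_time_min,
        dt_out_min=min(config.optics.frame_interval_min, 0.25))
    movie = render_movie(population, config.optics, seed=config.seed,
                         t_start_min=config.movie_start_min,
                         t_end_min=config.movie_end_min)
    if outdir is not None:
        outdir = Path(outdir)
        write_movie(movie, outdir)
        save_config(config, outdir / "run_config.yaml")
    return movie


def segment_movie(movie: Movie, config: RunConfig) -> LabelMaps:
    """Per-frame cell and nucleus segmentation, tracking, assignment.

    In passthrough mode the movie's truth masks are used directly (labels
    are already track-stable); otherwise classical segmentation runs on the
    outline and nuclear-marker channels and cells are linked by overlap.
    """
    seg = config.segmentation
    n_frames = movie.n_frames
    if seg.passthrough:
        cell_stack = movie.cell_labels.astype(np.int32)
        nuc_stack = movie.nucleus_labels.astype(np.int32)
    else:
        cells = [segment_cells(movie.channels["outline"][k],
                               blur_sigma=seg.blur_sigma_px,
                               min_area=seg.min_cell_area_px)
                 for k in range(n_frames)]
        track = track_cells(cells)
        cell_stack = track.relabel(np.stack(cells))
        nuc_stack = np.stack([segment_nuclei(movie.channels["nls"][k],
                                             blur_sigma=seg.blur_sigma_px,
                                             min_area=seg.min_nucleus_area_px)
                              for k in range(n_frames)]).astype(np.int32)
    excluded = []
    assignments = []
    dropped_all = []
    for k in range(n_frames):
        filtered, exc = filter_border_cells(cell_stack[k])
        cell_stack[k] = filtered
        mapping, dropped = assign_nuclei(filtered, nuc_stack[k])
        excluded.append(exc)
        assignments.append(mapping)
        dropped_all.append(dropped)
    return LabelMaps(cell_labels=cell_stack, nucleus_labels=nuc_stack,
                     nucleus_to_cell=assignments, excluded_border=excluded,
                     dropped_nuclei=dropped_all)


def _cell_bbox(mask: np.ndarray, pad: int = 2):
    rr, cc = np.nonzero(mask)
    return (slice(max(rr.min() - pad, 0), rr.max() + pad + 1),
            slice(max(cc.min() - pad, 0), cc.max() + pad + 1))


def measure_movie(movie: Movie, maps: LabelMaps, config: RunConfig,
                  channel: str = "reporter") -> pd.DataFrame:
    """Per-cell, per-frame compartment measurements from one channel.

    Background is estimated per frame from off-cell regions. Nuclei
    assigned to a cell are summed (both daughters post-anaphase). The
    top-k brightest-pixel estimate and the cell length (principal-axis
    extent, µm) are included for every cell.
    """
    q = config.quant
    px_um = movie.optics.pixel_size_um
    rows = []
    for k in range(movie.n_frames):
        img = movie.channels[channel][k]
        cells = maps.cell_labels[k]
        nucs = maps.nucleus_labels[k]
        assign = maps.nucleus_to_cell[k]
        b = qt.estimate_background(img, cells, n_rois=q.background_rois,
                                   roi_px=q.background_roi_px)
        slices = ndimage.find_objects(cells)
        for cid in (int(v) for v in np.unique(cells) if v != 0):
            sl = slices[cid - 1]
            img_c = img[sl]
            cell_mask = cells[sl] == cid
            nuc_ids = [n for n, c in assign.items() if c == cid]
            nuc_mask = np.isin(nucs[sl], nuc_ids) & cell_mask
            m = qt.measure_cell(img_c, cell_mask, nuc_mask, b,
                                cell_id=cid, t_min=float(movie.times_min[k]))
            n_px = int(cell_mask.sum())
            topk = (qt.topk_mean(img_c, cell_mask, q.topk)
                    if n_px >= q.topk else np.nan)
            rr, cc = np.nonzero(cell_mask)
            cr, ccol = rr.mean(), cc.mean()
            cov = np.cov(np.vstack([rr - cr, cc - ccol]))
            evals, evecs = np.linalg.eigh(cov)
            axis = evecs[:, np.argmax(evals)]
            along = (rr - cr) * axis[0] + (cc - ccol) * axis[1]
            length_um = float(np.ptp(along) + 1) * px_um
            rows.append({
                "cell_id": cid, "t_min": float(movie.times_min[k]),
                "frame": k,
                "area_cell_px2": m.area_cell, "area_nuc_px2": m.area_nuc,
                "area_cyt_px2": m.area_cyt,
                "i_cell": m.i_cell, "i_nuc": m.i_nuc, "i_cyt": m.i_cyt,
                "c_cell": m.c_cell, "c_nuc": m.c_nuc, "c_cyt": m.c_cyt,
                "topk_mean": topk, "background": b,
                "n_nuclei": len(nuc_ids), "length_um": length_um,
                "clamped": m.clamped,
            })
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config_hash(config)
    return df


def detect_events(movie: Movie, maps: LabelMaps, measurements: pd.DataFrame,
                  config: RunConfig,
                  focus_channel: str | None = None) -> pd.DataFrame:
    """Per-cell anaphase (nucleus count 1->2), and with a focus channel,
    SPB separation and Plo1 onset."""
    e = config.events
    cell_ids = sorted(measurements.cell_id.unique())
    anaphase, spb_sep, plo1 = [], [], []
    for cid in cell_ids:
        g = measurements[measurements.cell_id == cid].sort_values("t_min")
        t = g.t_min.to_numpy()
        anaphase.append(ev.detect_anaphase(t, g.n_nuclei.to_numpy(),
                                           persist=e.anaphase_persist_frames))
        if focus_channel is None:
            spb_sep.append(None)
            plo1.append(None)
            continue
        frames = g.frame.to_numpy()
        full_mask = maps.cell_labels[frames] == cid
        union = full_mask.any(axis=0)
        if not union.any():
            spb_sep.append(None)
            plo1.append(None)
            continue
        sl = _cell_bbox(union)
        crop_masks = full_mask[:, sl[0], sl[1]]
        crop_imgs = movie.channels[focus_channel][frames][:, sl[0], sl[1]]
        spb_sep.append(ev.detect_spb_separation(
            crop_imgs, crop_masks, t, mad_factor=e.spb_mad_factor,
            min_distance_px=e.spb_min_distance_px,
            persist=e.spb_persist_frames))
        topk = g.topk_mean.to_numpy()
        ok = np.isfinite(topk)
        if ok.sum() >= 8:
            plo1.append(ev.detect_plo1_onset(
                t[ok], topk[ok], sd_factor=e.plo1_sd_factor,
                persist=e.plo1_persist_frames,
                smooth_points=e.plo1_smooth_points))
        else:
            plo1.append(None)
    return ev.build_event_table(cell_ids, anaphase, spb_sep, plo1)


def export_window_table(measurements: pd.DataFrame, event_table: pd.DataFrame,
                        config: RunConfig,
                        value_col: str = "c_nuc") -> pd.DataFrame:
    """Two-breakpoint export-window fit per cell, plus the 10-90% width of
    the onset transition measured on the raw trace."""
    cp = config.changepoint
    rows = []
    anchors = event_table.set_index("cell_id").anaphase_time
    for cid, g in measurements.groupby("cell_id"):
        anchor = anchors.get(cid, np.nan)
        if not np.isfinite(anchor):
            log.info("cell %s: no anaphase detected, skipped", cid)
            continue
        g = g.sort_values("t_min")
        t = g.t_min.to_numpy()
        y = g[value_col].to_numpy()
        try:
            w = estimate_export_window(
                t, y, anaphase_time=float(anchor),
                window_min=cp.fit_window_min, smooth=cp.smooth,
                span=cp.loess_span, cell_id=int(cid),
                min_segment_points=cp.min_segment_points)
        except ValueError as exc:
            log.warning("cell %s: export fit failed (%s)", cid, exc)
            continue
        width = None
        if not w.flagged:
            onset_t = anchor - w.onset_before_anaphase_min
            sel = np.isfinite(y)
            try:
                width = transition_width(t[sel], y[sel], float(onset_t))
            except ValueError:
                width = None
        rows.append({
            "cell_id": cid,
            "anaphase_time": float(anchor),
            "onset_before_anaphase_min": w.onset_before_anaphase_min,
            "stop_before_anaphase_min": w.stop_before_anaphase_min,
            "flagged": w.flagged,
            "onset_width_min": width,
            "rss": None if w.fit is None else w.fit.rss,
        })
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config_hash(config)
    return df


def analyze_movie(movie: Movie, config: RunConfig,
                  focus_channel: str | None = None,
                  outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Full analysis of a rendered or loaded movie.

    Returns tables: measurements, events, export_windows, ensemble (nuclear
    concentration aligned to anaphase). Tables carry the config hash and
    are optionally written as CSV.
    """
    maps = segment_movie(movie, config)
    measurements = measure_movie(movie, maps, config)
    event_table = detect_events(movie, maps, measurements, config,
                                focus_channel=focus_channel)
    windows = export_window_table(measurements, event_table, config)

    traces, anchors, ids = [], [], []
    anchor_map = event_table.set_index("cell_id").anaphase_time
    for cid, g in measurements.groupby("cell_id"):
        a = anchor_map.get(cid, np.nan)
        if not np.isfinite(a):
            continue
        g = g.sort_values("t_min")
        traces.append((g.t_min.to_numpy(), g.c_nuc.to_numpy()))
        anchors.append(float(a))
        ids.append(int(cid))
    ensemble = (ev.align_and_pool(traces, anchors, ids).to_frame()
                if traces else pd.DataFrame())

    warn_rows = []
    for k, dropped in enumerate(maps.dropped_nuclei):
        warn_rows += [{"frame": k, "kind": "dropped_nucleus", "id": d}
                      for d in dropped]
    for k, excluded in enumerate(maps.excluded_border):
        warn_rows += [{"frame": k, "kind": "border_cell_excluded", "id": e}
                      for e in excluded]
    if len(windows):
        warn_rows += [{"frame": -1, "kind": "flagged_cell", "id": int(c)}
                      for c in windows[windows.flagged].cell_id]
    warnings = pd.DataFrame(warn_rows, columns=["frame", "kind", "id"])

    out = {"measurements": measurements, "events": event_table,
           "export_windows": windows, "ensemble": ensemble,
           "warnings": warnings}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = config_hash(config)
        for name, df in out.items():
            df = df.copy()
            if not df.empty:
                df["config_hash"] = h
            df.to_csv(outdir / f"{name}.csv", index=False)
        _write_exemplar_kymograph(movie, maps, measurements, outdir)
    return out


def _write_exemplar_kymograph(movie: Movie, maps: LabelMaps,
                              measurements: pd.DataFrame,
                              outdir: Path) -> None:
    """Profile matrix of one tracked cell, for the report."""
    from .kymograph import build_kymograph

    if measurements.empty:
        return
    cid = int(measurements.cell_id.iloc[0])
    try:
        kymo = build_kymograph(movie, maps.cell_labels, cid,
                               channel="reporter", mode="max")
    except (ValueError, KeyError) as exc:
        log.info("no exemplar kymograph written (%s)", exc)
        return
    kymo.to_frame().to_csv(outdir / "kymograph_exemplar.csv")


def analyze_traces(trace_df: pd.DataFrame, config: RunConfig,
                   outdir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Trace-only analysis of a ground-truth (or pre-measured) trace table.

    Expects tidy columns ``cell_id``, ``t_min``, nuclear amount/area (or a
    ready ``c_nuc``) and an ``event_anaphase`` column. The anaphase anchor
    is snapped up to the first frame at or after the true event, matching
    the frame-quantized detector on movies.
    """
    df = trace_df.copy()
    if "c_nuc" not in df:
        df["c_nuc"] = df.nuclear_amount / df.nuclear_area_um2
    rows = []
    for cid, g in df.groupby("cell_id"):
        g = g.sort_values("t_min")
        t = g.t_min.to_numpy()
        ana_true = float(g.event_anaphase.iloc[0])
        on_grid = t[t >= ana_true - 1e-9]
        if on_grid.size == 0:
            log.info("cell %s: anaphase outside trace window, skipped", cid)
            continue
        anchor = float(on_grid[0])
        cp = config.changepoint
        try:
            w = estimate_export_window(
                t, g.c_nuc.to_numpy(), anaphase_time=anchor,
                window_min=cp.fit_window_min, smooth=cp.smooth,
                span=cp.loess_span, cell_id=int(cid),
                min_segment_points=cp.min_segment_points)
        except ValueError as exc:
            log.warning("cell %s: export fit failed (%s)", cid, exc)
            continue
        rows.append({
            "cell_id": cid, "anaphase_time": anchor,
            "onset_before_anaphase_min": w.onset_before_anaphase_min,
            "stop_before_anaphase_min": w.stop_before_anaphase_min,
            "flagged": w.flagged,
        })
    windows = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        windows.to_csv(outdir / "export_windows.csv", index=False)
    return {"export_windows": windows}
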