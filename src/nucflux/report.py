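"""Plots and a markdown summary for a completed analyze run.

Every number printed in the report comes from a CSV row written by the
analysis stage; nothing is computed only inside plotting code.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["generate_report"]


def _ensemble_plot(ensemble: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    t = ensemble.t_rel_min
    ok = ensemble.n >= 2
    ax.fill_between(t[ok], (ensemble["mean"] - ensemble.sd)[ok],
                    (ensemble["mean"] + ensemble.sd)[ok],
                    alpha=0.3, lw=0, label="mean ± SD")
    ax.plot(t[ok], ensemble["mean"][ok], lw=1.5)
    ax.axvline(0, color="k", ls=":", lw=0.8)
    ax.set_xlabel("time relative to anaphase (min)")
    ax.set_ylabel("nuclear concentration (a.u./px²)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _windows_plot(windows: pd.DataFrame, path: Path) -> None:
    ok = windows[~windows.flagged.astype(bool)]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    data = [ok.onset_before_anaphase_min.dropna(),
            ok.stop_before_anaphase_min.dropna()]
    ax.boxplot(data, tick_labels=["onset", "stop"], whis=1.5)
    for i, vals in enumerate(data, start=1):
        x = np.random.default_rng(0).normal(i, 0.04, size=len(vals))
        ax.plot(x, vals, "o", ms=3, alpha=0.5)
    ax.set_ylabel("minutes before anaphase")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def generate_report(run_dir: str | Path, outdir: str | Path | None = None) -> Path:
    """Assemble plots + markdown from analyze CSVs in ``run_dir``.

    Missing tables are listed and a partial report produced. Returns the
    path of the markdown file.
    """
    run_dir = Path(run_dir)
    outdir = Path(outdir) if outdir else run_dir / "report"
    outdir.mkdir(parents=True, exist_ok=True)
    missing = []
    lines = ["# Run report", ""]

    wpath = run_dir / "export_windows.csv"
    if wpath.exists():
        windows = pd.read_csv(wpath)
        ok = windows[~windows.flagged.astype(bool)] if len(windows) else windows
        if len(ok):
            on = ok.onset_before_anaphase_min.dropna()
            st = ok.stop_before_anaphase_min.dropna()
            lines += [
                "## Export window",
                f"- cells fitted: {len(windows)} ({int(windows.flagged.sum())} flagged)",
                f"- ensemble median onset: {on.median():.2f} min before anaphase",
                f"- ensemble median stop: {st.median():.2f} min before anaphase",
            ]
            if "onset_width_min" in ok and ok.onset_width_min.notna().any():
                lines.append(f"- median onset 10-90% width: "
                             f"{ok.onset_width_min.median():.2f} min")
            _windows_plot(windows, outdir / "export_windows.png")
            lines += ["", "![export windows](export_windows.png)", ""]
    else:
        missing.append("export_windows.csv")

    epath = run_dir / "ensemble.csv"
    if epath.exists():
        ensemble = pd.read_csv(epath)
        if len(ensemble):
            _ensemble_plot(ensemble, outdir / "ensemble.png")
            lines += ["## Aligned ensemble",
                      "![ensemble](ensemble.png)", ""]
    else:
        missing.append("ensemble.csv")

    evpath = run_dir / "events.csv"
    if evpath.exists():
        events = pd.read_csv(evpath)
        n_spb = int(events.spb_separation_time.notna().sum())
        n_plo1 = int(events.plo1_onset_time.notna().sum())
        lines += ["## Events",
                  f"- anaphase detected: {int(events.anaphase_time.notna().sum())}"
                  f" / {len(events)} cells"]
        if n_spb or n_plo1:
            both = events.dropna(subset=["spb_separation_time",
                                         "plo1_onset_time"])
            lines.append(f"- SPB separation detected: {n_spb}; Plo1 onset: {n_plo1}")
            if len(both):
                interval = (both.spb_separation_time - both.plo1_onset_time)
                lines.append(f"- median Plo1 onset -> SPB separation: "
                             f"{interval.median():.2f} min")
        else:
            lines.append("- focus channel absent: Plo1/SPB sections not available")
        lines.append("")
    else:
        missing.append("events.csv")

    kpath = run_dir / "kymograph_exemplar.csv"
    if kpath.exists():
        kymo = pd.read_csv(kpath, index_col=0)
        fig, ax = plt.subplots(figsize=(5, 2.5))
        ax.imshow(kymo.to_numpy(), aspect="auto", cmap="magma",
                  interpolation="nearest")
        ax.set_xlabel("frame")
        ax.set_ylabel("axial position (px)")
        fig.tight_layout()
        fig.savefig(outdir / "kymograph.png", dpi=150)
        plt.close(fig)
        lines += ["## Exemplar kymograph", "![kymograph](kymograph.png)", ""]

    if missing:
        lines += ["## Missing tables", *(f"- {m}" for m in missing), ""]
    md = outdir / "report.md"
    md.write_text("\n".join(lines))
    return md
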