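# nucflux

Quantification of the transient, pre-mitotic nuclear export of cyclin B
(Cdc13) in fission yeast from single-cell fluorescence time-lapse movies —
compartment segmentation, concentration/amount decomposition,
event-aligned ensemble analysis, change-point timing of export onset and
stop, and the accompanying population statistics — together with a
synthetic-movie generator that emulates the imaging so every stage is
testable without any raw-data download.

**Who it is for.** Cell-cycle and quantitative-imaging groups measuring
nucleocytoplasmic partitioning of a reporter over the cell cycle: the
package turns multi-channel movies (or pre-measured trace tables) into
per-cell compartment concentrations, mitotic event times, and estimates of
when switch-like transport transitions begin and end.

## The quantities and the model

For each cell and frame, with background *b* subtracted per pixel,

    I_cyt = I_cell − I_nuc        A_cyt = A_cell − A_nuc
    c_x   = I_x / A_x             (x ∈ {cell, nuc, cyt})
    N/C   = c_nuc / c_cyt

— integrated signal per projected area, cytoplasm by subtraction. Traces
are aligned to nuclear separation at anaphase (t = 0) and the timing of
nuclear export is estimated per cell by a continuous piecewise-linear
(change-point) fit on the pre-anaphase window,

    y(t) = β₀ + β₁ t + γ₁ (t − τ₁)₊ + γ₂ (t − τ₂)₊ + ε,

with breakpoints (τ₁, τ₂) found by exhaustive search on the frame grid;
τ₁ is the export onset and τ₂ the export stop, reported as minutes before
anaphase. Transition sharpness is the 10–90% width of a logistic
slope-blend fitted locally at a breakpoint. In fission yeast this export
phase begins ~15 min before anaphase (concomitant with Plo1 enrichment at
the spindle pole body, ~8 min before SPB separation) and stops at SPB
separation, ~7 min before anaphase; the synthetic generator's defaults
encode exactly this phase structure. See `docs/methods.md` for the full
model, parameter table and numerical choices.

## Worked example

Simulate a small population at 15 s frame intervals, run the full pipeline
and summarize the recovered export window:

```python
from nucflux import OpticsConfig, RunConfig
from nucflux.pipeline import analyze_movie, simulate_run

config = RunConfig(seed=1, n_cells=8, species="cdc13",
                   optics=OpticsConfig(frame_interval_s=15.0,
                                       field_shape_px=(256, 512)))
movie = simulate_run(config)
tables = analyze_movie(movie, config)
windows = tables["export_windows"]
ok = windows[~windows.flagged]
print(f"cells fitted: {len(windows)} (flagged: {int(windows.flagged.sum())})")
print(f"median export onset: {ok.onset_before_anaphase_min.median():.2f} min before anaphase")
print(f"median export stop:  {ok.stop_before_anaphase_min.median():.2f} min before anaphase")
print(f"median onset 10-90% width: {ok.onset_width_min.median():.2f} min")
```

prints

```
cells fitted: 8 (flagged: 0)
median export onset: 15.00 min before anaphase
median export stop:  7.38 min before anaphase
median onset 10-90% width: 0.10 min
```

The generator placed the true onset 15 min and the true stop 7 min before
anaphase with a 0.5 min switch width; the pipeline — rendering with
photon noise, re-segmenting every frame, re-measuring concentrations, and
re-detecting anaphase from the nuclear-marker split — recovers the onset
on the frame grid, the stop to within half a minute, and a sub-minute
transition width, which is the end-to-end consistency the package is
built to demonstrate.

The same stages are available from the shell:

```bash
nucflux simulate --config run.yaml --out run/
nucflux analyze run/ --config run.yaml --out run/tables/ [--from-traces] [--focus-channel reporter]
nucflux report run/tables/
```

`analyze --from-traces` accepts a tidy per-cell trace CSV and skips the
imaging stages; `report` renders ensemble mean±SD bands, export-window box
plots and a markdown summary from the analysis CSVs.

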