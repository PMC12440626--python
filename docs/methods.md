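# Methods

`nucflux` quantifies a transient, pre-mitotic phase of cyclin B (Cdc13)
nuclear export in fission yeast from single-cell fluorescence time-lapse
movies, and ships a synthetic-movie generator that emulates the imaging so
the whole pipeline can be validated end to end by parameter recovery. This
note records the model, its assumptions, the tunable parameters, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## The kinetic model behind the generator

Each cell carries reporter amounts (arbitrary units) in three compartments
— nucleus N, cytoplasm C, and a spindle-pole-body (SPB) focus S — with
total T = N + C + S by construction, so compartment conservation is exact
at every time point. The dynamics are piecewise with smooth switches:
every transition is gated by a logistic whose 10–90% rise time is the
`transition_width_min` parameter (default 0.5 min, matching the reported
"switch-like", roughly-a-minute transitions).

Phases for the cyclin reporter (`cdc13`), on the cell's own clock:

1. **Interphase** — synthesis at `synthesis_rate` (1 a.u./min), a fraction
   `nuclear_synthesis_fraction` (0.35) routed to the nucleus. With a
   projected nuclear area fraction of 0.13 this yields an interphase
   nuclear/cytoplasmic concentration ratio of ≈ 3.6.
2. **Export window** `[anaphase − 15 min, anaphase − 7 min]` — a
   constant-rate flux moves `export_fraction` (0.3) of the nuclear amount
   present at onset into the cytoplasm. A zero-order flux is used
   deliberately: the observed single-cell traces are approximately linear
   between abrupt slope changes, and a first-order flux would make the
   middle segment exponential. During this window the cytoplasmic amount
   rises faster than the total while the nuclear amount falls and the
   whole-cell concentration stays nearly constant.
3. **Degradation** — from `degradation_onset_offset_min` (0, i.e. at
   anaphase) synthesis stops and all compartments decay exponentially with
   `degradation_halflife_min` (3 min).

Plo1 enrichment at the SPB and export onset are modelled as the same
instant (they are reported as concomitant); the parameterization
`plo1_onset_offset_min` (8 min before SPB separation) must therefore be
consistent with `export_onset_offset_min` (15) and
`spb_separation_offset_min` (7), and the config validator enforces
15 = 7 + 8.

Species variants: `cdc2` exports with the cyclin and keeps leaving the
nucleus after degradation onset but is itself stable; `cut2` (securin)
holds a flat N/C ratio until SPB separation, is then imported
(first-order, 0.08 /min) and degraded from anaphase; `mad3` is a stable
nuclear-enriched control with no export phase; `plo1` is spatially uniform
with an SPB focus accumulating at `spb_accumulation_rate` (0.5 a.u./min)
from Plo1 onset; `cdc13_NLS_KK` has a reduced nuclear synthesis fraction
(0.18 → N/C ≈ 1.5) with an intact export window; `cdc13_1_177_OE` is an
exporting fragment at 20× synthesis.

The generator implements a *net* flux from nucleus to cytoplasm; reduced
import and genuine export are observationally equivalent here and are not
distinguished.

**Geometry and growth.** Cells are rods (capsules) of fixed width 3.5 µm
growing linearly from birth length to `division_length_um` (14.5 µm) until
growth arrest at SPB separation; daughters are half the division length.
Cycle length is an affine map of birth length
(220 min − 10 min/µm × birth), giving built-in size homeostasis (negative
slope). The nucleus is a disc with 13% of the projected cell area. At
anaphase the nucleus splits abruptly into two resolvably separated discs:
the experimental anchor is the first frame at which two nuclei are
distinguishable, so the truth event is placed at that same instant rather
than at the start of a slow separation that would bake a detection lag
into the truth.

**Per-cell variability.** Event offsets, synthesis rate, export fraction,
cycle length and birth length receive independent Gaussian jitter with
configurable CVs (defaults 5–10%); per-cell substreams are derived from the
master seed by counter (`SeedSequence([seed, i])`), so populations are
reproducible and order-independent.

**Integration.** The three-compartment ODE is integrated with RK4 at a
0.05 min internal step and sampled onto the output grid; the flux function
is exposed (`kinetic_fluxes`) and a test reproduces every trace within 1%
by independent forward-Euler integration at a 100× finer step.

## Rendering

Frames are already-projected 2-D images. Compartment amounts are spread
uniformly over the compartment's pixels (so the noise-free integrated
signal equals the amount exactly), SPB foci are bilinearly splatted
points, and each channel is Gaussian-blurred (PSF σ = 1.3 px) before

    expected counts = background + photon_scale × blurred amount map,

with Poisson shot noise and Gaussian read noise. Channels: `outline` (a
uniform cell-body proxy standing in for brightfield-based cell
segmentation), `nls` (nuclear marker, splitting at anaphase), `reporter`
(the species' fluorophore including foci). Defaults — 0.11 µm pixels,
512×512 field (768×512 for 30-cell runs), background 10 counts, read noise
2, photon scale 2500 — are plausible for a 60×/1.42 system with an sCMOS
camera but are declared choices, not literature values. Pixel-centre
coordinates, row-major, origin top-left, shared by images and masks.

## Measurement conventions

Nuclei: Gaussian blur (σ 1.5 px) then global Otsu on a 256-bin histogram
of the min–max-scaled image (ties broken toward the lower threshold), hole
filling, minimum-area filter. Cells: same operators on the outline proxy;
a truth-passthrough mode bypasses segmentation so downstream stages can be
tested in isolation. Nuclei are assigned to the cell containing their
centroid (both post-anaphase nuclei are retained and summed until
division); border-touching cells are excluded; tracking links cells across
frames by maximal pixel overlap, with division handled as one parent
ending and two children starting.

Concentrations are background-subtracted integrated signal per area, with
the cytoplasm obtained by subtraction: I_cyt = I_cell − I_nuc and
A_cyt = A_cell − A_nuc, so the decomposition identities hold exactly.
Background is the mean over off-cell patches, estimated per frame to track
illumination drift. Autofluorescence is not corrected (matching the
measurement convention this pipeline reproduces), so both compartment
concentrations are slightly overestimated on real data; the generator can
emulate this with a cellular background term. The top-k brightest-pixel
estimator (k = 40) proxies nuclear or SPB-focus concentration where no
nuclear marker exists; the two-ROI estimator averages two discs flanking
the nucleus along the long axis. Trace smoothing is degree-2 loess with
tricube weights and span 0.3.

## Event detection and alignment

* **Anaphase** — first frame at which a cell's nucleus count goes 1 → 2
  and stays ≥ 2 for 2 frames. Nuclear separation and sister-chromatid
  separation are treated as the same anchor.
* **SPB separation** — per frame, up to two foci (local maxima above
  median + 6·MAD of in-cell pixels); separation is the first frame with
  two foci > 3 px apart persisting 2 frames.
* **Plo1 onset** — first sustained (3-frame) excursion of the
  loess-smoothed top-40 trace above its early-quartile baseline mean +
  4 SD. The detector smooths over a short 5-point window rather than the
  span-0.3 trace smoother: a wide symmetric smoother bleeds a sharp onset
  backwards by half its support and would bias the detected time early by
  minutes.

Aligned ensembles shift each cell's timestamps so the anchor is 0 and pool
on the shared acquisition grid without interpolation (event times are
frame-quantized; pools must share one frame interval). Mean and sample SD
are reported where ≥ 2 cells contribute; a single trace is its own
ensemble with SD 0.

## Change-point estimation

The timing claims are formalized as a continuous piecewise-linear model
fitted by exhaustive search: for every admissible pair of breakpoints on
the frame grid an OLS fit of the hinge basis {1, t, (t−τ₁)₊, (t−τ₂)₊} is
computed and the global RSS minimizer returned, ties broken toward earlier
breakpoints (for ≤ 60-frame traces a test verifies equality with full
enumeration). The export window is the 2-breakpoint fit over
[anaphase − 25 min, anaphase] — the degradation phase is excluded by
fitting only up to anaphase — on the loess-smoothed trace by default (raw
optional, and recorded); fits whose middle segment is not the steepest
decline are flagged and excluded from ensemble summaries.

Transition sharpness is measured on the raw trace within ±3 min of a
breakpoint by fitting a corner whose slope switches between the two
segment slopes as a logistic of time (equivalently, a softplus-smoothed
corner). The reported width is the 10–90% range of that slope-mixing
weight (2 ln 9 · τ): this matches the generator's width definition, which
gates fluxes (slopes), not levels. Blending the segment *lines* instead
inflates the width roughly threefold even on noise-free traces, because
the line-blend weight is not the slope-mixing weight. The optimizer is
multi-started over initial widths (0.1–4 min); smoothing is not applied
here because span-0.3 loess has multi-minute support and would dominate a
sub-minute width.

## Population statistics

Cycle length is the time between consecutive division events of a tracked
lineage; birth and pre-division lengths are read from the first and last
frames of a cycle. Group comparisons use the two-sided Wilcoxon rank-sum
test with continuity correction (normal approximation, midranks,
tie-corrected variance — the behaviour of R's `wilcox.test`); an exact
permutation version (n ≤ 10 per group) serves as the test-suite oracle.
Size homeostasis is OLS of cycle length on birth length with the Pearson
R. Quantiles use the linear-interpolation (type-7) convention; box
whiskers sit on the most extreme observations within 1.5 IQR of the
quartiles. N/C ratios are normalized to the mean ratio of the wild-type
reference population within an experiment.

## Problem sizes and validation scope

The standard validation run is 30 cells imaged at 15 s intervals over a
40 min window (161 frames, 768×512 px) — a size chosen to give stable
ensemble medians while a full simulate-and-analyze cycle stays in the
low minutes on a single core. On these movies the pipeline recovers the
configured timings: median export onset ≈ 15 min and stop ≈ 7 min before
anaphase, median Plo1-onset→SPB-separation interval ≈ 7–8 min, and median
onset transition width well under 1 min for a generated width of 0.5 min
(the Plo1 onset detector carries an intrinsic ~2–3 frame threshold-crossing
lag for a ramp signal, which shortens the measured interval slightly).

What passing these checks shows: the measurement conventions, event
detectors and change-point estimator are mutually consistent and recover
known truth through the full imaging chain at realistic noise. What it
does not show: robustness to the things the simulator does not emulate —
segmentation against real brightfield images (the proxy channel is
high-contrast by construction), mask errors from crowded or overlapping
cells, focus drift, photobleaching, autofluorescence gradients, nucleolar
exclusion of the reporter, or 3-D effects beyond the projected-areal
approximation. Real-data use should treat segmentation quality as the
first thing to audit.

## Known limitations

* The piecewise-linear estimator assumes exactly two slope changes in the
  fit window; cells with extra structure are only caught by the
  middle-segment-shape flag.
* Exhaustive breakpoint search is O(n²) least squares per cell; traces
  much longer than a few hundred frames would need a smarter search.
* The 3-breakpoint option exists but is unused by the default analysis.
* Event times are frame-quantized by design; sub-frame timing would
  require interpolation the detectors deliberately avoid.
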