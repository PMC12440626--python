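"""Run configuration: kinetic timeline, optics, and analysis parameter blocks.

All timeline parameters are in minutes and micrometres. The timeline
defaults encode the reported phase structure of mitotic entry in fission
yeast: nuclear export of cyclin B starts ~15 min before anaphase
(concomitant with Plo1 enrichment at the spindle pole body, ~8 min before
SPB separation) and stops at SPB separation, ~7 min before anaphase;
cyclin degradation starts at anaphase. Each switch is a smooth logistic
blend with a 10-90% width of ~0.5 min ("switch-like" transitions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """A parameter set violates a required ordering or range."""


@dataclass
class TimelineParams:
    """Ground-truth cell-cycle and kinetic parameters for one population.

    Event offsets are positive minutes *before* the reference event named
    in the field. Per-cell variability is controlled by coefficient-of-
    variation (CV) fields; a CV of 0 removes the corresponding jitter.
    """

    # -- event timing (minutes) ------------------------------------------
    export_onset_offset_min: float = 15.0   # before anaphase
    spb_separation_offset_min: float = 7.0  # before anaphase
    plo1_onset_offset_min: float = 8.0      # before SPB separation
    degradation_onset_offset_min: float = 0.0  # after anaphase (signed)
    transition_width_min: float = 0.5       # 10-90% width of each switch
    post_anaphase_min: float = 20.0         # anaphase -> division (septation)

    # -- cycle length vs birth length (size homeostasis) -----------------
    cycle_length_intercept_min: float = 220.0
    cycle_length_slope_min_per_um: float = -10.0

    # -- geometry (micrometres) ------------------------------------------
    birth_length_mean_um: float = 8.0
    division_length_um: float = 14.5
    cell_width_um: float = 3.5
    nuclear_area_fraction: float = 0.13

    # -- amounts / rates --------------------------------------------------
    synthesis_rate: float = 1.0             # a.u./min whole-cell synthesis
    export_fraction: float = 0.3            # fraction of nuclear amount moved
    degradation_halflife_min: float = 3.0
    nuclear_synthesis_fraction: float = 0.35  # fraction of synthesis to nucleus
    spb_accumulation_rate: float = 0.5      # a.u./min at focus (plo1 species)

    # -- per-cell variability (CVs unless stated) -------------------------
    cv_birth_length: float = 0.07
    cv_export_onset: float = 0.05
    cv_spb_separation: float = 0.05
    cv_plo1_offset: float = 0.05
    cv_synthesis_rate: float = 0.1
    cv_export_fraction: float = 0.1
    cv_cycle_length: float = 0.05
    anaphase_jitter_sd_min: float = 1.0     # spread of anaphase times in a movie

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.export_onset_offset_min > self.spb_separation_offset_min > 0:
            raise ConfigurationError(
                "require export_onset_offset_min > spb_separation_offset_min > 0 "
                f"(got {self.export_onset_offset_min} and "
                f"{self.spb_separation_offset_min})"
            )
        if self.transition_width_min <= 0:
            raise ConfigurationError("transition_width_min must be > 0")
        if not 0 <= self.export_fraction < 1:
            # 0 is the degenerate no-export limit, kept valid for controls
            raise ConfigurationError("export_fraction must lie in [0, 1)")
        for name in ("synthesis_rate", "degradation_halflife_min",
                     "spb_accumulation_rate", "post_anaphase_min"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        # Plo1 onset and export onset are concomitant; the two routes of
        # specifying the same instant must agree.
        implied = self.spb_separation_offset_min + self.plo1_onset_offset_min
        if abs(implied - self.export_onset_offset_min) > 1e-6:
            raise ConfigurationError(
                "plo1_onset_offset_min + spb_separation_offset_min must equal "
                f"export_onset_offset_min ({implied} != "
                f"{self.export_onset_offset_min}): Plo1 enrichment and export "
                "onset are the same instant"
            )

    def cycle_length(self, birth_length_um: float) -> float:
        return (self.cycle_length_intercept_min
                + self.cycle_length_slope_min_per_um * birth_length_um)


#: frame intervals used by the three imaging regimes, seconds
STANDARD_FRAME_INTERVALS_S = (300.0, 180.0, 15.0)


@dataclass
class OpticsConfig:
    """Synthetic microscope parameters.

    ``photon_scale`` converts per-pixel reporter amount (a.u.) into expected
    photon counts; expected pixel value = ``background_level`` +
    ``photon_scale`` x (amount map convolved with a Gaussian PSF). Noise is
    Poisson on the expected counts plus Gaussian read noise.
    """

    pixel_size_um: float = 0.11
    frame_interval_s: float = 300.0
    psf_sigma_px: float = 1.3
    background_level: float = 10.0
    read_noise_sd: float = 2.0
    photon_scale: float = 2500.0
    field_shape_px: tuple[int, int] = (512, 512)
    shot_noise: bool = True
    allowed_intervals_s: tuple[float, ...] = STANDARD_FRAME_INTERVALS_S

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.allowed_intervals_s and self.frame_interval_s not in self.allowed_intervals_s:
            raise ConfigurationError(
                f"frame_interval_s {self.frame_interval_s} not in configured "
                f"set {self.allowed_intervals_s}"
            )
        self.field_shape_px = tuple(int(v) for v in self.field_shape_px)

    @property
    def frame_interval_min(self) -> float:
        return self.frame_interval_s / 60.0

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass
class SegmentationConfig:
    blur_sigma_px: float = 1.5
    min_cell_area_px: int = 100
    min_nucleus_area_px: int = 30
    passthrough: bool = False          # use truth masks, bypass segmentation
    min_overlap_fraction: float = 0.5  # nucleus-in-cell containment check


@dataclass
class QuantConfig:
    topk: int = 40                     # brightest-pixel estimator size
    background_rois: int = 8
    background_roi_px: int = 15
    loess_span: float = 0.3


@dataclass
class EventConfig:
    anaphase_persist_frames: int = 2
    spb_persist_frames: int = 2
    spb_mad_factor: float = 6.0        # m: foci threshold median + m*MAD
    spb_min_distance_px: float = 3.0   # d_min
    plo1_sd_factor: float = 4.0        # q: onset threshold mean + q*SD
    plo1_persist_frames: int = 3
    plo1_smooth_points: int = 5        # local loess window for the detector


@dataclass
class ChangePointConfig:
    n_breakpoints: int = 2
    fit_window_min: float = 25.0       # pre-anaphase window used for fitting
    smooth: bool = True                # loess-smooth traces before fitting
    loess_span: float = 0.3
    min_segment_points: int = 2


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate/analyze run."""

    seed: int = 1
    n_cells: int = 30
    species: str = "cdc13"
    movie_start_min: float = 0.0
    movie_end_min: float = 40.0
    anaphase_time_min: float = 30.0
    timeline: TimelineParams = field(default_factory=TimelineParams)
    # default field enlarged to hold a 30-cell population without overlap
    optics: OpticsConfig = field(
        default_factory=lambda: OpticsConfig(field_shape_px=(768, 512)))
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    events: EventConfig = field(default_factory=EventConfig)
    changepoint: ChangePointConfig = field(default_factory=ChangePointConfig)


# ---------------------------------------------------------------------------
# serialization


def _to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def conv(v):
        if isinstance(v, tuple):
            return list(v)
        if isinstance(v, dict):
            return {k: conv(x) for k, x in v.items()}
        return v

    return {k: conv(v) for k, v in d.items()}


_NESTED = {
    "timeline": TimelineParams,
    "optics": OpticsConfig,
    "segmentation": SegmentationConfig,
    "quant": QuantConfig,
    "events": EventConfig,
    "changepoint": ChangePointConfig,
}

_TUPLE_FIELDS = {"field_shape_px", "allowed_intervals_s"}


def _from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _from_dict(_NESTED[f.name], v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config, path: str | Path) -> None:
    """Write a config dataclass to YAML or JSON (by file extension)."""
    path = Path(path)
    data = _to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path, cls=RunConfig):
    """Load a config dataclass previously written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_dict(cls, data)
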