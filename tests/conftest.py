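import numpy as np
import pytest

from nucflux import OpticsConfig, RunConfig, TimelineParams
from nucflux.pipeline import simulate_run


def no_jitter_params(**overrides) -> TimelineParams:
    """Timeline with all per-cell variability switched off."""
    kwargs = dict(cv_birth_length=0.0, cv_export_onset=0.0,
                  cv_spb_separation=0.0, cv_plo1_offset=0.0,
                  cv_synthesis_rate=0.0, cv_export_fraction=0.0,
                  cv_cycle_length=0.0, anaphase_jitter_sd_min=0.0)
    kwargs.update(overrides)
    return TimelineParams(**kwargs)


@pytest.fixture(scope="session")
def default_params() -> TimelineParams:
    return TimelineParams()


def tiny_run_config(n_cells=2, frame_interval_s=15.0, noise=True,
                    species="cdc13", seed=1, jitter=True,
                    field=(128, 168)) -> RunConfig:
    """Small, fast movie configuration for unit tests."""
    timeline = TimelineParams() if jitter else no_jitter_params()
    return RunConfig(
        seed=seed, n_cells=n_cells, species=species,
        movie_end_min=40.0, anaphase_time_min=30.0,
        timeline=timeline,
        optics=OpticsConfig(frame_interval_s=frame_interval_s,
                            field_shape_px=field, shot_noise=noise))


@pytest.fixture(scope="session")
def tiny_movie():
    """Two cdc13 cells, 15 s frames, default noise, small field."""
    cfg = tiny_run_config(n_cells=2)
    return cfg, simulate_run(cfg)


@pytest.fixture(scope="session")
def tiny_movie_noisefree():
    cfg = tiny_run_config(n_cells=2, noise=False)
    return cfg, simulate_run(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
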