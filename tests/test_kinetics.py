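"""Ground-truth kinetics generator: conservation, switch structure,
species variants, population sampling and config round-trips."""

import numpy as np
import pytest

from nucflux import (ConfigurationError, RunConfig, TimelineParams,
                     load_config, sample_population, save_config,
                     simulate_cell, simulate_lineage)
from nucflux.kinetics import (draw_cell_params, integrate_trace,
                              kinetic_fluxes)

from conftest import no_jitter_params


def test_compartment_conservation():
    """Total amount equals the sum of the three compartments everywhere."""
    for tr in sample_population(TimelineParams(), 5, seed=3):
        total = tr.nuclear_amount + tr.cytoplasmic_amount + tr.spb_amount
        np.testing.assert_allclose(tr.total_amount, total, rtol=1e-9)
        assert (tr.nuclear_amount >= 0).all()
        assert (tr.cytoplasmic_amount >= 0).all()
        assert (tr.spb_amount >= 0).all()


def test_event_ordering_and_concomitance():
    """plo1 onset = export onset < SPB separation < anaphase < division."""
    for tr in sample_population(TimelineParams(), 5, seed=7):
        e = tr.events
        assert e["plo1_onset"] == e["export_onset"]
        assert e["export_onset"] < e["spb_separation"] < e["anaphase"] \
            < e["division"]


def test_sharp_switch_limit():
    """With vanishing transition width the nuclear amount declines exactly
    on the open export interval and not before."""
    p = no_jitter_params(transition_width_min=1e-9)
    tr = simulate_cell(p, 8.0, "cdc13", seed=None, dt_out_min=0.25)
    t = tr.time_min
    n = tr.nuclear_amount
    on, off = tr.events["export_onset"], tr.events["spb_separation"]
    pre = (t > 1.0) & (t < on - 0.3)
    mid = (t > on + 0.3) & (t < off - 0.3)
    assert (np.diff(n[pre]) > 0).all()        # synthesis only
    assert (np.diff(n[mid]) < 0).all()        # export dominates


def test_monotonicity_before_degradation():
    """Total amount is non-decreasing until degradation onset."""
    tr = simulate_cell(TimelineParams(), 8.0, "cdc13", seed=5)
    sel = tr.time_min < tr.events["anaphase"] - 1.0
    assert (np.diff(tr.total_amount[sel]) >= -1e-9).all()


def test_no_export_matches_stable_species():
    """export_fraction = 0 reduces the exporting species to the shape of a
    constant-ratio control before anaphase."""
    p = no_jitter_params(export_fraction=0.0)
    a = simulate_cell(p, 8.0, "cdc13", seed=None)
    b = simulate_cell(p, 8.0, "mad3", seed=None)
    # stop short of anaphase: the exporter's degradation switch has a
    # (tiny) smooth tail that the stable control lacks
    sel = a.time_min < a.events["anaphase"] - 2.0
    np.testing.assert_allclose(a.nuclear_amount[sel], b.nuclear_amount[sel],
                               rtol=1e-6)


def test_fine_step_integration_oracle():
    """Forward-Euler integration of the same flux definitions at a 100x
    finer step reproduces the trace within 1% at all output times."""
    p = TimelineParams()
    tr = simulate_cell(p, 8.0, "cdc13", seed=1, dt_out_min=1.0)
    cell = tr.kinetics
    t_end = tr.time_min[-1] - tr.time_min[0]
    dt = 0.0005
    steps = int(np.ceil(t_end / dt))
    n = cell.nuclear_fraction * cell.initial_total
    c = (1 - cell.nuclear_fraction) * cell.initial_total
    s = 0.0
    out_t = tr.time_min - tr.time_min[0]
    ref = np.empty((out_t.size, 3))
    j = 0
    t = 0.0
    for i in range(steps + 1):
        while j < out_t.size and out_t[j] <= t + dt / 2:
            ref[j] = (n, c, s)
            j += 1
        dn, dc, ds = kinetic_fluxes(t, n, c, s, cell)
        n, c, s = n + dt * dn, c + dt * dc, s + dt * ds
        t += dt
    scale = tr.total_amount.max()
    for k, arr in enumerate([tr.nuclear_amount, tr.cytoplasmic_amount,
                             tr.spb_amount]):
        assert np.abs(arr - ref[:, k]).max() / scale < 0.01


def test_cut2_imports_at_spb_separation():
    """Securin keeps a flat nuclear share until SPB separation and is then
    imported into the nucleus."""
    p = no_jitter_params()
    tr = simulate_cell(p, 8.0, "cut2", seed=None)
    t = tr.time_min
    frac = tr.nuclear_amount / tr.total_amount
    sep, ana = tr.events["spb_separation"], tr.events["anaphase"]
    before = frac[(t > 1) & (t < sep - 0.5)]
    np.testing.assert_allclose(before, before[0], atol=1e-3)
    after = frac[(t > sep + 0.5) & (t < ana)]
    assert (np.diff(after) > 0).all()
    assert after[-1] > before[-1] + 0.05


def test_population_reproducible_and_order_independent():
    p = TimelineParams()
    a = sample_population(p, 4, seed=9)
    b = sample_population(p, 4, seed=9)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x.nuclear_amount, y.nuclear_amount)
    # cell i does not depend on how many cells precede it
    c = sample_population(p, 2, seed=9)
    np.testing.assert_array_equal(a[1].nuclear_amount, c[1].nuclear_amount)


def test_single_cell_population_matches_manual_draw():
    """n=1 equals simulate_cell driven by the same counter substream."""
    p = TimelineParams()
    pop = sample_population(p, 1, seed=11)
    rng = np.random.default_rng(np.random.SeedSequence([11, 0]))
    birth = p.birth_length_mean_um * (1 + p.cv_birth_length
                                      * rng.standard_normal())
    tr = simulate_cell(p, birth, "cdc13", seed=rng)
    np.testing.assert_array_equal(pop[0].nuclear_amount, tr.nuclear_amount)


def test_zero_cv_gives_identical_offsets():
    p = no_jitter_params()
    pop = sample_population(p, 4, seed=2)
    offsets = [t.events["anaphase"] - t.events["export_onset"] for t in pop]
    assert len(set(np.round(offsets, 9))) == 1


def test_sampler_recovers_configured_export_offset():
    """Monte-Carlo mean of (anaphase - export onset) sits within 2 SE of
    the configured 15 min."""
    p = TimelineParams()
    cells = [draw_cell_params(
        p, p.birth_length_mean_um, "cdc13",
        np.random.default_rng(np.random.SeedSequence([21, i])))
        for i in range(200)]
    offs = np.array([c.anaphase_min - c.export_onset_min for c in cells])
    se = offs.std(ddof=1) / np.sqrt(len(offs))
    assert abs(offs.mean() - p.export_onset_offset_min) < 2 * se


def test_size_homeostasis_negative_correlation():
    """Birth length and cycle length correlate negatively for a negative
    cycle-length slope (>= 100 cells)."""
    p = TimelineParams()
    births, cycles = [], []
    for i in range(150):
        rng = np.random.default_rng(np.random.SeedSequence([31, i]))
        b = p.birth_length_mean_um * (1 + p.cv_birth_length
                                      * rng.standard_normal())
        cell = draw_cell_params(p, b, "cdc13", rng)
        births.append(b)
        cycles.append(cell.cycle_length_min)
    assert np.corrcoef(births, cycles)[0, 1] < 0


def test_invalid_offset_ordering_raises():
    with pytest.raises(ConfigurationError, match="export_onset_offset"):
        TimelineParams(export_onset_offset_min=5.0)
    with pytest.raises(ConfigurationError, match="plo1_onset_offset"):
        TimelineParams(plo1_onset_offset_min=3.0)
    with pytest.raises(ValueError):
        sample_population(TimelineParams(), 0, seed=1)
    with pytest.raises(ValueError):
        simulate_cell(TimelineParams(), -1.0, "cdc13")


def test_lineage_cycles_abut():
    traces = simulate_lineage(TimelineParams(), 3, seed=5)
    assert len(traces) == 3
    for prev, nxt in zip(traces, traces[1:]):
        assert nxt.events["birth"] == pytest.approx(prev.events["division"])


def test_config_roundtrip(tmp_path):
    cfg = RunConfig(seed=7, n_cells=3,
                    timeline=TimelineParams(export_fraction=0.4))
    for ext in ("yaml", "json"):
        path = tmp_path / f"cfg.{ext}"
        save_config(cfg, path)
        back = load_config(path)
        assert back == cfg


def test_trace_table_schema():
    tr = simulate_cell(TimelineParams(), 8.0, "cdc13", seed=1, dt_out_min=5.0)
    df = tr.to_frame()
    for col in ("cell_id", "t_min", "nuclear_amount", "cytoplasmic_amount",
                "spb_amount", "total_amount", "cell_length_um",
                "event_anaphase"):
        assert col in df.columns
    assert (df.t_min.diff().dropna() > 0).all()
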