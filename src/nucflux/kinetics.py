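"""Ground-truth single-cell kinetics of a nucleocytoplasmic reporter.

Amounts (a.u.) in three compartments — nucleus N, cytoplasm C, and a
spindle-pole-body (SPB) focus S — follow piecewise dynamics whose switches
are smooth logistic blends. For the cyclin B reporter (``cdc13``):

* interphase: synthesis at rate ``k_s``, a fixed fraction into the nucleus;
* export window ``[export_onset, spb_separation]``: a constant-rate flux
  moves a configured fraction of the onset nuclear amount to the cytoplasm,
  giving the linear nuclear decline bracketed by abrupt slope changes seen
  in the traces — the total stays nearly constant while the cytoplasmic
  amount rises faster than the total and the nuclear amount falls;
* from degradation onset (anaphase by default): synthesis stops and all
  compartments decay exponentially.

Species variants: ``cdc2`` exports with cdc13 and continues to leave the
nucleus after degradation onset (loss of its nuclear binding partner) but is
itself stable; ``cut2`` (securin) keeps a flat nucleocytoplasmic ratio until
SPB separation and is then imported into the nucleus; ``mad3`` stays
nuclear-enriched with no export phase; ``plo1`` is diffuse with an SPB focus
that switches on at Plo1 onset; ``cdc13_NLS_KK`` has a reduced nuclear
fraction but an intact export window; ``cdc13_1_177_OE`` is an overexpressed
exporting fragment.

The total amount is defined as N + C + S, so compartment conservation holds
by construction at every time point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TimelineParams

__all__ = [
    "SPECIES",
    "CellKinetics",
    "GroundTruthTrace",
    "draw_cell_params",
    "kinetic_fluxes",
    "integrate_trace",
    "simulate_cell",
    "sample_population",
    "simulate_lineage",
]

#: internal RK4 step, minutes
_DT_INTERNAL = 0.05

# width w is the 10-90% rise time of the logistic: w = 2*ln(9)*tau
_W_TO_TAU = 1.0 / (2.0 * math.log(9.0))


def smooth_step(t: float, t0: float, width: float) -> float:
    """Logistic switch from 0 to 1 centred at ``t0`` with 10-90% width."""
    tau = width * _W_TO_TAU
    if tau < 1e-9:
        return 0.0 if t < t0 else 1.0
    x = (t - t0) / tau
    if x > 60.0:
        return 1.0
    if x < -60.0:
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SpeciesKinetics:
    """Flags and rate scales distinguishing the reporter species."""

    nuclear_enriched: bool = True     # else synthesis split by area (uniform)
    has_export: bool = False
    has_degradation: bool = False
    post_export: bool = False         # continued nuclear exit after degradation onset
    import_rate: float = 0.0          # /min, C->N from SPB separation (securin)
    spb_rate_scale: float = 0.0       # x spb_accumulation_rate
    synthesis_scale: float = 1.0


SPECIES: dict[str, SpeciesKinetics] = {
    "cdc13": SpeciesKinetics(has_export=True, has_degradation=True,
                             spb_rate_scale=0.05),
    "cdc2": SpeciesKinetics(has_export=True, post_export=True),
    "cut2": SpeciesKinetics(nuclear_enriched=False, has_degradation=True,
                            import_rate=0.08),
    "mad3": SpeciesKinetics(),
    "plo1": SpeciesKinetics(nuclear_enriched=False, spb_rate_scale=1.0),
    "cdc13_NLS_KK": SpeciesKinetics(has_export=True, has_degradation=True,
                                    spb_rate_scale=0.05),
    "cdc13_1_177_OE": SpeciesKinetics(has_export=True, has_degradation=True,
                                      synthesis_scale=20.0),
}

#: fraction of synthesis routed to the nucleus, per species
_NUCLEAR_FRACTION = {
    "cdc13": 0.35,
    "cdc2": 0.35,
    "mad3": 0.35,
    "cdc13_1_177_OE": 0.35,
    "cdc13_NLS_KK": 0.18,   # lowered N/C ratio, export window intact
}


@dataclass
class CellKinetics:
    """Fully resolved per-cell parameters, times on the cell's own clock
    (birth = 0, minutes)."""

    species: str
    birth_length_um: float
    division_length_um: float
    cycle_length_min: float
    anaphase_min: float
    spb_separation_min: float
    export_onset_min: float
    degradation_onset_min: float
    transition_width_min: float
    growth_arrest_min: float
    cell_width_um: float
    nuclear_area_fraction: float
    k_synthesis: float          # a.u./min
    export_rate: float          # a.u./min, constant flux during the window
    k_post_export: float        # /min, continued nuclear exit (cdc2)
    k_degradation: float        # /min after degradation onset
    nuclear_fraction: float     # of synthesis
    spb_rate: float             # a.u./min into the focus after Plo1 onset
    import_rate: float          # /min, C->N after SPB separation
    post_export: bool
    has_export: bool
    has_degradation: bool
    initial_total: float

    @property
    def plo1_onset_min(self) -> float:
        # Plo1 enrichment at the SPB and export onset are concomitant.
        return self.export_onset_min


def _capsule_area(length: float, width: float) -> float:
    if length <= width:
        return math.pi * (length / 2.0) ** 2
    return (length - width) * width + math.pi * (width / 2.0) ** 2


def draw_cell_params(
    params: TimelineParams,
    birth_length_um: float,
    species: str = "cdc13",
    rng: np.random.Generator | None = None,
) -> CellKinetics:
    """Resolve one cell's kinetic parameters, applying per-cell jitter.

    With ``rng=None`` (or all CVs zero) the nominal parameter values are
    used unchanged.
    """
    if birth_length_um <= 0:
        raise ValueError("birth_length_um must be > 0")
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; known: {sorted(SPECIES)}")
    params.validate()
    sp = SPECIES[species]

    def jitter(value: float, cv: float) -> float:
        if rng is None or cv == 0:
            return value
        return value * (1.0 + cv * rng.standard_normal())

    cycle = jitter(params.cycle_length(birth_length_um), params.cv_cycle_length)
    cycle = max(cycle, params.post_anaphase_min + params.export_onset_offset_min + 10.0)
    anaphase = cycle - params.post_anaphase_min
    spb_off = jitter(params.spb_separation_offset_min, params.cv_spb_separation)
    spb_off = max(spb_off, 1.0)
    export_off = jitter(params.export_onset_offset_min, params.cv_export_onset)
    export_off = max(export_off, spb_off + 1.0)
    k_s = jitter(params.synthesis_rate, params.cv_synthesis_rate) * sp.synthesis_scale
    k_s = max(k_s, 0.05 * params.synthesis_rate * sp.synthesis_scale)
    frac = jitter(params.export_fraction, params.cv_export_fraction)
    frac = min(max(frac, 0.0), 0.95)
    window = export_off - spb_off
    k_deg = (math.log(2.0) / params.degradation_halflife_min
             if sp.has_degradation and params.degradation_halflife_min > 0 else 0.0)
    nf = (_NUCLEAR_FRACTION[species] if sp.nuclear_enriched
          else params.nuclear_area_fraction)
    # constant-rate export: fraction `frac` of the nuclear amount present at
    # onset leaves over the window, producing the linear decline between the
    # two abrupt slope changes that the traces show. Before onset the
    # nucleus only gains nf * k_s per minute, so its amount at onset is known
    # in closed form.
    initial_total = k_s * cycle
    anaphase_local = anaphase
    export_onset_local = anaphase_local - export_off
    n_at_onset = nf * (initial_total + k_s * export_onset_local)
    export_rate = (frac * n_at_onset / window
                   if sp.has_export and frac > 0 else 0.0)
    k_post = (-math.log1p(-frac) / window
              if sp.post_export and frac > 0 else 0.0)

    return CellKinetics(
        species=species,
        birth_length_um=birth_length_um,
        division_length_um=params.division_length_um,
        cycle_length_min=cycle,
        anaphase_min=anaphase,
        spb_separation_min=anaphase - spb_off,
        export_onset_min=anaphase - export_off,
        degradation_onset_min=anaphase + params.degradation_onset_offset_min,
        transition_width_min=params.transition_width_min,
        growth_arrest_min=anaphase - spb_off,
        cell_width_um=params.cell_width_um,
        nuclear_area_fraction=params.nuclear_area_fraction,
        k_synthesis=k_s,
        export_rate=export_rate,
        k_post_export=k_post,
        k_degradation=k_deg,
        nuclear_fraction=nf,
        spb_rate=params.spb_accumulation_rate * sp.spb_rate_scale,
        import_rate=sp.import_rate,
        post_export=sp.post_export,
        has_export=sp.has_export,
        has_degradation=sp.has_degradation,
        initial_total=k_s * cycle,
    )


def kinetic_fluxes(t: float, n: float, c: float, s: float,
                   cell: CellKinetics) -> tuple[float, float, float]:
    """Time derivatives (dN/dt, dC/dt, dS/dt) of the compartment amounts.

    ``t`` is on the cell's own clock (birth = 0, minutes). This is the single
    source of truth for the dynamics; the integrator and any external
    cross-check both consume it.
    """
    w = cell.transition_width_min
    gate_deg = smooth_step(t, cell.degradation_onset_min, w)

    syn = cell.k_synthesis * (1.0 - gate_deg)
    dn = cell.nuclear_fraction * syn
    dc = (1.0 - cell.nuclear_fraction) * syn
    ds = 0.0

    if cell.has_export and cell.export_rate > 0:
        gate = (smooth_step(t, cell.export_onset_min, w)
                * (1.0 - smooth_step(t, cell.spb_separation_min, w)))
        # constant-rate flux (linear nuclear decline); guarded near n = 0
        j = min(cell.export_rate * gate, max(n, 0.0) * 10.0)
        dn -= j
        dc += j
    if cell.post_export and cell.k_post_export > 0:
        j = cell.k_post_export * gate_deg * n
        dn -= j
        dc += j
    if cell.import_rate > 0:
        j = cell.import_rate * smooth_step(t, cell.spb_separation_min, w) * c
        dc -= j
        dn += j
    if cell.spb_rate > 0:
        # focus accumulation from the cytoplasmic pool, capped so C stays >= 0
        j = cell.spb_rate * smooth_step(t, cell.plo1_onset_min, w)
        j = min(j, max(c, 0.0) * 2.0)
        dc -= j
        ds += j
    if cell.has_degradation:
        k = cell.k_degradation * gate_deg
        dn -= k * n
        dc -= k * c
        ds -= k * s
    return dn, dc, ds


def _integrate_dense(cell: CellKinetics, t_end: float,
                     dt: float = _DT_INTERNAL) -> tuple[np.ndarray, np.ndarray]:
    """RK4 integration of the compartment amounts on a dense local grid."""
    n_steps = max(1, int(math.ceil(t_end / dt)))
    ts = np.linspace(0.0, t_end, n_steps + 1)
    h = ts[1] - ts[0]
    out = np.empty((n_steps + 1, 3))
    n = cell.nuclear_fraction * cell.initial_total
    c = (1.0 - cell.nuclear_fraction) * cell.initial_total
    s = 0.0
    out[0] = (n, c, s)
    for i in range(n_steps):
        t = ts[i]
        k1 = kinetic_fluxes(t, n, c, s, cell)
        k2 = kinetic_fluxes(t + h / 2, n + h / 2 * k1[0], c + h / 2 * k1[1],
                            s + h / 2 * k1[2], cell)
        k3 = kinetic_fluxes(t + h / 2, n + h / 2 * k2[0], c + h / 2 * k2[1],
                            s + h / 2 * k2[2], cell)
        k4 = kinetic_fluxes(t + h, n + h * k3[0], c + h * k3[1],
                            s + h * k3[2], cell)
        n += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        c += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        s += h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        n, c, s = max(n, 0.0), max(c, 0.0), max(s, 0.0)
        out[i + 1] = (n, c, s)
    return ts, out


@dataclass
class GroundTruthTrace:
    """One cell's ground-truth compartment amounts and geometry over time.

    Times are absolute movie minutes; ``events`` holds absolute times for
    birth, plo1_onset, export_onset, spb_separation, anaphase and division.
    """

    cell_id: int
    species: str
    time_min: np.ndarray
    nuclear_amount: np.ndarray
    cytoplasmic_amount: np.ndarray
    spb_amount: np.ndarray
    nuclear_area_um2: np.ndarray
    cell_area_um2: np.ndarray
    cell_length_um: np.ndarray
    events: dict[str, float]
    birth_length_um: float
    division_length_um: float
    kinetics: CellKinetics = field(repr=False, default=None)

    @property
    def total_amount(self) -> np.ndarray:
        return self.nuclear_amount + self.cytoplasmic_amount + self.spb_amount

    @property
    def nuclear_concentration(self) -> np.ndarray:
        """a.u. per µm² of projected nuclear area."""
        return self.nuclear_amount / self.nuclear_area_um2

    @property
    def cytoplasmic_concentration(self) -> np.ndarray:
        return self.cytoplasmic_amount / (self.cell_area_um2 - self.nuclear_area_um2)

    def at(self, t: float | np.ndarray) -> dict[str, np.ndarray]:
        """Linear interpolation of amounts and geometry at absolute time(s)."""
        out = {}
        for name in ("nuclear_amount", "cytoplasmic_amount", "spb_amount",
                     "nuclear_area_um2", "cell_area_um2", "cell_length_um"):
            out[name] = np.interp(t, self.time_min, getattr(self, name))
        return out

    def alive_at(self, t: float) -> bool:
        return self.events["birth"] <= t <= self.events["division"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": self.cell_id,
            "species": self.species,
            "t_min": self.time_min,
            "nuclear_amount": self.nuclear_amount,
            "cytoplasmic_amount": self.cytoplasmic_amount,
            "spb_amount": self.spb_amount,
            "total_amount": self.total_amount,
            "nuclear_area_um2": self.nuclear_area_um2,
            "cell_area_um2": self.cell_area_um2,
            "cell_length_um": self.cell_length_um,
        })
        for k, v in self.events.items():
            df[f"event_{k}"] = v
        return df


def integrate_trace(
    cell: CellKinetics,
    cell_id: int = 0,
    birth_time_min: float = 0.0,
    dt_out_min: float = 0.25,
    t_grid: np.ndarray | None = None,
) -> GroundTruthTrace:
    """Integrate one cell's kinetics and sample them on an output grid.

    ``t_grid`` (absolute minutes) restricts output to grid points within the
    cell's lifetime; otherwise an even grid at ``dt_out_min`` covers the full
    cycle.
    """
    t_div_abs = birth_time_min + cell.cycle_length_min
    if t_grid is None:
        local = np.arange(0.0, cell.cycle_length_min + dt_out_min / 2, dt_out_min)
        local = np.minimum(local, cell.cycle_length_min)
    else:
        t_grid = np.asarray(t_grid, dtype=float)
        sel = (t_grid >= birth_time_min - 1e-9) & (t_grid <= t_div_abs + 1e-9)
        local = t_grid[sel] - birth_time_min
    if local.size == 0:
        raise ValueError("output grid does not intersect the cell's lifetime")

    ts, amounts = _integrate_dense(cell, float(local[-1]))
    n = np.interp(local, ts, amounts[:, 0])
    c = np.interp(local, ts, amounts[:, 1])
    s = np.interp(local, ts, amounts[:, 2])

    # linear tip growth until mitotic arrest, length frozen afterwards
    arrest = cell.growth_arrest_min
    frac = np.clip(local, 0.0, arrest) / arrest
    length = cell.birth_length_um + (cell.division_length_um - cell.birth_length_um) * frac
    area = np.array([_capsule_area(l, cell.cell_width_um) for l in length])
    nuc_area = cell.nuclear_area_fraction * area

    events = {
        "birth": birth_time_min,
        "plo1_onset": birth_time_min + cell.plo1_onset_min,
        "export_onset": birth_time_min + cell.export_onset_min,
        "spb_separation": birth_time_min + cell.spb_separation_min,
        "anaphase": birth_time_min + cell.anaphase_min,
        "division": t_div_abs,
    }
    return GroundTruthTrace(
        cell_id=cell_id,
        species=cell.species,
        time_min=local + birth_time_min,
        nuclear_amount=n,
        cytoplasmic_amount=c,
        spb_amount=s,
        nuclear_area_um2=nuc_area,
        cell_area_um2=area,
        cell_length_um=length,
        events=events,
        birth_length_um=cell.birth_length_um,
        division_length_um=cell.division_length_um,
        kinetics=cell,
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_cell(
    params: TimelineParams,
    birth_length_um: float,
    species: str = "cdc13",
    seed: int | np.random.Generator | None = None,
    cell_id: int = 0,
    birth_time_min: float = 0.0,
    dt_out_min: float = 0.25,
    t_grid: np.ndarray | None = None,
) -> GroundTruthTrace:
    """Simulate one cell cycle; deterministic given ``seed``.

    ``seed=None`` disables per-cell jitter (nominal parameters).
    """
    rng = _as_rng(seed) if seed is not None else None
    cell = draw_cell_params(params, birth_length_um, species, rng)
    return integrate_trace(cell, cell_id=cell_id, birth_time_min=birth_time_min,
                           dt_out_min=dt_out_min, t_grid=t_grid)


def sample_population(
    params: TimelineParams,
    n: int,
    seed: int = 0,
    species: str = "cdc13",
    anaphase_time_min: float | None = None,
    dt_out_min: float = 0.25,
    t_grid: np.ndarray | None = None,
) -> list[GroundTruthTrace]:
    """Draw ``n`` independent cells with parameter jitter.

    Per-cell randomness comes from counter-derived substreams
    (``SeedSequence([seed, i])``), so populations are order-independent and
    reproducible. If ``anaphase_time_min`` is given, birth times are chosen
    so each cell's anaphase falls near it (jittered by
    ``params.anaphase_jitter_sd_min``); otherwise all cells are born at 0.
    """
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    traces = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        birth = params.birth_length_mean_um * (
            1.0 + params.cv_birth_length * rng.standard_normal())
        birth = max(birth, 0.5 * params.birth_length_mean_um)
        cell = draw_cell_params(params, birth, species, rng)
        if anaphase_time_min is None:
            birth_time = 0.0
        else:
            target = anaphase_time_min
            if params.anaphase_jitter_sd_min > 0:
                target += params.anaphase_jitter_sd_min * rng.standard_normal()
            birth_time = target - cell.anaphase_min
        traces.append(integrate_trace(cell, cell_id=i, birth_time_min=birth_time,
                                      dt_out_min=dt_out_min, t_grid=t_grid))
    return traces


def simulate_lineage(
    params: TimelineParams,
    n_cycles: int,
    seed: int = 0,
    species: str = "cdc13",
    lineage_id: int = 0,
    dt_out_min: float = 1.0,
) -> list[GroundTruthTrace]:
    """Follow one cell through ``n_cycles`` consecutive divisions.

    After each division one daughter (half the division length, with birth-
    length jitter) is followed; traces share ``cell_id`` = ``lineage_id`` and
    abut in time, so consecutive division events define measurable cycle
    lengths.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), lineage_id]))
    birth = params.birth_length_mean_um * (
        1.0 + params.cv_birth_length * rng.standard_normal())
    t0 = 0.0
    out = []
    for _ in range(n_cycles):
        cell = draw_cell_params(params, birth, species, rng)
        tr = integrate_trace(cell, cell_id=lineage_id, birth_time_min=t0,
                             dt_out_min=dt_out_min)
        out.append(tr)
        t0 = tr.events["division"]
        birth = cell.division_length_um / 2.0 * (
            1.0 + 0.03 * rng.standard_normal())
    return out


def population_to_frame(traces: list[GroundTruthTrace]) -> pd.DataFrame:
    """Tidy table: one row per cell per frame, with event columns."""
    return pd.concat([t.to_frame() for t in traces], ignore_index=True)
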