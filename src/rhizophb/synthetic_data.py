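"""Seeded synthetic inputs with the statistical structure the analyses assume.

No raw nodule or starvation data are deposited for this system, so every
pipeline stage is exercised on generated inputs that emulate the relevant
structure: multiplicative (lognormal) stain noise around an instrument
response curve, debris events the scatter gate can act on, nested
isolate/plant/residual variance with a settable isolate-variance fraction
and a right-skewed (lognormal) option, and starvation trajectories in which
PHB is partitioned asymmetrically at division so that bimodal per-cell
distributions emerge as the population grows.

Every generator is a deterministic function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flow_calibration import (
    CalibrationStandard,
    EventTable,
    GatingConfig,
    StandardCurve,
)

__all__ = [
    "EventSimConfig",
    "NoduleStudyDesign",
    "RealizedComponents",
    "StarvationSimConfig",
    "StarvationSample",
    "default_instrument_curve",
    "DEFAULT_STANDARD_LEVELS_PG",
    "simulate_standards",
    "simulate_event_table",
    "simulate_nodule_study",
    "simulate_starvation",
    "starvation_series_frame",
]


def default_instrument_curve() -> StandardCurve:
    """Ground-truth instrument response used by the generators: F = 200 * pg."""
    return StandardCurve(
        slope=1.0,
        intercept=-math.log10(200.0),
        fit_domain="log-log",
        r_squared=1.0,
        fluorescence_range=(1e-2, 1e5),
    )


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given coefficient of variation."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(0.0, sigma, size=size))


# six GC-referenced standards spanning the 0-2.5 pg/cell working range
DEFAULT_STANDARD_LEVELS_PG = (0.05, 0.2, 0.5, 1.0, 1.7, 2.5)


def simulate_standards(
    levels=DEFAULT_STANDARD_LEVELS_PG,
    noise_cv: float = 0.05,
    seed: int | None = None,
    curve: StandardCurve | None = None,
    batch_id: str = "batch1",
) -> list[CalibrationStandard]:
    """Calibration standards whose fluorescence sits on the instrument curve
    up to multiplicative measurement noise."""
    pg = np.asarray(levels, dtype=float)
    if np.unique(pg).size < 2:
        raise ValueError("need >= 2 distinct standard levels")
    if curve is None:
        curve = default_instrument_curve()
    rng = np.random.default_rng(seed)
    noise = _lognormal_factor(rng, noise_cv, pg.size)
    return [
        CalibrationStandard(
            standard_id=f"std{k+1}",
            known_phb_pg=float(p),
            geom_mean_fluorescence=float(curve.inverse(p) * noise[k]),
            batch_id=batch_id,
        )
        for k, p in enumerate(pg)
    ]


@dataclass(frozen=True)
class EventSimConfig:
    """Per-cell event generator: lognormal fluorescence + optional debris."""

    n_cells: int = 1000
    true_phb_pg: float = 0.5
    cv: float = 0.3
    debris_fraction: float = 0.0
    seed: int | None = None
    sample_id: str = "sim"
    curve: StandardCurve = field(default_factory=default_instrument_curve)
    gate: GatingConfig = field(default_factory=GatingConfig)

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0 <= self.debris_fraction < 1:
            raise ValueError("debris_fraction must lie in [0, 1)")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


def _scatter_inside(rng: np.random.Generator, gate: GatingConfig, n: int):
    flo, fhi = gate.forward_scatter_bounds
    slo, shi = gate.side_scatter_bounds
    # cells cluster in the middle of the gate box
    fsc = rng.uniform(flo + 0.2 * (fhi - flo), flo + 0.8 * (fhi - flo), n)
    ssc = rng.uniform(slo + 0.2 * (shi - slo), slo + 0.8 * (shi - slo), n)
    return fsc, ssc


def simulate_event_table(config: EventSimConfig) -> EventTable:
    """Events for one sample: cells on the curve at ``true_phb_pg`` plus debris.

    Debris events are placed below the scatter gate with near-zero
    fluorescence, so gating recovers exactly the cell events. The debris
    count is chosen so debris make up ``debris_fraction`` of all events.
    """
    rng = np.random.default_rng(config.seed)
    gate = config.gate
    n_cells = config.n_cells
    n_debris = round(n_cells * config.debris_fraction / (1 - config.debris_fraction))

    f_center = config.curve.inverse(config.true_phb_pg)
    fl_cells = f_center * _lognormal_factor(rng, config.cv, n_cells)
    fsc_c, ssc_c = _scatter_inside(rng, gate, n_cells)

    flo = gate.forward_scatter_bounds[0]
    slo = gate.side_scatter_bounds[0]
    fl_debris = rng.uniform(0.0, 0.5 * gate.min_fluorescence, n_debris)
    fsc_d = rng.uniform(0.0, 0.9 * flo, n_debris)
    ssc_d = rng.uniform(0.0, 0.9 * slo, n_debris)

    fl = np.concatenate([fl_cells, fl_debris])
    fsc = np.concatenate([fsc_c, fsc_d])
    ssc = np.concatenate([ssc_c, ssc_d])
    order = rng.permutation(fl.size)
    return EventTable(
        sample_id=config.sample_id,
        fluorescence=fl[order],
        forward_scatter=fsc[order],
        side_scatter=ssc[order],
    )


@dataclass(frozen=True)
class NoduleStudyDesign:
    """Balanced nested study: isolates x plants x nodules.

    Variance fractions partition the total variance among isolate, plant and
    residual effects. With ``skew='lognormal'`` (default, emulating the
    right-skewed nodule distributions seen in the field) the effects are
    added on the natural-log scale with total log-scale SD ``total_sd_pg``
    and the phenotype is grand_mean_pg * exp(effects); with ``skew='normal'``
    the effects are added on the pg scale directly, so the fractions are
    variance fractions of the measurements themselves.
    """

    n_isolates: int = 20
    plants_per_isolate: int = 3
    nodules_per_plant: int = 3
    grand_mean_pg: float = 0.35
    isolate_fraction: float = 0.63
    plant_fraction: float = 0.185
    residual_fraction: float = 0.185
    total_sd_pg: float = 0.6
    skew: str = "lognormal"
    seed: int | None = None

    def __post_init__(self) -> None:
        for n in (self.n_isolates, self.plants_per_isolate, self.nodules_per_plant):
            if n < 1:
                raise ValueError("design counts must be >= 1")
        fr = (self.isolate_fraction, self.plant_fraction, self.residual_fraction)
        if any(f < 0 for f in fr):
            raise ValueError("variance fractions must be >= 0")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("variance fractions must sum to 1")
        if self.skew not in ("lognormal", "normal"):
            raise ValueError("skew must be 'lognormal' or 'normal'")


@dataclass(frozen=True)
class RealizedComponents:
    """Variance decomposition actually realised by one simulated dataset.

    Sample variances of the drawn isolate, plant and residual effects (on the
    log scale for lognormal skew). The realised isolate-variance fraction is
    the natural target for inference that conditions on the isolate panel,
    such as the plant-resampling bootstrap.
    """

    v_isolate: float
    v_plant: float
    v_residual: float

    @property
    def h2(self) -> float:
        return self.v_isolate / (self.v_isolate + self.v_plant + self.v_residual)


def simulate_nodule_study(
    design: NoduleStudyDesign, return_realized: bool = False
):
    """Nodule phenotype table (isolate_id, plant_id, side, mean_phb_pg).

    With ``return_realized`` also returns the :class:`RealizedComponents` of
    the drawn effects.
    """
    rng = np.random.default_rng(design.seed)
    i, p, n = design.n_isolates, design.plants_per_isolate, design.nodules_per_plant
    sd = design.total_sd_pg
    e_iso = rng.normal(0, sd * math.sqrt(design.isolate_fraction), size=(i, 1, 1))
    e_pl = rng.normal(0, sd * math.sqrt(design.plant_fraction), size=(i, p, 1))
    e_res = rng.normal(0, sd * math.sqrt(design.residual_fraction), size=(i, p, n))
    eff = e_iso + e_pl + e_res
    if design.skew == "lognormal":
        values = design.grand_mean_pg * np.exp(eff)
    else:
        values = design.grand_mean_pg + eff
    iso_ids = np.repeat([f"iso{k:02d}" for k in range(i)], p * n)
    plant_ids = np.repeat(
        [f"iso{k:02d}_plant{j}" for k in range(i) for j in range(p)], n
    )
    df = pd.DataFrame(
        {
            "isolate_id": iso_ids,
            "plant_id": plant_ids,
            "side": "focal",
            "mean_phb_pg": values.ravel(),
        }
    )
    if not return_realized:
        return df
    realized = RealizedComponents(
        v_isolate=float(np.var(e_iso, ddof=1)) if i > 1 else 0.0,
        v_plant=float(np.var(e_pl, ddof=1)) if i * p > 1 else 0.0,
        v_residual=float(np.var(e_res, ddof=1)) if i * p * n > 1 else 0.0,
    )
    return df, realized


@dataclass(frozen=True)
class StarvationSample:
    """One starvation-culture sampling point."""

    isolate_id: str
    replicate_id: str
    day: int
    cfu_per_ml: float
    events: EventTable
    phb_pg: np.ndarray  # true per-cell PHB (pg) behind the events


@dataclass(frozen=True)
class StarvationSimConfig:
    """Individual-based starvation culture with asymmetric PHB partitioning.

    Each simulated cell carries a PHB store that declines on a biphasic
    schedule (fast during roughly the first month, slow thereafter). Cells
    divide while the carrying capacity allows and either an external
    supplement budget (divisions attainable without PHB, emulating residual
    resources in the buffer) or their own PHB (at ``division_phb_cost_pg``
    per division) can pay for it. At division the parent keeps
    (1 - daughter_phb_fraction) of its PHB; the default 0 gives fully
    asymmetric old-pole retention, producing a low-PHB daughter subgroup.
    No PHB synthesis occurs, so total PHB mass never increases.
    """

    n_cells_initial: int = 400
    initial_phb_mean_pg: float = 1.0
    initial_phb_cv: float = 0.4
    # fast first-month use (roughly 70% of a 1 pg endowment over 29 days),
    # then a trickle near ten-fold the dormancy requirement at 26 C
    phase1_rate_pg_day: float = 0.024
    phase1_days: int = 30
    phase2_rate_pg_day: float = 6e-6
    daughter_phb_fraction: float = 0.0
    division_phb_cost_pg: float = 0.02
    # chosen so a low-density culture grows roughly ten-fold within the
    # first month, the level of short-term growth these cultures exhibit
    division_prob_per_day: float = 0.25
    carrying_capacity_cfu_per_ml: float = 1e6
    initial_cfu_per_ml: float = 1e5
    external_growth_supplement: float = 4.0  # fold growth attainable without PHB
    sampling_days: tuple[int, ...] = (0, 7, 14, 21, 29, 127, 430)
    measurement_cv: float = 0.10
    # background (non-specific) stain signal of a PHB-free cell, expressed in
    # pg equivalents; sits just above the debris gate so intact daughter
    # cells remain visible in gated events
    floor_pg: float = 0.06
    isolate_id: str = "isoA"
    replicate_id: str = "rep1"
    seed: int | None = None
    curve: StandardCurve = field(default_factory=default_instrument_curve)
    gate: GatingConfig = field(default_factory=GatingConfig)

    def __post_init__(self) -> None:
        if not 0 <= self.daughter_phb_fraction <= 0.5:
            raise ValueError("daughter_phb_fraction must lie in [0, 0.5]")
        for r in (self.phase1_rate_pg_day, self.phase2_rate_pg_day):
            if r < 0:
                raise ValueError("use rates must be >= 0")
        if self.external_growth_supplement < 1:
            raise ValueError("external_growth_supplement is a fold >= 1")
        if self.initial_cfu_per_ml <= 0:
            raise ValueError("initial_cfu_per_ml must be > 0")


def _emit_sample(cfg: StarvationSimConfig, rng, day: int, phb: np.ndarray,
                 cfu: float) -> StarvationSample:
    fl = np.array(
        [cfg.curve.inverse(max(p, cfg.floor_pg)) for p in phb]
    ) * _lognormal_factor(rng, cfg.measurement_cv, phb.size)
    fsc, ssc = _scatter_inside(rng, cfg.gate, phb.size)
    events = EventTable(
        sample_id=f"{cfg.isolate_id}_{cfg.replicate_id}_d{day}",
        fluorescence=fl,
        forward_scatter=fsc,
        side_scatter=ssc,
    )
    return StarvationSample(
        isolate_id=cfg.isolate_id,
        replicate_id=cfg.replicate_id,
        day=day,
        cfu_per_ml=cfu,
        events=events,
        phb_pg=phb.copy(),
    )


def simulate_starvation(config: StarvationSimConfig) -> list[StarvationSample]:
    """Run the starvation culture and emit samples at the sampling days."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    phb = cfg.initial_phb_mean_pg * _lognormal_factor(
        rng, cfg.initial_phb_cv, cfg.n_cells_initial
    )
    n0 = cfg.n_cells_initial
    cells_per_cfu = n0 / cfg.initial_cfu_per_ml
    max_cells = int(round(cfg.carrying_capacity_cfu_per_ml * cells_per_cfu))
    supplement_budget = int(round(n0 * (cfg.external_growth_supplement - 1.0)))

    samples: list[StarvationSample] = []
    sampling = sorted(set(int(d) for d in cfg.sampling_days))
    if sampling and sampling[0] == 0:
        samples.append(_emit_sample(cfg, rng, 0, phb, phb.size / cells_per_cfu))
        sampling = sampling[1:]
    if not sampling:
        return samples

    for day in range(1, sampling[-1] + 1):
        rate = cfg.phase1_rate_pg_day if day <= cfg.phase1_days else cfg.phase2_rate_pg_day
        phb = np.maximum(phb - rate, 0.0)
        if phb.size < max_cells:
            headroom = max_cells - phb.size
            willing = np.flatnonzero(rng.random(phb.size) < cfg.division_prob_per_day)
            new_daughters = []
            for idx in willing:
                if headroom <= 0:
                    break
                if supplement_budget > 0:
                    supplement_budget -= 1
                elif phb[idx] >= cfg.division_phb_cost_pg:
                    phb[idx] -= cfg.division_phb_cost_pg
                else:
                    continue
                d_share = cfg.daughter_phb_fraction * phb[idx]
                phb[idx] -= d_share
                new_daughters.append(d_share)
                headroom -= 1
            if new_daughters:
                phb = np.concatenate([phb, np.array(new_daughters)])
        if day in sampling:
            samples.append(_emit_sample(cfg, rng, day, phb, phb.size / cells_per_cfu))
    return samples


def starvation_series_frame(samples: list[StarvationSample]) -> pd.DataFrame:
    """Long table (isolate_id, replicate_id, day, cfu_per_ml) from samples."""
    return pd.DataFrame(
        {
            "isolate_id": [s.isolate_id for s in samples],
            "replicate_id": [s.replicate_id for s in samples],
            "day": [s.day for s in samples],
            "cfu_per_ml": [s.cfu_per_ml for s in samples],
        }
    )
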