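"""Temperature-dependent model of PHB expenditure by a non-growing soil cell.

A resting rhizobial cell respires carbon at a rate that depends on soil
temperature and on its metabolic state. The per-day metabolic rate is

    log10(m) = alpha * T + beta

with m in g C respired per g structural-biomass C per day and T in deg C.
Five states are modelled: full somatic maintenance (FSM: everything except
new biomass), three intermediates at exactly 10%, 1% and 0.1% of FSM
(same alpha, beta offset -1, -2, -3), and deep dormancy (its own alpha/beta,
roughly a thousand-fold below FSM). The FSM and dormancy coefficients were
digitised from a published compilation of prokaryote metabolic rates; the
printed slopes are used as 9.9e-2 and 8.4e-2 per deg C (the magnitude that
reproduces the documented thousand-fold FSM/dormancy span — see
docs/methods.md).

The daily PHB budget converts respiration to polymer mass:

    phb_per_day = m * b * C_b / C_phb        [pg PHB / day]

where b is structural biomass (0.5 pg), C_b the carbon fraction of biomass
(96/150, from C8H8O2N1) and C_phb the carbon fraction of PHB (48/86, from
C4H6O2). Soil temperature follows an annual sinusoid (first-order Fourier
fit to monthly means at 20 cm depth):

    T(d) = (Tmax + Tmin)/2 + (Tmax - Tmin)/2 * sin(2*pi*(d - delta)/365)

Days are integer calendar days on a 365-day year (no leap days); the model
evaluates temperature once per day. Because T is periodic, PHB required over
whole years is start-day independent, which gives O(365) evaluation of
arbitrarily long horizons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TemperatureModel",
    "TemperatureFit",
    "MetabolicState",
    "CellParams",
    "SurvivalCurve",
    "DaysSupported",
    "STATES",
    "STATE_ORDER",
    "soil_temperature",
    "fit_temperature_model",
    "metabolic_rate",
    "daily_phb_requirement",
    "phb_required",
    "days_supported",
    "survival_curve",
    "phb_biomass_fraction",
]

DAYS_PER_YEAR = 365
DAYS_PER_MONTH = 365.0 / 12.0


@dataclass(frozen=True)
class TemperatureModel:
    """Annual sinusoidal soil temperature (Waseca, MN defaults, 20 cm depth)."""

    t_max: float = 25.0
    t_min: float = -3.0
    delta: float = 121.0  # calendar day of the upward midpoint crossing (5 May)

    def __post_init__(self) -> None:
        if not self.t_max > self.t_min:
            raise ValueError("t_max must exceed t_min")
        if not 1 <= self.delta <= 365:
            raise ValueError("delta must be a calendar day in [1, 365]")


@dataclass(frozen=True)
class TemperatureFit:
    model: TemperatureModel | None
    sse: float
    degenerate: bool = False


@dataclass(frozen=True)
class MetabolicState:
    """Arrhenius-like log-linear metabolic rate: log10(m) = alpha*T + beta."""

    label: str
    alpha: float  # per deg C
    beta: float   # log10(g C / g biomass C / day) at 0 deg C
    beta_offset: float = 0.0  # calibration hook, default off

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")

    def with_offset(self, beta_offset: float) -> "MetabolicState":
        return replace(self, beta_offset=beta_offset)


_FSM_ALPHA = 9.9e-2
_FSM_BETA = -5.14

STATES: dict[str, MetabolicState] = {
    "full_somatic_maintenance": MetabolicState("full_somatic_maintenance", _FSM_ALPHA, _FSM_BETA),
    "intermediate_10pct": MetabolicState("intermediate_10pct", _FSM_ALPHA, _FSM_BETA - 1.0),
    "intermediate_1pct": MetabolicState("intermediate_1pct", _FSM_ALPHA, _FSM_BETA - 2.0),
    "intermediate_0.1pct": MetabolicState("intermediate_0.1pct", _FSM_ALPHA, _FSM_BETA - 3.0),
    "dormancy": MetabolicState("dormancy", 8.4e-2, -8.17),
}

# fastest to slowest metabolism
STATE_ORDER = [
    "full_somatic_maintenance",
    "intermediate_10pct",
    "intermediate_1pct",
    "intermediate_0.1pct",
    "dormancy",
]


@dataclass(frozen=True)
class CellParams:
    """Stoichiometry of a resting cell.

    carbon fractions follow C8H8O2N1 for structural biomass (96/150) and
    C4H6O2 for PHB (48/86), with integer atomic masses 12/1/16/14.
    """

    structural_biomass_pg: float = 0.5
    carbon_fraction_biomass: float = 96.0 / 150.0
    carbon_fraction_phb: float = 48.0 / 86.0

    def __post_init__(self) -> None:
        if self.structural_biomass_pg <= 0:
            raise ValueError("structural_biomass_pg must be > 0")
        for f in (self.carbon_fraction_biomass, self.carbon_fraction_phb):
            if not 0 < f < 1:
                raise ValueError("carbon fractions must lie in (0, 1)")


def _resolve_state(state: str | MetabolicState) -> MetabolicState:
    if isinstance(state, MetabolicState):
        return state
    try:
        return STATES[state]
    except KeyError:
        raise ValueError(f"unknown metabolic state {state!r}; one of {STATE_ORDER}") from None


def soil_temperature(day, model: TemperatureModel = TemperatureModel()):
    """Soil temperature (deg C) on a calendar day; periodic with period 365."""
    d = np.asarray(day, dtype=float)
    mid = 0.5 * (model.t_max + model.t_min)
    amp = 0.5 * (model.t_max - model.t_min)
    out = mid + amp * np.sin(2.0 * math.pi * (d - model.delta) / DAYS_PER_YEAR)
    return float(out) if np.isscalar(day) else out


def fit_temperature_model(monthly_means) -> TemperatureFit:
    """Fit the annual sinusoid to 12 monthly mean temperatures.

    ``monthly_means``: iterable of (month 1..12, mean_temp) pairs. Month m is
    placed at its midpoint day (m - 0.5) * 365/12. delta is found by grid
    search over integer calendar days; midpoint and amplitude follow in
    closed form by OLS given delta. A constant series is degenerate (zero
    amplitude, delta undefined).
    """
    pairs = sorted((int(m), float(t)) for m, t in monthly_means)
    if len(pairs) != 12 or [m for m, _ in pairs] != list(range(1, 13)):
        raise ValueError("need exactly one mean temperature for each month 1..12")
    days = np.array([(m - 0.5) * DAYS_PER_MONTH for m, _ in pairs])
    temps = np.array([t for _, t in pairs])
    if np.allclose(temps, temps[0]):
        return TemperatureFit(model=None, sse=0.0, degenerate=True)
    best = None
    for delta in range(1, DAYS_PER_YEAR + 1):
        s = np.sin(2.0 * math.pi * (days - delta) / DAYS_PER_YEAR)
        sbar = s.mean()
        sxx = float(np.sum((s - sbar) ** 2))
        if sxx == 0:
            continue
        amp = float(np.sum((s - sbar) * (temps - temps.mean()))) / sxx
        if amp <= 0:
            continue
        mid = float(temps.mean() - amp * sbar)
        sse = float(np.sum((temps - (mid + amp * s)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, mid, amp, delta)
    assert best is not None
    sse, mid, amp, delta = best
    model = TemperatureModel(t_max=mid + amp, t_min=mid - amp, delta=float(delta))
    return TemperatureFit(model=model, sse=sse, degenerate=False)


def metabolic_rate(temp, state: str | MetabolicState):
    """Metabolic rate m (g C respired / g biomass C / day) at a temperature."""
    st = _resolve_state(state)
    t = np.asarray(temp, dtype=float)
    out = 10.0 ** (st.alpha * t + st.beta + st.beta_offset)
    return float(out) if np.isscalar(temp) else out


def daily_phb_requirement(
    temp, state: str | MetabolicState, cell: CellParams = CellParams()
):
    """pg PHB consumed per day at a given temperature and metabolic state."""
    m = metabolic_rate(temp, state)
    return (
        m * cell.structural_biomass_pg * cell.carbon_fraction_biomass
        / cell.carbon_fraction_phb
    )


def _daily_cycle(
    start_day: int,
    state: str | MetabolicState,
    cell: CellParams,
    temp_model: TemperatureModel,
) -> np.ndarray:
    """Daily PHB requirement (pg) for days start_day+1 .. start_day+365."""
    days = start_day + 1 + np.arange(DAYS_PER_YEAR)
    temps = soil_temperature(days, temp_model)
    return np.asarray(daily_phb_requirement(temps, state, cell))


def phb_required(
    duration_days: int,
    start_day: int = 258,
    state: str | MetabolicState = "dormancy",
    cell: CellParams = CellParams(),
    temp_model: TemperatureModel = TemperatureModel(),
) -> float:
    """pg PHB needed to sustain a state for ``duration_days`` from ``start_day``.

    Sums the daily requirement over days start_day+1 .. start_day+t, using the
    periodicity of the temperature cycle so that arbitrarily long horizons
    cost O(365). Additive: cost over t1+t2 days equals cost over t1 plus cost
    over t2 starting t1 days later.
    """
    t = int(duration_days)
    if t != duration_days or t < 0:
        raise ValueError("duration_days must be a non-negative integer")
    cycle = _daily_cycle(int(start_day), state, cell, temp_model)
    csum = np.concatenate(([0.0], np.cumsum(cycle)))
    q, r = divmod(t, DAYS_PER_YEAR)
    return float(q * csum[DAYS_PER_YEAR] + csum[r])


@dataclass(frozen=True)
class DaysSupported:
    days: int
    censored: bool = False


def days_supported(
    phb_pg: float,
    start_day: int = 258,
    state: str | MetabolicState = "dormancy",
    cell: CellParams = CellParams(),
    temp_model: TemperatureModel = TemperatureModel(),
    max_days: int = 10_000_000,
) -> DaysSupported:
    """Largest t <= max_days whose cumulative PHB cost fits within the budget.

    Exact generalized inverse of :func:`phb_required` on integer days
    (monotone non-decreasing in phb_pg). If the budget outlasts ``max_days``
    the result is censored at max_days.
    """
    if phb_pg < 0:
        raise ValueError("phb_pg must be >= 0")
    cycle = _daily_cycle(int(start_day), state, cell, temp_model)
    csum = np.concatenate(([0.0], np.cumsum(cycle)))
    year_cost = float(csum[DAYS_PER_YEAR])
    rtol = 1e-9  # forgive float round-off in the budget comparison
    budget = float(phb_pg)
    q = int(budget // year_cost)
    while (q + 1) * year_cost <= budget * (1.0 + rtol):
        q += 1
    while q > 0 and q * year_cost > budget * (1.0 + rtol):
        q -= 1
    rem = budget - q * year_cost
    k = int(np.searchsorted(csum, rem * (1.0 + rtol) + 1e-300, side="right")) - 1
    k = min(max(k, 0), DAYS_PER_YEAR)
    days = q * DAYS_PER_YEAR + k
    if days >= max_days:
        return DaysSupported(days=int(max_days), censored=True)
    return DaysSupported(days=days, censored=False)


@dataclass(frozen=True)
class SurvivalCurve:
    state: str
    start_day: int
    phb_pg: tuple[float, ...]
    days: tuple[int, ...]
    censored: tuple[bool, ...]


def survival_curve(
    phb_grid,
    start_day: int = 258,
    states=STATE_ORDER,
    cell: CellParams = CellParams(),
    temp_model: TemperatureModel = TemperatureModel(),
    max_days: int = 10_000_000,
) -> list[SurvivalCurve]:
    """Days-supported as a function of PHB endowment, one curve per state."""
    grid = np.asarray(phb_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("phb_grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("phb_grid must be sorted ascending")
    curves = []
    for state in states:
        st = _resolve_state(state)
        res = [
            days_supported(p, start_day, st, cell, temp_model, max_days) for p in grid
        ]
        curves.append(
            SurvivalCurve(
                state=st.label,
                start_day=int(start_day),
                phb_pg=tuple(float(p) for p in grid),
                days=tuple(r.days for r in res),
                censored=tuple(r.censored for r in res),
            )
        )
    return curves


def phb_biomass_fraction(phb_pg: float, structural_biomass_pg: float = 0.5) -> float:
    """Fraction of total cell biomass made up by PHB (pg / (pg + structural))."""
    if phb_pg < 0 or structural_biomass_pg <= 0:
        raise ValueError("phb_pg >= 0 and structural_biomass_pg > 0 required")
    return phb_pg / (phb_pg + structural_biomass_pg)
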