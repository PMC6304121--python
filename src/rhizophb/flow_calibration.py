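"""Calibrated per-cell PHB quantification from flow-cytometry event tables.

A flow cytometer reports, per event, a lipid-stain fluorescence intensity
(Nile Red / Bodipy on FL1 or FL3) plus forward and side scatter. Events from
a crushed nodule are a mixture of intact rhizobia and debris; debris is
removed with a deterministic gate (rectangular scatter bounds plus a
fluorescence floor), the gated fluorescences are summarised by their
geometric mean (robust to the heavy right tail of stain intensities), and
the geometric mean is converted to pg PHB per cell through a standard curve
fitted to reference standards whose PHB content was measured independently
by gas chromatography.

Standards are run per instrument batch, so curves are fitted per ``batch_id``
and never pooled across batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GatingConfig",
    "GateResult",
    "CalibrationStandard",
    "StandardCurve",
    "PhbPrediction",
    "NoduleSummary",
    "gate_events",
    "geometric_mean",
    "fit_standard_curve",
    "fluorescence_to_phb",
    "nodule_mean_phb",
    "fit_batch_curves",
    "calibrate_samples",
]


class EmptyAfterGatingError(ValueError):
    """Raised when gating removes every event in a sample."""


class UnderdeterminedCurveError(ValueError):
    """Raised when a standard curve cannot be identified from the standards."""


@dataclass
class EventTable:
    """Per-cell measurements for one sample (nodule or starvation aliquot).

    All channels are in arbitrary instrument units, finite and non-negative.
    """

    sample_id: str
    fluorescence: np.ndarray
    forward_scatter: np.ndarray
    side_scatter: np.ndarray

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.forward_scatter = np.asarray(self.forward_scatter, dtype=float)
        self.side_scatter = np.asarray(self.side_scatter, dtype=float)
        n = self.fluorescence.size
        if n == 0:
            raise ValueError(f"sample {self.sample_id!r}: event table is empty")
        if self.forward_scatter.size != n or self.side_scatter.size != n:
            raise ValueError(f"sample {self.sample_id!r}: channel lengths differ")
        for name in ("fluorescence", "forward_scatter", "side_scatter"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be finite and >= 0"
                )

    def __len__(self) -> int:
        return int(self.fluorescence.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "fluorescence": self.fluorescence,
                "forward_scatter": self.forward_scatter,
                "side_scatter": self.side_scatter,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None) -> "EventTable":
        if sample_id is not None:
            df = df[df["sample_id"] == sample_id]
        else:
            ids = df["sample_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple samples; pass sample_id")
            sample_id = ids[0]
        return cls(
            sample_id=str(sample_id),
            fluorescence=df["fluorescence"].to_numpy(),
            forward_scatter=df["forward_scatter"].to_numpy(),
            side_scatter=df["side_scatter"].to_numpy(),
        )


@dataclass(frozen=True)
class GatingConfig:
    """Deterministic debris gate: fluorescence floor + rectangular scatter box."""

    min_fluorescence: float = 5.0
    forward_scatter_bounds: tuple[float, float] = (50.0, 5000.0)
    side_scatter_bounds: tuple[float, float] = (50.0, 5000.0)

    def __post_init__(self) -> None:
        if self.min_fluorescence < 0:
            raise ValueError("min_fluorescence must be >= 0")
        for lo, hi in (self.forward_scatter_bounds, self.side_scatter_bounds):
            if not lo < hi:
                raise ValueError("scatter bounds must satisfy low < high")


@dataclass
class GateResult:
    events: EventTable
    excluded_fraction: float
    n_input: int


def gate_events(events: EventTable, config: GatingConfig) -> GateResult:
    """Remove debris events; keep order; report the fraction excluded.

    An event is retained iff its fluorescence is at or above the floor and its
    forward/side scatter fall inside the rectangular bounds (inclusive).
    Raises :class:`EmptyAfterGatingError` if nothing survives.
    """
    flo, fhi = config.forward_scatter_bounds
    slo, shi = config.side_scatter_bounds
    keep = (
        (events.fluorescence >= config.min_fluorescence)
        & (events.forward_scatter >= flo)
        & (events.forward_scatter <= fhi)
        & (events.side_scatter >= slo)
        & (events.side_scatter <= shi)
    )
    n = len(events)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise EmptyAfterGatingError(
            f"empty-after-gating: all {n} events excluded for sample "
            f"{events.sample_id!r}"
        )
    gated = EventTable(
        sample_id=events.sample_id,
        fluorescence=events.fluorescence[keep],
        forward_scatter=events.forward_scatter[keep],
        side_scatter=events.side_scatter[keep],
    )
    return GateResult(events=gated, excluded_fraction=1.0 - n_keep / n, n_input=n)


def geometric_mean(values) -> float:
    """exp(mean(log x)) for strictly positive values.

    Scale-equivariant: ``geometric_mean(k * x) == k * geometric_mean(x)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("geometric_mean of empty input")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("geometric_mean requires finite values > 0")
    return float(np.exp(np.mean(np.log(v))))


@dataclass(frozen=True)
class CalibrationStandard:
    """One reference standard: GC-measured PHB content + its measured signal."""

    standard_id: str
    known_phb_pg: float
    geom_mean_fluorescence: float
    batch_id: str = "default"

    def __post_init__(self) -> None:
        if self.known_phb_pg < 0:
            raise ValueError("known_phb_pg must be >= 0")
        if self.geom_mean_fluorescence <= 0:
            raise ValueError("geom_mean_fluorescence must be > 0")


@dataclass(frozen=True)
class PhbPrediction:
    value_pg: float
    extrapolated: bool = False
    clamped: bool = False

    @property
    def flags(self) -> tuple[str, ...]:
        out = []
        if self.extrapolated:
            out.append("extrapolated")
        if self.clamped:
            out.append("clamped")
        return tuple(out)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted mapping from geometric-mean fluorescence to pg PHB per cell.

    ``fit_domain='log-log'`` (default) fits log10(pg) on log10(fluorescence);
    ``'linear'`` fits pg on fluorescence directly. Both are ordinary least
    squares. The curve must be strictly increasing (slope > 0).
    """

    slope: float
    intercept: float
    fit_domain: str = "log-log"
    r_squared: float = 1.0
    fluorescence_range: tuple[float, float] = (0.0, math.inf)

    def __post_init__(self) -> None:
        if self.fit_domain not in ("linear", "log-log"):
            raise ValueError("fit_domain must be 'linear' or 'log-log'")
        if self.slope <= 0:
            raise ValueError("standard curve must be strictly increasing (slope > 0)")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, fluorescence: float) -> PhbPrediction:
        """Map a geometric-mean fluorescence to pg PHB, with range/clamp flags."""
        f = float(fluorescence)
        if f <= 0:
            raise ValueError("fluorescence must be > 0")
        lo, hi = self.fluorescence_range
        extrapolated = not (lo <= f <= hi)
        if self.fit_domain == "log-log":
            pg = 10.0 ** (self.slope * math.log10(f) + self.intercept)
            clamped = False
        else:
            pg = self.slope * f + self.intercept
            clamped = pg < 0
            if clamped:
                pg = 0.0
        return PhbPrediction(value_pg=pg, extrapolated=extrapolated, clamped=clamped)

    def inverse(self, phb_pg: float) -> float:
        """Fluorescence that maps to the given pg PHB (forward instrument model).

        Used by the synthetic-data generator to place events on the curve.
        """
        pg = float(phb_pg)
        if self.fit_domain == "log-log":
            if pg <= 0:
                raise ValueError("log-log curve defined only for pg > 0")
            return 10.0 ** ((math.log10(pg) - self.intercept) / self.slope)
        f = (pg - self.intercept) / self.slope
        if f <= 0:
            raise ValueError("pg value maps to non-positive fluorescence")
        return f


def fit_standard_curve(
    standards: list[CalibrationStandard], fit_domain: str = "log-log"
) -> StandardCurve:
    """Least-squares standard curve of known pg PHB versus fluorescence.

    Requires at least two standards with distinct fluorescence values.
    In the log-log domain every standard must have strictly positive PHB.
    """
    if fit_domain not in ("linear", "log-log"):
        raise ValueError("fit_domain must be 'linear' or 'log-log'")
    if len(standards) < 2:
        raise UnderdeterminedCurveError("underdetermined-curve: need >= 2 standards")
    f = np.array([s.geom_mean_fluorescence for s in standards], dtype=float)
    pg = np.array([s.known_phb_pg for s in standards], dtype=float)
    if np.allclose(f, f[0]):
        raise UnderdeterminedCurveError(
            "underdetermined-curve: standards share a single fluorescence value"
        )
    if fit_domain == "log-log":
        if np.any(pg <= 0):
            raise ValueError(
                "log-log fit requires known_phb_pg > 0 for every standard; "
                "use fit_domain='linear' or drop zero-PHB standards"
            )
        x, y = np.log10(f), np.log10(pg)
    else:
        x, y = f, pg
    # explicit normal equations (slope/intercept of simple OLS)
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    syy = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 if syy == 0 else max(0.0, 1.0 - float(np.sum(resid**2)) / syy)
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        fit_domain=fit_domain,
        r_squared=min(r2, 1.0),
        fluorescence_range=(float(f.min()), float(f.max())),
    )


def fluorescence_to_phb(geom_mean_fluorescence: float, curve: StandardCurve) -> PhbPrediction:
    """Convert a geometric-mean fluorescence to pg PHB per cell via the curve."""
    return curve.predict(geom_mean_fluorescence)


@dataclass
class NoduleSummary:
    sample_id: str
    mean_phb_pg: float
    n_gated: int
    excluded_fraction: float
    flags: tuple[str, ...] = field(default_factory=tuple)


def nodule_mean_phb(
    events: EventTable, config: GatingConfig, curve: StandardCurve
) -> NoduleSummary:
    """Gate -> geometric mean -> standard curve, for one sample."""
    gated = gate_events(events, config)
    gm = geometric_mean(gated.events.fluorescence)
    pred = fluorescence_to_phb(gm, curve)
    return NoduleSummary(
        sample_id=events.sample_id,
        mean_phb_pg=pred.value_pg,
        n_gated=len(gated.events),
        excluded_fraction=gated.excluded_fraction,
        flags=pred.flags,
    )


def fit_batch_curves(
    standards: pd.DataFrame, fit_domain: str = "log-log"
) -> dict[str, StandardCurve]:
    """One curve per batch_id (standards are rerun with each instrument batch)."""
    required = {"standard_id", "batch_id", "known_phb_pg", "geom_mean_fluorescence"}
    missing = required - set(standards.columns)
    if missing:
        raise ValueError(f"standards table missing columns: {sorted(missing)}")
    curves: dict[str, StandardCurve] = {}
    for batch_id, grp in standards.groupby("batch_id"):
        stds = [
            CalibrationStandard(
                standard_id=str(r.standard_id),
                known_phb_pg=float(r.known_phb_pg),
                geom_mean_fluorescence=float(r.geom_mean_fluorescence),
                batch_id=str(batch_id),
            )
            for r in grp.itertuples()
        ]
        curves[str(batch_id)] = fit_standard_curve(stds, fit_domain=fit_domain)
    return curves


def calibrate_samples(
    events: pd.DataFrame,
    standards: pd.DataFrame,
    config: GatingConfig,
    fit_domain: str = "log-log",
    batch_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Calibrate every sample in a long event table.

    ``events`` has columns sample_id, fluorescence, forward_scatter,
    side_scatter. ``batch_of`` maps sample_id to batch_id (default: the sole
    batch in the standards table).
    """
    curves = fit_batch_curves(standards, fit_domain=fit_domain)
    rows = []
    for sample_id, grp in events.groupby("sample_id", sort=True):
        if batch_of is not None:
            batch = batch_of[str(sample_id)]
        elif len(curves) == 1:
            batch = next(iter(curves))
        else:
            raise ValueError("multiple batches in standards: pass batch_of mapping")
        tab = EventTable.from_frame(grp, sample_id=sample_id)
        summ = nodule_mean_phb(tab, config, curves[batch])
        rows.append(
            {
                "sample_id": summ.sample_id,
                "mean_phb_pg": summ.mean_phb_pg,
                "n_gated": summ.n_gated,
                "excluded_fraction": summ.excluded_fraction,
                "flags": ";".join(summ.flags),
            }
        )
    return pd.DataFrame(rows)
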