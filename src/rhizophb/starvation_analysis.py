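"""Analytics for rhizobial starvation-culture time series.

Starving rhizobia divide asymmetrically, retaining PHB mostly in the
old-pole (parental) cell, so a growing starvation culture develops a bimodal
per-cell PHB distribution: a high-PHB parental subgroup and a low-PHB
daughter subgroup. This module splits calibrated per-cell PHB distributions
into those subgroups, tracks PHB-use rates within the high subgroup (whose
size is assumed constant during starvation), expresses use rates relative to
theoretical state requirements from the survival model, follows relative
population size from CFU counts, and regresses short-term net growth on PHB
use across isolates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .flow_calibration import geometric_mean
from .survival_model import CellParams, daily_phb_requirement

__all__ = [
    "SubgroupSplit",
    "UseRate",
    "RegressionResult",
    "split_phb_subgroups",
    "phb_use_rate",
    "rate_relative_to_state",
    "relative_population",
    "growth_vs_use_regression",
    "use_rate_table",
]

# calibrated pg values at/below this are treated as at the detection floor
# when log-transformed (daughter cells can carry essentially no PHB)
DETECTION_FLOOR_PG = 1e-3


@dataclass(frozen=True)
class SubgroupSplit:
    threshold_pg: float
    frac_high: float
    mean_phb_high: float
    mean_phb_low: float
    bimodality_flag: bool
    n_events: int

    @property
    def frac_low(self) -> float:
        return 1.0 - self.frac_high


def split_phb_subgroups(
    phb_pg,
    method: str = "valley",
    threshold_pg: float | None = None,
    bins: int = 64,
    smooth_sigma: float = 2.0,
    min_prominence_frac: float = 0.05,
    valley_depth_frac: float = 0.5,
    min_subgroup_frac: float = 0.02,
    floor_pg: float = DETECTION_FLOOR_PG,
    summary: str = "geometric",
) -> SubgroupSplit:
    """Split a per-cell PHB distribution into high/low subgroups.

    Default method finds the minimum-density valley between the two most
    prominent modes of a smoothed histogram of log10(pg). A split is accepted
    only if the valley is genuinely low (below ``valley_depth_frac`` of the
    smaller mode) and both subgroups hold at least ``min_subgroup_frac`` of
    events; otherwise the distribution is declared unimodal (bimodality_flag
    False, frac_high 1 by convention). ``method='fixed'`` applies
    ``threshold_pg`` directly, for exact reproduction of a chosen cut.
    """
    v = np.asarray(phb_pg, dtype=float)
    if v.size == 0:
        raise ValueError("empty PHB value array")
    if v.size < 50 and method == "valley":
        raise ValueError("valley method needs >= 50 events")
    logv = np.log10(np.clip(v, floor_pg, None))

    if method == "fixed":
        if threshold_pg is None or threshold_pg <= 0:
            raise ValueError("fixed method requires threshold_pg > 0")
        thr = float(threshold_pg)
        bimodal = True
    elif method == "valley":
        counts, edges = np.histogram(logv, bins=bins)
        dens = ndimage.gaussian_filter1d(counts.astype(float), smooth_sigma)
        # peak detection on a log-compressed axis so a minority mode (e.g. a
        # small parental subgroup among many daughters) is still resolved
        logdens = np.log1p(dens)
        # zero-pad so a mode sitting at the histogram boundary (e.g. all
        # daughter cells at the detection floor) is still a detectable peak
        padded = np.concatenate([[0.0], logdens, [0.0]])
        peaks, _ = signal.find_peaks(
            padded, prominence=min_prominence_frac * logdens.max()
        )
        peaks = peaks - 1
        if peaks.size < 2:
            return _split_summary(v, None, floor_pg, summary)
        top2 = np.sort(peaks[np.argsort(logdens[peaks])[-2:]])
        lo_pk, hi_pk = int(top2[0]), int(top2[1])
        valley = lo_pk + int(np.argmin(dens[lo_pk : hi_pk + 1]))
        if dens[valley] > valley_depth_frac * min(dens[lo_pk], dens[hi_pk]):
            return _split_summary(v, None, floor_pg, summary)
        centers = 0.5 * (edges[:-1] + edges[1:])
        thr = float(10 ** centers[valley])
        frac_high = float(np.mean(v > thr))
        if not min_subgroup_frac <= frac_high <= 1 - min_subgroup_frac:
            return _split_summary(v, None, floor_pg, summary)
        bimodal = True
    else:
        raise ValueError("method must be 'valley' or 'fixed'")
    return _split_summary(v, thr, floor_pg, summary, bimodal=bimodal)


def _subgroup_mean(vals: np.ndarray, floor_pg: float, summary: str) -> float:
    if vals.size == 0:
        return float("nan")
    if summary == "arithmetic":
        return float(vals.mean())
    return geometric_mean(np.clip(vals, floor_pg, None))


def _split_summary(v, thr, floor_pg, summary, bimodal=True) -> SubgroupSplit:
    if thr is None:  # unimodal: everything counts as the high subgroup
        return SubgroupSplit(
            threshold_pg=float("nan"),
            frac_high=1.0,
            mean_phb_high=_subgroup_mean(v, floor_pg, summary),
            mean_phb_low=float("nan"),
            bimodality_flag=False,
            n_events=int(v.size),
        )
    high = v[v > thr]
    low = v[v <= thr]
    return SubgroupSplit(
        threshold_pg=thr,
        frac_high=high.size / v.size,
        mean_phb_high=_subgroup_mean(high, floor_pg, summary),
        mean_phb_low=_subgroup_mean(low, floor_pg, summary),
        bimodality_flag=bimodal,
        n_events=int(v.size),
    )


@dataclass(frozen=True)
class UseRate:
    rate_pg_per_day: float
    accumulation: bool  # True when mean PHB increased over the interval


def phb_use_rate(mean_phb_start: float, mean_phb_end: float, days: float) -> UseRate:
    """(start - end) / days; negative rates flag net accumulation, not error."""
    if days <= 0:
        raise ValueError("days must be > 0")
    rate = (mean_phb_start - mean_phb_end) / days
    return UseRate(rate_pg_per_day=float(rate), accumulation=rate < 0)


def rate_relative_to_state(
    rate_pg_per_day: float,
    temp: float = 26.0,
    state: str = "full_somatic_maintenance",
    cell: CellParams = CellParams(),
) -> float:
    """Observed PHB-use rate as a multiple of a state's theoretical requirement.

    Default reference: full somatic maintenance at 26 deg C (the growth-chamber
    temperature of the source cultures).
    """
    if rate_pg_per_day < 0:
        raise ValueError("rate must be >= 0")
    return rate_pg_per_day / daily_phb_requirement(temp, state, cell)


def use_rate_table(
    days,
    mean_phb_pg,
    temp: float = 26.0,
    cell: CellParams = CellParams(),
) -> pd.DataFrame:
    """Interval PHB-use rates for a high-subgroup time series.

    Returns one row per adjacent sampling interval with the rate in pg/day
    and its ratio to theoretical full-somatic-maintenance and dormancy
    requirements at ``temp``.
    """
    d = np.asarray(days, dtype=float)
    m = np.asarray(mean_phb_pg, dtype=float)
    if d.size != m.size or d.size < 2:
        raise ValueError("need matched day/mean series of length >= 2")
    order = np.argsort(d)
    d, m = d[order], m[order]
    rows = []
    for k in range(d.size - 1):
        ur = phb_use_rate(m[k], m[k + 1], d[k + 1] - d[k])
        nonneg = max(ur.rate_pg_per_day, 0.0)
        rows.append(
            {
                "day_start": d[k],
                "day_end": d[k + 1],
                "rate_pg_per_day": ur.rate_pg_per_day,
                "accumulation": ur.accumulation,
                "relative_to_fsm": rate_relative_to_state(
                    nonneg, temp, "full_somatic_maintenance", cell
                ),
                "relative_to_dormancy": rate_relative_to_state(
                    nonneg, temp, "dormancy", cell
                ),
            }
        )
    return pd.DataFrame(rows)


def relative_population(series: pd.DataFrame) -> pd.DataFrame:
    """Fold change in viable population versus day 0, per day.

    ``series`` columns: replicate_id, day, cfu_per_ml. Each replicate is
    normalised by its own day-0 count, then replicates are combined by
    geometric mean (fold changes are ratios). Invariant to uniform CFU
    rescaling, e.g. dilution factors.
    """
    required = {"replicate_id", "day", "cfu_per_ml"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    folds = []
    for rep, grp in series.groupby("replicate_id"):
        day0 = grp.loc[grp["day"] == 0, "cfu_per_ml"]
        if day0.empty or float(day0.iloc[0]) <= 0:
            raise ValueError(f"replicate {rep!r} lacks a positive day-0 CFU count")
        base = float(day0.iloc[0])
        g = grp[["day"]].copy()
        g["fold"] = grp["cfu_per_ml"] / base
        folds.append(g)
    allf = pd.concat(folds, ignore_index=True)
    out = (
        allf.groupby("day")["fold"]
        .apply(lambda x: geometric_mean(x.to_numpy()))
        .reset_index()
        .rename(columns={"fold": "relative_population"})
    )
    return out


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    df_residual: int
    p_value: float
    n_points: int
    n_excluded: int


def growth_vs_use_regression(
    points: pd.DataFrame, exclude_negative_growth: bool = True
) -> RegressionResult:
    """OLS of net fold growth on PHB used across isolates, with F-test of slope.

    ``points`` columns: phb_used_pg, net_fold_growth (one row per isolate).
    When ``exclude_negative_growth``, isolates whose population shrank
    (fold growth < 1) are dropped before fitting.
    """
    required = {"phb_used_pg", "net_fold_growth"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"points missing columns: {sorted(missing)}")
    df = points.copy()
    n0 = len(df)
    if exclude_negative_growth:
        df = df[df["net_fold_growth"] >= 1.0]
    n = len(df)
    if n < 3:
        raise ValueError("need >= 3 points after exclusions")
    x = df["phb_used_pg"].to_numpy(dtype=float)
    y = df["net_fold_growth"].to_numpy(dtype=float)
    res = stats.linregress(x, y)
    df_resid = n - 2
    if np.isfinite(res.stderr) and res.stderr > 0:
        f_stat = (res.slope / res.stderr) ** 2
        p = float(stats.f.sf(f_stat, 1, df_resid))
    else:  # perfect fit: slope F unbounded, p below machine resolution
        f_stat = float("inf")
        p = 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        f_statistic=float(f_stat),
        df_residual=df_resid,
        p_value=p,
        n_points=n,
        n_excluded=n0 - n,
    )
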