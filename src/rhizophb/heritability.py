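"""Broad-sense heritability of nodule PHB from nested isolate/plant/nodule data.

The phenotype is the mean PHB per cell of a nodule. Nodules are nested in
plants, plants in rhizobial isolates, and apparent broad-sense heritability
is the fraction of total phenotypic variance attributable to isolate
identity:

    H2 = V_isolate / (V_isolate + V_plant + V_residual)

Variance components come from the two-level nested random-effects model
(isolate, plant-within-isolate, residual). For balanced designs the
components are computed from the nested-ANOVA mean squares (the
expected-mean-squares estimator, which coincides with REML at interior
solutions for balanced data); unbalanced designs are fitted by REML via
statsmodels MixedLM. Negative component estimates are truncated to zero and
flagged.

Inference is resampling-based: a plant-level bootstrap (plants resampled
with replacement within isolate, each carrying all its nodules) gives the
bootstrap mean and percentile confidence interval, and a permutation null
(plants randomly reassigned to isolates) gives a p-value with the add-one
convention p = (1 + #{H2_null >= H2_obs}) / (n_perm + 1).

A plant-averaged two-group permutation test (used for contrasts such as
Brilliant-Green-sensitive versus -tolerant nodules) is also provided; it
enumerates all label assignments exactly when feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "H2Estimate",
    "PermutationResult",
    "GroupTestResult",
    "fit_variance_components",
    "broad_sense_h2",
    "bootstrap_h2",
    "permutation_null_h2",
    "plantwise_group_permutation_test",
    "empirical_interval",
]


@dataclass(frozen=True)
class VarianceComponents:
    v_isolate: float
    v_plant: float
    v_residual: float
    truncated: tuple[str, ...] = ()
    method: str = "ems-balanced"
    degenerate: bool = False

    @property
    def total(self) -> float:
        return self.v_isolate + self.v_plant + self.v_residual


@dataclass(frozen=True)
class H2Estimate:
    point: float
    boot_mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_degenerate: int
    seed: int | None


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed: float
    null_q95: float
    n_perm: int
    significant: bool


@dataclass(frozen=True)
class GroupTestResult:
    p_value: float
    statistic: float
    method: str  # 'exact' or 'monte-carlo'
    n_assignments: int


# ---------------------------------------------------------------------------
# balanced-design machinery


def _check_columns(data: pd.DataFrame) -> None:
    required = {"isolate_id", "plant_id", "mean_phb_pg"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"nodule table missing columns: {sorted(missing)}")
    plants = data.groupby("plant_id")["isolate_id"].nunique()
    if (plants > 1).any():
        bad = plants[plants > 1].index.tolist()
        raise ValueError(f"plants mapped to more than one isolate: {bad}")


def _balanced_array(data: pd.DataFrame) -> np.ndarray | None:
    """Return values shaped (isolates, plants, nodules) if the design is balanced."""
    counts = data.groupby(["isolate_id", "plant_id"]).size()
    n_per_plant = counts.unique()
    if len(n_per_plant) != 1:
        return None
    plants_per_iso = counts.groupby("isolate_id").size().unique()
    if len(plants_per_iso) != 1:
        return None
    n = int(n_per_plant[0])
    p = int(plants_per_iso[0])
    ordered = data.sort_values(["isolate_id", "plant_id"], kind="stable")
    i = ordered["isolate_id"].nunique()
    return ordered["mean_phb_pg"].to_numpy(dtype=float).reshape(i, p, n)


def _mean_squares(values: np.ndarray):
    """Stratum mean squares for arrays shaped (..., I, P, N); vectorised.

    Returns (ms_isolate, ms_plant, ms_error) plus the design (i, p, n).
    """
    i, p, n = values.shape[-3:]
    if i < 2:
        raise ValueError("no between-isolate contrast: need >= 2 isolates")
    if p < 2:
        raise ValueError("need >= 2 plants per isolate to separate plant variance")
    plant_means = values.mean(axis=-1)
    iso_means = plant_means.mean(axis=-1)
    grand = iso_means.mean(axis=-1)
    ms_iso = p * n * np.sum((iso_means - grand[..., None]) ** 2, axis=-1) / (i - 1)
    ms_plant = (
        n
        * np.sum((plant_means - iso_means[..., None]) ** 2, axis=(-1, -2))
        / (i * (p - 1))
    )
    if n > 1:
        ms_err = np.sum(
            (values - plant_means[..., None]) ** 2, axis=(-1, -2, -3)
        ) / (i * p * (n - 1))
    else:
        ms_err = np.zeros(np.shape(ms_plant))
    return ms_iso, ms_plant, ms_err, (i, p, n)


def _ems_components(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (possibly negative) expected-mean-squares component estimates."""
    ms_iso, ms_plant, ms_err, (i, p, n) = _mean_squares(values)
    v_res = ms_err
    v_plant = (ms_plant - ms_err) / n
    v_iso = (ms_iso - ms_plant) / (p * n)
    return v_iso, v_plant, v_res


def _reml_balanced(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constrained REML components for balanced nested data; vectorised.

    For a balanced two-level nested design the REML likelihood factors over
    the three independent strata, whose expected mean squares are
    lambda_err = v_res, lambda_plant = v_res + n*v_plant and
    lambda_iso = v_res + n*v_plant + p*n*v_iso with lambda_iso >= lambda_plant
    >= lambda_err. The unconstrained maximisers are the observed mean
    squares; when the ordering is violated the constrained solution pools
    adjacent strata weighted by their degrees of freedom
    (pool-adjacent-violators). At interior solutions this coincides with the
    expected-mean-squares estimator.
    """
    ms_iso, ms_plant, ms_err, (i, p, n) = _mean_squares(values)
    df_iso = float(i - 1)
    df_plant = float(i * (p - 1))
    df_err = float(i * p * (n - 1))
    lam_iso = np.asarray(ms_iso, dtype=float)
    lam_plant = np.asarray(ms_plant, dtype=float)
    lam_err = np.asarray(ms_err, dtype=float)
    if df_err > 0:
        # violation at the bottom: pool plant and error strata
        pool_pe = (df_plant * lam_plant + df_err * lam_err) / (df_plant + df_err)
        low = lam_plant < lam_err
        lam_plant = np.where(low, pool_pe, lam_plant)
        lam_err = np.where(low, pool_pe, lam_err)
    # violation at the top: pool isolate and plant strata
    pool_ip = (df_iso * lam_iso + df_plant * lam_plant) / (df_iso + df_plant)
    high = lam_iso < lam_plant
    lam_iso = np.where(high, pool_ip, lam_iso)
    lam_plant = np.where(high, pool_ip, lam_plant)
    if df_err > 0:
        # top pooling may break the bottom ordering: pool everything
        pool_all = (df_iso * ms_iso + df_plant * ms_plant + df_err * ms_err) / (
            df_iso + df_plant + df_err
        )
        allpool = lam_plant < lam_err
        lam_iso = np.where(allpool, pool_all, lam_iso)
        lam_plant = np.where(allpool, pool_all, lam_plant)
        lam_err = np.where(allpool, pool_all, lam_err)
    v_res = lam_err
    v_plant = (lam_plant - lam_err) / n
    v_iso = (lam_iso - lam_plant) / (p * n)
    return v_iso, v_plant, v_res


def _henderson3_weighted(
    plant_sum: np.ndarray, plant_sumsq: np.ndarray, weights: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Henderson method-III components for plant-weighted resamples; vectorised.

    A bootstrap replicate of a balanced (I, P, N) design re-draws, within each
    isolate, P plants with replacement; a plant drawn w times re-enters the
    fit under its original identity, i.e. as one plant whose N nodules appear
    w times. The replicate is therefore an unbalanced nested design fully
    described by per-plant sufficient statistics (sum, sum of squares) and
    integer weights, and the quadratic-form (Henderson III) component
    estimators have a closed form in those quantities. For the unit-weight
    replicate this reduces to the balanced ANOVA estimator.

    ``plant_sum``/``plant_sumsq``: (I, P); ``weights``: (..., I, P) with each
    isolate's weights summing to P. Returns raw (possibly negative)
    v_isolate, v_plant, v_residual with the leading shape of ``weights``.
    """
    i, p = plant_sum.shape
    w = weights.astype(float)
    n_tot = i * p * n
    n_iso = p * n  # per-isolate observation count is preserved by resampling
    t0 = np.sum(w * plant_sumsq, axis=(-1, -2))
    tp = np.sum(w * plant_sum**2 / n, axis=(-1, -2))
    iso_tot = np.sum(w * plant_sum, axis=-1)
    ta = np.sum(iso_tot**2 / n_iso, axis=-1)
    tmu = np.sum(iso_tot, axis=-1) ** 2 / n_tot
    ss_err = t0 - tp
    ss_plant = tp - ta
    ss_iso = ta - tmu
    p_unique = np.sum(w > 0, axis=(-1, -2))
    ww2 = np.sum(w**2, axis=(-1, -2))
    sum_k = n / p * ww2         # sum_i sum_j n_ij^2 / n_i.
    k_all = n / (i * p) * ww2   # sum_ij n_ij^2 / n_tot
    c_iso = n_tot - i * n_iso**2 / n_tot  # = p*n*(i-1)
    df_err = n_tot - p_unique
    df_plant = p_unique - i
    v_res = ss_err / np.maximum(df_err, 1)
    denom_plant = n_tot - sum_k
    with np.errstate(invalid="ignore", divide="ignore"):
        v_plant = np.where(
            denom_plant > 0,
            (ss_plant - df_plant * v_res) / np.where(denom_plant > 0, denom_plant, 1.0),
            np.nan,
        )
    v_iso = (ss_iso - (i - 1) * v_res - (sum_k - k_all) * v_plant) / c_iso
    return v_iso, v_plant, v_res


def _reml_components(data: pd.DataFrame) -> VarianceComponents:
    import warnings

    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = data.copy()
    df["plant_id"] = df["plant_id"].astype(str)
    md = smf.mixedlm(
        "mean_phb_pg ~ 1",
        data=df,
        groups=df["isolate_id"],
        re_formula="1",
        vc_formula={"plant": "0 + C(plant_id)"},
    )
    with warnings.catch_warnings():
        # boundary (zero-variance) solutions are legitimate here
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = md.fit(reml=True)
    v_iso = float(np.asarray(res.cov_re)[0, 0])
    v_plant = float(np.asarray(res.vcomp).ravel()[0])
    v_res = float(res.scale)
    return VarianceComponents(
        v_isolate=max(v_iso, 0.0),
        v_plant=max(v_plant, 0.0),
        v_residual=max(v_res, 0.0),
        truncated=(),
        method="reml-mixedlm",
    )


def fit_variance_components(
    data: pd.DataFrame, method: str = "auto"
) -> VarianceComponents:
    """Estimate (v_isolate, v_plant, v_residual) from a nodule table.

    ``data`` columns: isolate_id, plant_id, mean_phb_pg. ``method`` is
    'auto' (balanced closed form when possible, else REML), 'ems' (balanced
    only) or 'reml'.
    """
    _check_columns(data)
    if data["isolate_id"].nunique() < 2:
        raise ValueError("no between-isolate contrast: need >= 2 isolates")
    values = data["mean_phb_pg"].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return VarianceComponents(0.0, 0.0, 0.0, degenerate=True)
    if method not in ("auto", "ems", "reml"):
        raise ValueError("method must be 'auto', 'ems' or 'reml'")
    arr = _balanced_array(data) if method in ("auto", "ems") else None
    if arr is None:
        if method == "ems":
            raise ValueError("method='ems' requires a balanced design")
        return _reml_components(data)
    raw = _ems_components(arr)
    truncated = tuple(
        name
        for name, v in zip(("v_isolate", "v_plant", "v_residual"), raw)
        if float(v) < 0
    )
    v_iso, v_plant, v_res = (max(float(x), 0.0) for x in _reml_balanced(arr))
    return VarianceComponents(
        v_isolate=v_iso,
        v_plant=v_plant,
        v_residual=v_res,
        truncated=truncated,
        method="reml-balanced",
    )


def broad_sense_h2(components: VarianceComponents) -> float:
    """V_isolate over total phenotypic variance; NaN when all components are 0."""
    total = components.total
    if total <= 0:
        return float("nan")
    return components.v_isolate / total


def _h2_from_arrays(v_iso, v_plant, v_res):
    """Truncated-ratio H2 for vectorised component arrays; NaN where degenerate."""
    v_iso = np.maximum(v_iso, 0.0)
    v_plant = np.maximum(v_plant, 0.0)
    v_res = np.maximum(v_res, 0.0)
    total = v_iso + v_plant + v_res
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(total > 0, v_iso / np.where(total > 0, total, 1.0), np.nan)
    return h2


def _point_h2(data: pd.DataFrame, method: str) -> float:
    return broad_sense_h2(fit_variance_components(data, method=method))


def bootstrap_h2(
    data: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> H2Estimate:
    """Plant-resampling bootstrap for H2 (percentile 95% CI).

    Each replicate resamples plants with replacement *within* isolate, a
    resampled plant carrying all its nodules, so the isolate panel is fixed
    and the estimand unchanged. A plant drawn more than once re-enters the
    fit under its original plant identity (its nodules appear with
    multiplicity), which keeps the plant-level variance from being
    spuriously deflated by duplicate "new" plants and leaves the bootstrap
    mean centred on the estimate (see docs/methods.md). Replicates whose
    components are all zero or unidentifiable are recorded as degenerate and
    dropped from the summaries.
    """
    _check_columns(data)
    point = _point_h2(data, method)
    rng = np.random.default_rng(seed)
    arr = _balanced_array(data)
    if arr is not None:
        i, p, n = arr.shape
        draws = rng.integers(0, p, size=(n_boot, i, p))
        weights = (draws[..., None] == np.arange(p)).sum(axis=-2)  # (n_boot, i, p)
        h2 = _h2_from_arrays(
            *_henderson3_weighted(arr.sum(-1), (arr**2).sum(-1), weights, n)
        )
    else:
        h2 = np.empty(n_boot)
        plants_by_iso = {
            iso: [g for _, g in grp.groupby("plant_id")]
            for iso, grp in data.groupby("isolate_id")
        }
        for b in range(n_boot):
            parts = []
            for iso, plants in plants_by_iso.items():
                take = rng.integers(0, len(plants), size=len(plants))
                # duplicates keep their plant_id and simply stack rows
                parts.extend(plants[t] for t in take)
            try:
                h2[b] = _point_h2(pd.concat(parts, ignore_index=True), "reml")
            except ValueError:
                h2[b] = np.nan
    ok = h2[np.isfinite(h2)]
    n_degenerate = int(n_boot - ok.size)
    if ok.size == 0:
        return H2Estimate(point, float("nan"), float("nan"), float("nan"),
                          n_boot, n_degenerate, seed)
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return H2Estimate(
        point=point,
        boot_mean=float(ok.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_degenerate=n_degenerate,
        seed=seed,
    )


def permutation_null_h2(
    data: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Permutation null for H2: plants randomly reassigned to isolates.

    Plants keep their nodules; only the plant-to-isolate assignment is
    shuffled. Significance follows the 95th-percentile rejection rule; the
    reported p uses the add-one convention.
    """
    _check_columns(data)
    observed = _point_h2(data, method)
    rng = np.random.default_rng(seed)
    if not np.isfinite(observed):  # degenerate data: nothing to detect
        return PermutationResult(1.0, observed, float("nan"), n_perm, False)
    arr = _balanced_array(data)
    if arr is not None:
        i, p, n = arr.shape
        slabs = arr.reshape(i * p, n)
        keys = rng.random((n_perm, i * p))
        order = np.argsort(keys, axis=1)
        shuffled = slabs[order].reshape(n_perm, i, p, n)
        null = _h2_from_arrays(*_reml_balanced(shuffled))
    else:
        plant_groups = [g for _, g in data.groupby("plant_id")]
        labels = np.array(
            [g["isolate_id"].iloc[0] for g in plant_groups], dtype=object
        )
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(labels)
            parts = []
            for g, lab in zip(plant_groups, perm):
                part = g.copy()
                part["isolate_id"] = lab
                parts.append(part)
            try:
                null[b] = _point_h2(pd.concat(parts, ignore_index=True), method)
            except ValueError:
                null[b] = np.nan
    exceed = int(np.sum(null[np.isfinite(null)] >= observed))
    p = (1 + exceed) / (n_perm + 1)
    q95 = float(np.nanpercentile(null, 95)) if np.isfinite(null).any() else float("nan")
    return PermutationResult(
        p_value=p,
        observed=observed,
        null_q95=q95,
        n_perm=n_perm,
        significant=bool(observed > q95),
    )


# ---------------------------------------------------------------------------
# plant-averaged two-group permutation test


def plantwise_group_permutation_test(
    values: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    max_exact: int = 100_000,
) -> GroupTestResult:
    """Two-sided permutation test on plant-level group means.

    ``values`` columns: plant_id, group, value (pg per cell). Multiple nodules
    of the same group on one plant are averaged first (to avoid
    pseudoreplication), giving one record per plant x group. The statistic is
    the difference of group means of these plant-level values. All label
    assignments are enumerated exactly when their number is at most
    ``max_exact``; otherwise Monte-Carlo with the add-one correction.
    """
    required = {"plant_id", "group", "value"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"group table missing columns: {sorted(missing)}")
    plant_means = (
        values.groupby(["group", "plant_id"])["value"].mean().reset_index()
    )
    groups = plant_means["group"].unique()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    g1 = plant_means.loc[plant_means["group"] == groups[0], "value"].to_numpy()
    g2 = plant_means.loc[plant_means["group"] == groups[1], "value"].to_numpy()
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs >= 2 plant-level values")
    pooled = np.concatenate([g1, g2])
    n, n1 = pooled.size, g1.size
    obs = abs(g1.mean() - g2.mean())
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))

    n_total = math.comb(n, n1)
    if n_total <= max_exact:
        total = pooled.sum()
        count = 0
        for idx in combinations(range(n), n1):
            s1 = pooled[list(idx)].sum()
            stat = abs(s1 / n1 - (total - s1) / (n - n1))
            if stat >= obs - tol:
                count += 1
        return GroupTestResult(
            p_value=count / n_total,
            statistic=float(g1.mean() - g2.mean()),
            method="exact",
            n_assignments=n_total,
        )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n1].mean() - perm[n1:].mean())
        if stat >= obs - tol:
            count += 1
    return GroupTestResult(
        p_value=(1 + count) / (n_perm + 1),
        statistic=float(g1.mean() - g2.mean()),
        method="monte-carlo",
        n_assignments=n_perm,
    )


def empirical_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Central empirical percentile interval (linear-interpolation quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(v, [tail, 100 - tail])
    return float(lo), float(hi)
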