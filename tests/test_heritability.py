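"""Variance components, broad-sense heritability and resampling inference."""

import numpy as np
import pandas as pd
import pytest

from rhizophb.heritability import (
    VarianceComponents,
    bootstrap_h2,
    broad_sense_h2,
    empirical_interval,
    fit_variance_components,
    permutation_null_h2,
    plantwise_group_permutation_test,
)
from rhizophb.synthetic_data import NoduleStudyDesign, simulate_nodule_study


def nodule_frame(values):
    """values: array (I, P, N) -> long table."""
    values = np.asarray(values, dtype=float)
    i, p, n = values.shape
    rows = []
    for a in range(i):
        for b in range(p):
            for c in range(n):
                rows.append(
                    {
                        "isolate_id": f"i{a}",
                        "plant_id": f"i{a}p{b}",
                        "mean_phb_pg": values[a, b, c],
                    }
                )
    return pd.DataFrame(rows)


def ems_oracle(values):
    """Naive-loop expected-mean-squares estimator (balanced designs only)."""
    values = np.asarray(values, dtype=float)
    i, p, n = values.shape
    grand = values.mean()
    ss_iso = ss_plant = ss_err = 0.0
    for a in range(i):
        iso_mean = values[a].mean()
        ss_iso += p * n * (iso_mean - grand) ** 2
        for b in range(p):
            pm = values[a, b].mean()
            ss_plant += n * (pm - iso_mean) ** 2
            for c in range(n):
                ss_err += (values[a, b, c] - pm) ** 2
    ms_iso = ss_iso / (i - 1)
    ms_plant = ss_plant / (i * (p - 1))
    ms_err = ss_err / (i * p * (n - 1))
    return (
        (ms_iso - ms_plant) / (p * n),
        (ms_plant - ms_err) / n,
        ms_err,
    )


class TestVarianceComponents:
    def test_pure_isolate_signal(self):
        vals = np.zeros((3, 2, 2))
        vals[0], vals[1], vals[2] = 1.0, 2.0, 3.0
        comp = fit_variance_components(nodule_frame(vals))
        assert comp.v_plant == 0.0 and comp.v_residual == 0.0
        assert comp.v_isolate == pytest.approx(np.var([1, 2, 3], ddof=1), rel=1e-12)

    def test_matches_naive_ems_oracle_on_balanced_data(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            vals = (
                0.5
                + rng.normal(0, 0.4, (8, 1, 1))
                + rng.normal(0, 0.2, (8, 3, 1))
                + rng.normal(0, 0.2, (8, 3, 3))
            )
            comp = fit_variance_components(nodule_frame(vals))
            oi, op, oe = ems_oracle(vals)
            if min(oi, op, oe) > 0:  # interior solution: REML == EMS
                assert comp.v_isolate == pytest.approx(oi, abs=1e-10)
                assert comp.v_plant == pytest.approx(op, abs=1e-10)
                assert comp.v_residual == pytest.approx(oe, abs=1e-10)

    def test_balanced_path_agrees_with_mixedlm_reml(self):
        df = simulate_nodule_study(
            NoduleStudyDesign(n_isolates=10, grand_mean_pg=1.0, total_sd_pg=0.3,
                              skew="normal", seed=12)
        )
        fast = fit_variance_components(df, method="auto")
        slow = fit_variance_components(df, method="reml")
        assert fast.v_isolate == pytest.approx(slow.v_isolate, rel=1e-3, abs=1e-6)
        assert fast.v_plant == pytest.approx(slow.v_plant, rel=1e-3, abs=1e-6)
        assert fast.v_residual == pytest.approx(slow.v_residual, rel=1e-3, abs=1e-6)

    def test_negative_isolate_component_truncated_and_flagged(self):
        # isolate means identical, plant means wildly different: EMS v_iso < 0
        vals = np.array(
            [[[0.0, 0.0], [10.0, 10.0]], [[10.0, 10.0], [0.0, 0.0]]]
        )
        comp = fit_variance_components(nodule_frame(vals))
        assert comp.v_isolate == 0.0
        assert "v_isolate" in comp.truncated

    def test_single_isolate_rejected(self):
        vals = np.ones((1, 3, 3)) + np.arange(9).reshape(1, 3, 3)
        with pytest.raises(ValueError, match="isolate"):
            fit_variance_components(nodule_frame(vals))

    def test_identical_values_degenerate(self):
        comp = fit_variance_components(nodule_frame(np.full((3, 2, 2), 0.7)))
        assert comp.degenerate
        assert comp.total == 0.0


class TestBroadSenseH2:
    @pytest.mark.parametrize(
        "comps, expected",
        [((1, 0, 0), 1.0), ((0, 1, 1), 0.0), ((2, 1, 1), 0.5)],
    )
    def test_ratio_arithmetic(self, comps, expected):
        assert broad_sense_h2(VarianceComponents(*comps)) == pytest.approx(expected)

    def test_all_zero_is_nan(self):
        assert np.isnan(broad_sense_h2(VarianceComponents(0, 0, 0)))


class TestBootstrap:
    def test_same_seed_gives_identical_results(self):
        df = simulate_nodule_study(NoduleStudyDesign(seed=5))
        a = bootstrap_h2(df, n_boot=300, seed=17)
        b = bootstrap_h2(df, n_boot=300, seed=17)
        assert a == b

    def test_constant_data_fully_degenerate(self):
        df = nodule_frame(np.full((4, 3, 3), 1.0))
        est = bootstrap_h2(df, n_boot=50, seed=0)
        assert est.n_degenerate == 50
        assert np.isnan(est.boot_mean)

    def test_ci_brackets_boot_mean(self):
        df = simulate_nodule_study(
            NoduleStudyDesign(grand_mean_pg=1.0, total_sd_pg=0.3, skew="normal", seed=8)
        )
        est = bootstrap_h2(df, n_boot=500, seed=2)
        assert est.ci_low <= est.boot_mean <= est.ci_high
        assert 0.0 <= est.ci_low and est.ci_high <= 1.0

    def test_scale_invariance(self):
        df = simulate_nodule_study(
            NoduleStudyDesign(grand_mean_pg=1.0, total_sd_pg=0.3, skew="normal", seed=9)
        )
        scaled = df.assign(mean_phb_pg=df["mean_phb_pg"] * 37.5)
        a = bootstrap_h2(df, n_boot=400, seed=3)
        b = bootstrap_h2(scaled, n_boot=400, seed=3)
        assert b.point == pytest.approx(a.point, rel=1e-9)
        assert b.boot_mean == pytest.approx(a.boot_mean, rel=1e-9)
        assert b.ci_low == pytest.approx(a.ci_low, rel=1e-9)
        assert b.ci_high == pytest.approx(a.ci_high, rel=1e-9)

    def test_unbalanced_fallback_runs(self):
        df = simulate_nodule_study(
            NoduleStudyDesign(n_isolates=4, grand_mean_pg=1.0, total_sd_pg=0.3,
                              skew="normal", seed=10)
        )
        df = df.iloc[:-2]  # drop two nodules: unbalanced
        est = bootstrap_h2(df, n_boot=8, seed=1)
        assert est.n_boot == 8
        assert 0 <= est.point <= 1


class TestPermutationNull:
    def test_identical_values_give_p_one(self):
        df = nodule_frame(np.full((4, 3, 3), 2.0))
        res = permutation_null_h2(df, n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_overwhelming_isolate_effect_gives_minimal_p(self):
        rng = np.random.default_rng(0)
        vals = 100.0 * np.arange(6)[:, None, None] + rng.normal(0, 0.1, (6, 3, 3))
        res = permutation_null_h2(nodule_frame(vals), n_perm=200, seed=1)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.significant

    def test_scale_invariance_of_p(self):
        df = simulate_nodule_study(
            NoduleStudyDesign(grand_mean_pg=1.0, total_sd_pg=0.3, skew="normal", seed=6)
        )
        a = permutation_null_h2(df, n_perm=300, seed=4)
        b = permutation_null_h2(
            df.assign(mean_phb_pg=df["mean_phb_pg"] * 5.0), n_perm=300, seed=4
        )
        assert a.p_value == b.p_value


class TestGroupPermutationTest:
    @staticmethod
    def frame(g1, g2):
        rows = [
            {"plant_id": f"a{i}", "group": "BG_sensitive", "value": v}
            for i, v in enumerate(g1)
        ] + [
            {"plant_id": f"b{i}", "group": "BG_tolerant", "value": v}
            for i, v in enumerate(g2)
        ]
        return pd.DataFrame(rows)

    def test_exact_enumeration_worked_example(self):
        res = plantwise_group_permutation_test(self.frame([1, 2], [10, 11]))
        assert res.method == "exact"
        assert res.n_assignments == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_groups_give_p_one(self):
        res = plantwise_group_permutation_test(self.frame([1, 2, 3], [3, 1, 2]))
        assert res.p_value == 1.0

    def test_monte_carlo_matches_exact_within_binomial_error(self):
        g1, g2 = [0.1, 0.4, 0.9, 0.2], [0.5, 1.1, 0.8, 1.4]
        exact = plantwise_group_permutation_test(self.frame(g1, g2))
        mc = plantwise_group_permutation_test(
            self.frame(g1, g2), n_perm=4000, seed=9, max_exact=1
        )
        p = exact.p_value
        assert abs(mc.p_value - p) < 3 * np.sqrt(p * (1 - p) / 4000) + 1e-3

    def test_plant_averaging_collapses_pseudoreplicates(self):
        df = self.frame([1, 2], [10, 11])
        dup = pd.concat(
            [df, pd.DataFrame([{"plant_id": "a0", "group": "BG_sensitive",
                                "value": 1.0}])],
            ignore_index=True,
        )
        assert plantwise_group_permutation_test(dup).p_value == pytest.approx(2 / 6)

    def test_input_order_invariance(self):
        df = self.frame([0.3, 0.7, 0.2], [1.0, 0.9, 1.4])
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = plantwise_group_permutation_test(df, n_perm=500, seed=7, max_exact=1)
        b = plantwise_group_permutation_test(shuffled, n_perm=500, seed=7, max_exact=1)
        assert a.p_value == b.p_value


class TestEmpiricalInterval:
    def test_constant_vector(self):
        assert empirical_interval([3.3, 3.3, 3.3]) == (3.3, 3.3)

    def test_linear_interpolation_quantiles(self):
        lo, hi = empirical_interval(np.arange(1, 1001))
        assert lo == pytest.approx(25.975)
        assert hi == pytest.approx(975.025)

    def test_focal_interval_wider_than_reference_on_split_root_data(self):
        rng = np.random.default_rng(11)
        reference = 0.4 + rng.normal(0, 0.05, 200)  # environment + error only
        iso_effects = rng.normal(0, 0.25, 20)
        focal = 0.4 + np.repeat(iso_effects, 10) + rng.normal(0, 0.05, 200)
        ref_lo, ref_hi = empirical_interval(reference)
        foc_lo, foc_hi = empirical_interval(focal)
        assert (foc_hi - foc_lo) > (ref_hi - ref_lo)
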