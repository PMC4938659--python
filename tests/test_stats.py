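"""Statistical battery: ANOVA, trends, t-test battery, variance and stress tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from picoma import (
    classify_lines,
    control_drift_anova,
    holm_adjust,
    per_line_trend,
    st_significance_battery,
    stress_confirmation,
    variance_ratio_test,
)
from picoma.simulate import simulate_stress_assay


def _control_frame(groups):
    rows = []
    for bn, values in enumerate(groups, start=1):
        for i, g in enumerate(values):
            rows.append(dict(bottleneck=bn, replicate=f"c{i}", g=float(g)))
    return pd.DataFrame(rows)


class TestControlDriftAnova:
    def test_identical_constant_groups(self):
        f, p = control_drift_anova(_control_frame([[2, 2, 2], [2, 2, 2]]))
        assert (f, p) == (0.0, 1.0)

    def test_hand_computed_fixture(self):
        # groups {1,2,3} and {4,5,6}: SS_between 13.5, SS_within 4, df (1,4)
        f, p = control_drift_anova(_control_frame([[1, 2, 3], [4, 5, 6]]))
        assert f == pytest.approx(13.5, rel=1e-12)
        assert p == pytest.approx(float(sps.f.sf(13.5, 1, 4)), rel=1e-12)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(2.0, 0.1, size=6) for _ in range(4)]
        f, p = control_drift_anova(_control_frame(groups))
        ref = sps.f_oneway(*groups)
        assert f == pytest.approx(float(ref.statistic), rel=1e-10)
        assert p == pytest.approx(float(ref.pvalue), rel=1e-10)

    def test_degenerate_within_variance_is_error(self):
        with pytest.raises(ValueError):
            control_drift_anova(_control_frame([[1, 1, 1], [2, 2, 2]]))

    def test_p_uniform_under_null(self):
        """Null p-values are uniform (KS over 1000 simulated experiments)."""
        rng = np.random.default_rng(17)
        p_values = [
            control_drift_anova(
                _control_frame([rng.normal(2, 0.1, 5) for _ in range(4)])
            )[1]
            for _ in range(1000)
        ]
        assert sps.kstest(p_values, "uniform").pvalue > 0.01


class TestTrend:
    def test_strictly_decreasing_series(self):
        res = per_line_trend([10, 20, 30, 40], [1.0, 0.9, 0.8, 0.7], "L1")
        assert res.rho == pytest.approx(-1.0)
        assert not res.undefined

    def test_constant_series_flagged_undefined(self):
        res = per_line_trend([10, 20, 30], [1.0, 1.0, 1.0], "L1")
        assert res.undefined and math.isnan(res.rho)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            per_line_trend([1, 2], [1.0, 0.9])

    def test_simulated_deleterious_pressure_recovered(self):
        """A line under steady per-generation decline shows negative rho."""
        rng = np.random.default_rng(3)
        generations = np.arange(14, 14 * 22, 14, dtype=float)
        g_r = 1.0 - 0.004 * generations / 14 + rng.normal(0, 0.01, generations.size)
        res = per_line_trend(generations, g_r, "sim")
        assert res.rho < 0
        assert res.p_value < 0.05


class TestHolm:
    def test_analytic_step_down(self):
        adjusted = holm_adjust([0.01, 0.02, 0.04])
        assert np.allclose(adjusted, [0.03, 0.04, 0.04])

    def test_adjusted_at_least_raw_and_single_family(self):
        raw = np.array([0.04, 0.001, 0.2, 0.03])
        adjusted = holm_adjust(raw)
        assert np.all(adjusted >= raw)
        assert holm_adjust([0.03])[0] == pytest.approx(0.03)


def _assay_from_growth(growth: dict, inoculum=50_000.0, days=7.0) -> pd.DataFrame:
    """Build an assay table from per-(condition, line) replicate G values."""
    rows = []
    for (condition, line_id), g_values in growth.items():
        for i, g in enumerate(g_values):
            rows.append(
                dict(condition=condition, line_id=line_id, replicate=f"r{i}",
                     cells=inoculum * float(g) ** days,
                     is_control=line_id == "control")
            )
    return pd.DataFrame(rows)


class TestSTBattery:
    def test_identical_groups_not_significant(self):
        assay = _assay_from_growth(
            {("std", "control"): [1.9, 2.0, 2.1], ("std", "A"): [1.9, 2.0, 2.1]}
        )
        res = st_significance_battery(assay)
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)
        assert not res.loc[0, "significant"]

    def test_planted_shifts_flagged_exactly(self):
        """Exactly the 3 of 8 lines with a 5-SD growth shift are flagged."""
        rng = np.random.default_rng(21)
        sd = 0.01
        growth = {("std", "control"): rng.normal(2.0, sd, 6)}
        shifted = {"L2", "L5", "L7"}
        for i in range(8):
            line = f"L{i + 1}"
            mean = 2.0 - 5 * sd if line in shifted else 2.0
            growth[("std", line)] = rng.normal(mean, sd, 6)
        res = st_significance_battery(_assay_from_growth(growth), alpha=0.01)
        flagged = set(res.loc[res["significant"], "line_id"])
        assert flagged == shifted
        assert (res.loc[res["line_id"].isin(shifted), "s_t"] < 0).all()

    def test_single_replicate_comparison_skipped(self):
        assay = _assay_from_growth(
            {("std", "control"): [2.0, 2.1, 1.9], ("std", "A"): [1.5]}
        )
        with pytest.warns(UserWarning, match="<2 replicates"):
            res = st_significance_battery(assay)
        assert res.empty

    def test_invariant_to_replicate_ordering(self):
        rng = np.random.default_rng(9)
        growth = {("std", "control"): rng.normal(2, 0.02, 4),
                  ("std", "A"): rng.normal(1.95, 0.02, 3),
                  ("std", "B"): rng.normal(2.05, 0.02, 3)}
        assay = _assay_from_growth(growth)
        shuffled = assay.sample(frac=1.0, random_state=1).reset_index(drop=True)
        left = st_significance_battery(assay)
        right = st_significance_battery(shuffled)
        pd.testing.assert_frame_equal(left, right)

    def test_global_family_is_more_conservative(self):
        rng = np.random.default_rng(2)
        growth = {}
        for cond in ["a", "b"]:
            growth[(cond, "control")] = rng.normal(2, 0.02, 4)
            for i in range(4):
                growth[(cond, f"L{i}")] = rng.normal(1.97, 0.02, 3)
        assay = _assay_from_growth(growth)
        per_cond = st_significance_battery(assay, family="condition")
        global_fam = st_significance_battery(assay, family="global")
        assert (global_fam["p_adjusted"] >= per_cond["p_adjusted"] - 1e-12).all()


class TestVarianceRatio:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = variance_ratio_test(x, x)
        assert res.f_statistic == 1.0
        assert res.p_value == 1.0

    def test_fourfold_variance(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0, 1, 10)
        y = (y - y.mean()) / y.std(ddof=1)  # sample variance exactly 1
        x = 2.0 * y  # sample variance exactly 4
        res = variance_ratio_test(x, y)
        assert res.f_statistic == pytest.approx(4.0, rel=1e-12)
        expected = 2 * float(sps.f.sf(4.0, 9, 9))
        assert res.p_value == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(0.0510, abs=5e-4)

    def test_zero_reference_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_ratio_test([1.0, 2.0], [3.0, 3.0])

    def test_condition_specific_dispersion_detected(self):
        """Stress-only effect dispersion inflates S_T variance under stress."""
        from picoma import ExperimentDesign, GxE, SimulationParams
        from picoma.simulate import Mutation, simulate_ma_experiment

        params = SimulationParams(
            design=ExperimentDesign(n_lines=12, n_bottlenecks=2),
            gxe=GxE(conditions=("standard", "stress")),
            count_noise_cv=0.02,
            seed=31,
        )
        experiment = simulate_ma_experiment(params)
        rng = np.random.default_rng(13)
        for line_id in experiment.surviving_lines:
            stress_effect = float(np.exp(rng.normal(0.0, 0.15)))
            experiment.mutations[line_id].append(
                Mutation("deleterious", 1.0,
                         {"standard": 1.0, "stress": stress_effect})
            )
        assay = simulate_stress_assay(experiment, ["standard", "stress"])
        res = st_significance_battery(assay)
        by_cond = {c: g["s_t"].to_numpy() for c, g in res.groupby("condition")}
        out = variance_ratio_test(by_cond["stress"], by_cond["standard"],
                                  "stress", "standard")
        assert out.f_statistic > 1.0
        assert out.p_value < 0.05


class TestStressConfirmation:
    def test_halved_growth(self):
        std = [2.0, 2.1, 1.9, 2.0]
        cond = [g / 2 for g in std]
        res = stress_confirmation(std, cond)
        assert res.growth_reduction_percent == pytest.approx(50.0)
        assert res.stressful

    def test_identical_groups_not_stressful(self):
        res = stress_confirmation([1.9, 2.0, 2.1], [1.9, 2.0, 2.1])
        assert not res.stressful

    def test_faster_condition_not_stressful(self):
        # low salinity can speed growth: significant but not a stress
        std = [2.00, 2.01, 1.99, 2.00, 2.02, 1.98]
        cond = [2.30, 2.31, 2.29, 2.30, 2.32, 2.28]
        res = stress_confirmation(std, cond)
        assert res.p_value < 0.05
        assert not res.stressful
        assert res.growth_reduction_percent < 0

    def test_all_tied_flagged_undefined(self):
        res = stress_confirmation([2.0, 2.0], [2.0, 2.0])
        assert res.undefined and math.isnan(res.p_value)


class TestClassifyLines:
    def test_no_significant_results(self):
        res = pd.DataFrame(
            {"line_id": ["A"], "condition": ["std"], "s_t": [0.01],
             "significant": [False]}
        )
        out = classify_lines(res)
        assert out.loc[0, ["n_negative", "n_positive"]].tolist() == [0, 0]
        assert out.loc[0, "n_nonsignificant"] == 1

    def test_line_counted_in_both_directions(self):
        res = pd.DataFrame(
            {"line_id": ["A", "A"], "condition": ["x", "y"],
             "s_t": [-0.1, 0.2], "significant": [True, True]}
        )
        out = classify_lines(res)
        assert out.loc[0, "n_negative"] == 1
        assert out.loc[0, "n_positive"] == 1

    def test_planted_effects_classified(self, planted_experiment):
        """Injected 2-negative / 1-positive structure is recovered."""
        experiment, _ = planted_experiment
        assay = simulate_stress_assay(experiment, ["standard", "stress"])
        res = st_significance_battery(assay)
        out = classify_lines(res).set_index("line_id")
        negative_lines = set(out.index[out["n_negative"] > 0])
        positive_lines = set(out.index[out["n_positive"] > 0])
        assert {"L001", "L003"} <= negative_lines
        assert "L002" in positive_lines
        # the three clean lines show no significant effect anywhere
        for line in ["L004", "L005", "L006"]:
            assert out.loc[line, ["n_negative", "n_positive"]].sum() == 0
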