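"""WTA ratios, Krinsky-Robb CIs, relative importance, CV and net benefit."""

import numpy as np
import pytest

from dcevalue import (
    UndefinedWTAError,
    compensating_variation,
    krinsky_robb_ci,
    marginal_wta,
    net_benefit,
    relative_importance,
    result_from_table,
    scenario_utility,
    scenario_valuation,
    total_scenario_wta,
)
from dcevalue.welfare import CovarianceError, UndefinedImportanceError, round_euro

# every published WTA cell: (group, level, WTA in euro per year)
PUBLISHED_WTA = [
    ("all", "pharmacy_model:office_15min_q3m", 275.50),
    ("all", "pharmacy_model:office_30min_q6m", 444.00),
    ("all", "integration:partial", 188.00),
    ("all", "integration:full", 311.00),
    ("all", "waiting_time:48h_30d", 190.50),
    ("all", "waiting_time:same_day_15d", 575.00),
    ("intervention", "pharmacy_model:office_15min_q3m", 201.67),
    ("intervention", "pharmacy_model:office_30min_q6m", 316.00),
    ("intervention", "integration:partial", 139.00),
    ("intervention", "integration:full", 211.33),
    ("intervention", "waiting_time:48h_30d", 89.00),
    ("intervention", "waiting_time:same_day_15d", 349.67),
    ("control", "pharmacy_model:office_15min_q3m", 481.00),
    ("control", "pharmacy_model:office_30min_q6m", 792.00),
    ("control", "integration:partial", 308.00),
    ("control", "integration:full", 617.00),
    ("control", "waiting_time:48h_30d", 585.00),
    ("control", "waiting_time:same_day_15d", 1349.00),
]


@pytest.fixture(scope="module")
def results(fx):
    return {g: result_from_table(t, fx.lr_chi2[g]) for g, t in fx.coefficients.items()}


class TestMarginalWTA:
    @pytest.mark.parametrize("group,level,expected", PUBLISHED_WTA)
    def test_published_wta_cells(self, results, group, level, expected):
        est = marginal_wta(results[group], level)
        assert round_euro(est.wta) == pytest.approx(expected, abs=0.01)

    def test_zero_coefficient_gives_zero_wta(self, make_result):
        res = make_result(["a", "cost"], [0.0, 0.5])
        assert marginal_wta(res, "a").wta == 0.0

    def test_zero_cost_coefficient_raises(self, make_result):
        res = make_result(["a", "cost"], [1.0, 0.0])
        with pytest.raises(UndefinedWTAError):
            marginal_wta(res, "a")

    def test_insignificant_cost_flagged(self, results):
        est = marginal_wta(results["intervention"], "integration:full")
        assert est.warning is not None and "not statistically significant" in est.warning

    def test_negate_flag_flips_sign(self, make_result):
        res = make_result(["a", "cost"], [1.0, 0.5])
        assert marginal_wta(res, "a", negate=True).wta == -2.0


class TestKrinskyRobb:
    def test_zero_covariance_collapses_to_point(self, make_result):
        res = make_result(["a", "cost"], [1.0, 0.5], cov=np.zeros((2, 2)))
        lo, hi = krinsky_robb_ci(res, "a", reps=500, seed=1)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_deterministic_given_seed(self, results):
        args = (results["intervention"], "waiting_time:same_day_15d")
        assert krinsky_robb_ci(*args, reps=200, seed=9) == krinsky_robb_ci(
            *args, reps=200, seed=9
        )

    def test_matches_direct_normal_ratio_simulation(self, make_result):
        # diagonal covariance: the ratio distribution can be simulated
        # directly and independently of the KR machinery
        res = make_result(["a", "cost"], [1.0, 0.5], cov=np.diag([0.04, 0.01]))
        lo, hi = krinsky_robb_ci(res, "a", reps=200_000, seed=2)
        rng = np.random.default_rng(987654)  # unrelated stream
        num = rng.normal(1.0, 0.2, size=200_000)
        den = rng.normal(0.5, 0.1, size=200_000)
        olo, ohi = np.percentile(num / den, [2.5, 97.5])
        assert lo == pytest.approx(olo, rel=0.02, abs=0.02)
        assert hi == pytest.approx(ohi, rel=0.02, abs=0.02)

    def test_width_nondecreasing_in_covariance_scale(self, make_result):
        widths = []
        for scale in (1.0, 4.0, 9.0):
            res = make_result(
                ["a", "cost"], [1.0, 0.5], cov=scale * np.diag([0.01, 0.0004])
            )
            lo, hi = krinsky_robb_ci(res, "a", reps=4000, seed=3)
            widths.append(hi - lo)
        assert widths[0] <= widths[1] <= widths[2]

    def test_non_psd_covariance_raises_with_repair_hint(self, make_result):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
        res = make_result(["a", "cost"], [1.0, 0.5], cov=bad)
        with pytest.raises(CovarianceError, match="repair"):
            krinsky_robb_ci(res, "a", reps=100, seed=0)
        lo, hi = krinsky_robb_ci(res, "a", reps=100, seed=0, repair=True)
        assert lo <= hi


class TestRelativeImportance:
    def test_equal_ranges_split_evenly(self, make_result):
        res = make_result(["m:hi", "w:hi", "cost"], [1.0, 1.0, 0.5])
        from dcevalue import AttributeSpec

        attrs = (
            AttributeSpec(name="m", levels=("lo", "hi")),
            AttributeSpec(name="w", levels=("lo", "hi")),
        )
        shares = relative_importance(res, attrs, p_threshold=None)
        assert shares == {"m": pytest.approx(0.5), "w": pytest.approx(0.5)}

    def test_ranges_two_one_one(self, make_result):
        from dcevalue import AttributeSpec

        res = make_result(["a:hi", "b:hi", "c:hi"], [2.0, 1.0, 1.0])
        attrs = tuple(AttributeSpec(name=n, levels=("lo", "hi")) for n in "abc")
        shares = relative_importance(res, attrs, p_threshold=None)
        assert shares == {
            "a": pytest.approx(0.5),
            "b": pytest.approx(0.25),
            "c": pytest.approx(0.25),
        }

    def test_published_ordering_of_significant_attributes(self, results, fx):
        shares = relative_importance(results["all"], fx.attributes)
        # stroke risk and cost drop out (not significant)
        assert set(shares) == {"waiting_time", "pharmacy_model", "integration"}
        assert shares["waiting_time"] > shares["pharmacy_model"] > shares["integration"]
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_scale_invariance(self, results, fx):
        import dataclasses

        res = results["all"]
        scaled = dataclasses.replace(res, beta=3.0 * res.beta, cov=9.0 * res.cov)
        s1 = relative_importance(res, fx.attributes)
        s2 = relative_importance(scaled, fx.attributes)
        for k in s1:
            assert s1[k] == pytest.approx(s2[k])

    def test_all_zero_ranges_undefined(self, make_result):
        from dcevalue import AttributeSpec

        res = make_result(["a:hi", "cost"], [0.0, 0.5])
        attrs = (AttributeSpec(name="a", levels=("lo", "hi")),)
        with pytest.raises(UndefinedImportanceError):
            relative_importance(res, attrs, p_threshold=None)


class TestScenarioUtility:
    def test_reference_profile_is_zero(self, results, fx):
        assert scenario_utility(results["all"], (0, 0, 0, 0, 0), fx.attributes) == 0.0

    def test_best_scenario_sums_printed_coefficients(self, results, fx):
        v = scenario_utility(results["intervention"], fx.best_profile, fx.attributes)
        assert v == pytest.approx(0.948 + 0.634 + 1.049)

    def test_linear_in_cost(self, results, fx):
        r = results["intervention"]
        v0 = scenario_utility(r, (1, 1, 1, 1, 0), fx.attributes)
        v76 = scenario_utility(r, (1, 1, 1, 1, 3), fx.attributes)
        assert v76 - v0 == pytest.approx(r["cost"] * 76.0)


class TestScenarioWTAAndCV:
    def test_published_total_is_877(self, results, fx):
        total, parts = total_scenario_wta(
            results["intervention"], fx.best_profile, fx.worst_profile, fx.attributes
        )
        assert round_euro(total) == pytest.approx(877.00, abs=0.01)
        assert len(parts) == 3

    def test_identical_scenarios_zero(self, results, fx):
        total, parts = total_scenario_wta(
            results["intervention"], fx.best_profile, fx.best_profile, fx.attributes
        )
        assert total == 0.0 and parts == []

    def test_single_attribute_difference_equals_marginal(self, results, fx):
        r = results["intervention"]
        total, _ = total_scenario_wta(
            r, (0, 0, 2, 0, 0), (0, 0, 0, 0, 0), fx.attributes
        )
        assert total == pytest.approx(
            marginal_wta(r, "waiting_time:same_day_15d").wta
        )

    def test_cv_hand_computed_logsum(self, make_result, fx):
        # states with utilities (0, ln 3) vs (0, 0) at beta_cost = 1:
        # CV = ln(4) - ln(2) = ln 2
        from dcevalue import AttributeSpec

        attrs = (
            AttributeSpec(name="a", levels=("lo", "hi")),
            AttributeSpec(
                name="cost", levels=("c0", "c1"), coding="continuous",
                level_values=(0.0, 1.0),
            ),
        )
        res = make_result(["a:hi", "cost"], [np.log(3), 1.0])
        cv = compensating_variation(
            res, [(0, 0), (0, 0)], [(0, 0), (1, 0)], attrs
        )
        assert cv == pytest.approx(np.log(2))

    def test_cv_zero_for_identical_states(self, results, fx):
        cv = compensating_variation(
            results["intervention"], [fx.best_profile], [fx.best_profile], fx.attributes
        )
        assert cv == 0.0

    def test_cv_published_scenario_equals_877(self, results, fx):
        cv = compensating_variation(
            results["intervention"], [fx.worst_profile], [fx.best_profile], fx.attributes
        )
        assert round_euro(cv) == pytest.approx(877.00, abs=0.01)


class TestWTAAdditivityProperty:
    def test_cv_identity_on_random_coefficients(self, fx, make_result):
        # single-alternative CV == summed marginal WTA, exactly, for any beta
        rng = np.random.default_rng(23)
        names = tuple(fx.coefficients["all"].names)
        for _ in range(20):
            beta = rng.normal(scale=0.8, size=9)
            beta[-1] = rng.uniform(0.001, 0.1)  # nonzero cost coefficient
            res = make_result(names, beta)
            total, _ = total_scenario_wta(
                res, fx.best_profile, fx.worst_profile, fx.attributes
            )
            cv = compensating_variation(
                res, [fx.worst_profile], [fx.best_profile], fx.attributes
            )
            assert cv == pytest.approx(total, rel=1e-12)


class TestNetBenefit:
    def test_published_net_benefit(self):
        assert round_euro(net_benefit(877.00, 88.80)) == pytest.approx(788.20)

    def test_zero_when_wta_equals_cost(self):
        assert net_benefit(100.0, 100.0) == 0.0

    def test_negative_passed_through(self):
        assert net_benefit(50.0, 88.80) == pytest.approx(-38.80)

    def test_scenario_valuation_bundle(self, results, fx):
        val = scenario_valuation(
            results["intervention"],
            fx.attributes,
            fx.best_profile,
            fx.worst_profile,
            fx.incremental_cost,
            reps=200,
            seed=6,
        )
        assert round_euro(val.total_wta) == pytest.approx(877.00, abs=0.01)
        assert round_euro(val.net_benefit) == pytest.approx(788.20, abs=0.01)
        assert val.net_benefit == pytest.approx(val.total_wta - val.incremental_cost)
        for m in val.marginal:
            assert m.ci is not None and m.ci[0] <= m.ci[1]
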