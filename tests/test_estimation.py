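"""Conditional logit: likelihood, MLE oracles, inference, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from dcevalue import (
    BootstrapUnstableError,
    ConditionalLogit,
    SeparationError,
    SimulationConfig,
    bootstrap_coefficients,
    fit_clogit,
    log_likelihood,
    lr_test,
    simulate_choices,
)


def _encoded_frame(sets):
    """Build an encoded long-format frame from [(x_A, x_B, chosen_idx), ...]."""
    rows = []
    for sid, (xa, xb, pick) in enumerate(sets):
        for alt, x in enumerate((np.atleast_1d(xa), np.atleast_1d(xb))):
            rec = {"respondent_id": "r", "set_id": sid, "chosen": alt == pick}
            rec.update({f"x{j}": v for j, v in enumerate(x)})
            rows.append(rec)
    return pd.DataFrame(rows)


class TestLogLikelihood:
    def test_null_model_is_n_log_half(self):
        data = _encoded_frame([(1.0, 0.0, 0), (0.5, 1.0, 1), (0.0, 2.0, 0)])
        assert log_likelihood([0.0], data) == pytest.approx(-3 * np.log(2))

    def test_hand_computed_logit_probability(self):
        # V_A - V_B = ln 3 and A chosen: P(A) = 3/4
        data = _encoded_frame([(np.log(3), 0.0, 0)])
        assert log_likelihood([1.0], data) == pytest.approx(np.log(0.75))

    def test_set_constant_shift_leaves_ll_unchanged(self):
        sets = [(1.0, 0.0, 0), (0.3, 0.9, 1), (2.0, 0.5, 0)]
        shifted = [(a + 5.0, b + 5.0, p) for a, b, p in sets]
        beta = [0.7]
        assert log_likelihood(beta, _encoded_frame(sets)) == pytest.approx(
            log_likelihood(beta, _encoded_frame(shifted))
        )

    def test_dimension_mismatch_rejected(self):
        data = _encoded_frame([(1.0, 0.0, 0)])
        with pytest.raises(ValueError, match="length"):
            log_likelihood([1.0, 2.0], data)


def _grid_refine_oracle(data, lo=-5.0, hi=5.0, step0=0.25, final_step=1e-5):
    """Hierarchical grid maximization of the conditional-logit likelihood.

    For a concave objective, iteratively zooming the grid around the coarse
    argmax is equivalent to a dense global grid at the final resolution.
    """
    covs = [c for c in data.columns if c not in ("respondent_id", "set_id", "chosen")]
    assert len(covs) == 2
    centre = np.zeros(2)
    half = (hi - lo) / 2
    step = step0
    while True:
        g0 = np.arange(centre[0] - half, centre[0] + half + step / 2, step)
        g1 = np.arange(centre[1] - half, centre[1] + half + step / 2, step)
        best, arg = -np.inf, centre
        for b0 in g0:
            lls = [log_likelihood([b0, b1], data) for b1 in g1]
            j = int(np.argmax(lls))
            if lls[j] > best:
                best, arg = lls[j], np.array([b0, g1[j]])
        centre = arg
        if step <= final_step:
            return centre
        half = 2 * step
        step /= 5


class TestMLE:
    def test_tiny_instance_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        sets = []
        true = np.array([0.8, -0.5])
        for _ in range(6):
            xa, xb = rng.normal(size=(2, 2))
            p = 1 / (1 + np.exp(-(xa - xb) @ true))
            sets.append((xa, xb, 0 if rng.uniform() < p else 1))
        data = _encoded_frame(sets)
        mle = fit_clogit(data).beta
        oracle = _grid_refine_oracle(data)
        assert np.max(np.abs(mle - oracle)) < 1e-4

    def test_parameter_recovery(self, fx, design36, attrs):
        obs = simulate_choices(
            SimulationConfig(
                design=design36,
                true_beta=fx.coefficients["intervention"].beta_array(),
                n_respondents={"intervention": 500},
                seed=77,
            )
        )
        res = fit_clogit(obs, attrs)
        true = fx.coefficients["intervention"].beta_array()
        assert np.all(np.abs(res.beta - true) <= 3 * res.se)

    def test_matches_stratified_partial_likelihood_fit(self, sim500, attrs):
        # independent implementation: stratified (per-choice-set) conditional
        # likelihood as fitted by statsmodels
        from statsmodels.discrete.conditional_models import (
            ConditionalLogit as SMConditionalLogit,
        )

        from dcevalue.data import encode_design_matrix

        enc = encode_design_matrix(sim500, attrs)
        covs = [c for c in enc.columns if c not in ("respondent_id", "set_id", "chosen")]
        strata = pd.factorize(
            pd.Series(list(zip(enc["respondent_id"], enc["set_id"])))
        )[0]
        sm_fit = SMConditionalLogit(
            enc["chosen"].astype(int), enc[covs], groups=strata
        ).fit(disp=0)
        ours = fit_clogit(sim500, attrs)
        assert np.max(np.abs(ours.beta - sm_fit.params.values)) < 1e-3
        assert ours.llf >= sm_fit.llf - 1e-6
        assert np.max(np.abs(ours.cov - sm_fit.cov_params().values)) < 1e-4

    def test_constant_covariate_raises_not_silent_zero(self, attrs):
        sets = [(np.array([1.0, 3.0]), np.array([0.0, 3.0]), 0) for _ in range(5)]
        data = _encoded_frame(sets)
        with pytest.raises(SeparationError, match="never differ"):
            fit_clogit(data)

    def test_perfect_predictor_raises_separation(self):
        # x0 always higher for the chosen alternative
        rng = np.random.default_rng(1)
        sets = []
        for _ in range(10):
            xa, xb = rng.normal(size=2)
            lo, hi = sorted((xa, xb))
            sets.append((hi, lo, 0))
        with pytest.raises(SeparationError, match="perfectly predicts"):
            fit_clogit(_encoded_frame(sets))

    def test_likelihood_concave_along_segments(self, sim500, attrs):
        from dcevalue.data import encode_design_matrix

        enc = encode_design_matrix(sim500[:400], attrs)
        rng = np.random.default_rng(5)
        for _ in range(5):
            b0, b1 = rng.normal(scale=0.5, size=(2, 9))
            ts = np.linspace(0, 1, 9)
            lls = [log_likelihood(b0 + t * (b1 - b0), enc) for t in ts]
            chords = np.diff(lls, 2)  # second differences of a concave fn <= 0
            assert np.all(chords <= 1e-8)

    def test_deterministic_given_data_and_start(self, sim500, attrs):
        r1 = fit_clogit(sim500, attrs)
        r2 = fit_clogit(sim500, attrs)
        assert np.array_equal(r1.beta, r2.beta)


class TestEstimatorProtocol:
    def test_sklearn_clone_and_params(self):
        est = ConditionalLogit(tol=1e-6, max_iter=50)
        cloned = clone(est)
        assert cloned.get_params() == {"tol": 1e-6, "max_iter": 50, "start": None}

    def test_predict_proba_sums_to_one_within_sets(self, sim500, attrs):
        from dcevalue.data import encode_design_matrix

        enc = encode_design_matrix(sim500, attrs)
        covs = [c for c in enc.columns if c not in ("respondent_id", "set_id", "chosen")]
        sets = pd.factorize(
            pd.Series(list(zip(enc["respondent_id"], enc["set_id"])))
        )[0]
        est = ConditionalLogit().fit(enc[covs], enc["chosen"], sets=sets)
        proba = est.predict_proba(enc[covs].to_numpy(), sets=sets)
        sums = np.bincount(sets, weights=proba)
        assert np.allclose(sums, 1.0)


class TestLRTest:
    def test_null_equals_full_gives_unit_p(self, make_result):
        res = make_result(["a"], [0.0])
        object.__setattr__(res, "llf", res.llnull)
        chi2, df, p = lr_test(res)
        assert chi2 == 0.0 and p == 1.0

    def test_study_model_degrees_of_freedom(self, fit500):
        chi2, df, p = lr_test(fit500)
        assert df == 9
        assert chi2 == pytest.approx(2 * (fit500.llf - fit500.llnull))
        assert chi2 > 0 and 0 <= p < 1

    def test_type_i_error_under_null(self, design36, attrs):
        # simulated null: true beta = 0, LR test at alpha = .05
        from scipy import stats

        reps, rejections = 120, 0
        for k in range(reps):
            obs = simulate_choices(
                SimulationConfig(
                    design=design36,
                    true_beta=np.zeros(9),
                    n_respondents={"intervention": 78, "control": 44},
                    seed=1000 + k,
                )
            )
            _, _, p = lr_test(fit_clogit(obs, attrs))
            rejections += p < 0.05
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= rejections <= hi


class TestBootstrap:
    def test_reproducible_given_seed(self, sim500, attrs):
        sub = [o for o in sim500 if o.respondent_id <= "r0060"]
        ci1, f1 = bootstrap_coefficients(sub, attrs, reps=20, seed=3)
        ci2, f2 = bootstrap_coefficients(sub, attrs, reps=20, seed=3)
        assert ci1 == ci2 and f1 == f2

    def test_bounds_ordered_and_cover_point_estimate_roughly(self, sim500, attrs):
        sub = [o for o in sim500 if o.respondent_id <= "r0150"]
        res = fit_clogit(sub, attrs)
        ci, _ = bootstrap_coefficients(sub, attrs, reps=60, seed=4)
        for name in res.names:
            lo, hi = ci[name]
            assert lo < hi
        # most point estimates should lie inside their own bootstrap CI
        inside = sum(ci[n][0] <= res[n] <= ci[n][1] for n in res.names)
        assert inside >= 7

    def test_single_respondent_is_unstable(self, sim500, attrs):
        one = [o for o in sim500 if o.respondent_id == "r0001"]
        with pytest.raises(BootstrapUnstableError):
            bootstrap_coefficients(one, attrs, reps=10, seed=0)

    def test_reps_below_two_rejected(self, sim500, attrs):
        with pytest.raises(ValueError):
            bootstrap_coefficients(sim500, attrs, reps=1, seed=0)

    def test_coverage_of_true_coefficient(self, fx, attrs):
        # scaled-down coverage study: nominal 95% CI for the strongest
        # coefficient should cover the truth in most replicates
        from dcevalue import search_fractional_design

        design = search_fractional_design(attrs, 36, 9, seed=31, n_restarts=2)
        true = fx.coefficients["intervention"].beta_array()
        j = list(fx.coefficients["intervention"].names).index(
            "waiting_time:same_day_15d"
        )
        covered = 0
        outer = 25
        for k in range(outer):
            obs = simulate_choices(
                SimulationConfig(
                    design=design,
                    true_beta=true,
                    n_respondents={"intervention": 120},
                    seed=5000 + k,
                )
            )
            ci, _ = bootstrap_coefficients(obs, attrs, reps=60, seed=k)
            lo, hi = ci["waiting_time:same_day_15d"]
            covered += lo <= true[j] <= hi
        assert covered >= 19  # ~95% nominal; binomial 3-sigma lower bound
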