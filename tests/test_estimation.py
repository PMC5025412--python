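"""Estimators: logit probabilities, conditional logit, simulated-likelihood
mixed logit, latent-class EM, and model selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from dcequip.coding import ResponseDataset
from dcequip.estimation import (
    ClogitEstimate,
    MixedLogitEstimate,
    ModelSpec,
    choose_class_count,
    clogit_fit,
    conditional_coefficients,
    halton_normal_draws,
    information_criteria,
    lcm_fit,
    lcm_loglik,
    logit_prob,
    msl_loglik,
    mxl_fit,
    panel_arrays,
    posterior_class_probs,
    select_n_classes,
    sequence_prob,
    share_sign,
)


class TestLogitProb:
    def test_zero_coefficients_give_uniform(self):
        p = logit_prob(np.zeros(3), np.random.default_rng(0).normal(size=(2, 3)))
        assert np.allclose(p, 0.5)

    def test_log2_utility_difference_gives_two_thirds(self):
        p = logit_prob(np.array([1.0]), np.array([[math.log(2)], [0.0]]))
        assert np.allclose(p, [2 / 3, 1 / 3])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-500, 500), st.integers(0, 2**16))
    def test_shift_invariance_and_simplex(self, shift, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(3, 4))
        beta = rng.normal(size=4)
        p = logit_prob(beta, X)
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).all()
        # add a constant utility to every alternative via an extra column
        Xs = np.hstack([X, np.full((3, 1), 1.0)])
        ps = logit_prob(np.append(beta, shift), Xs)
        assert np.allclose(p, ps)


class TestSequenceProb:
    def _one_resp(self, probs_per_set):
        """Construct a 1-covariate panel whose per-set chosen
        probabilities are exactly the requested values at beta=1."""
        rows = []
        for t, p in enumerate(probs_per_set):
            # choose x difference so that sigma(dx) = p for chosen alt 0
            dx = math.log(p / (1 - p))
            rows.append({"respondent_id": 1, "set_id": t, "alternative_index": 0,
                         "chosen": 1, "x": dx})
            rows.append({"respondent_id": 1, "set_id": t, "alternative_index": 1,
                         "chosen": 0, "x": 0.0})
        return pd.DataFrame(rows)

    def test_single_set_equals_logit_prob(self):
        df = self._one_resp([0.7])
        p = sequence_prob(np.array([1.0]), df, ["x"])
        assert p == pytest.approx(0.7)

    def test_product_and_order_invariance(self):
        df = self._one_resp([0.5, 0.25])
        assert sequence_prob(np.array([1.0]), df, ["x"]) == pytest.approx(0.125)
        shuffled = df.iloc[[2, 3, 0, 1]].reset_index(drop=True)
        assert sequence_prob(np.array([1.0]), shuffled, ["x"]) == pytest.approx(0.125)


class TestConditionalLogit:
    def test_recovers_truth_within_3_se(self, homogeneous_data):
        pop, _, data = homogeneous_data
        est = clogit_fit(data)
        assert est.converged
        truth = pd.Series(np.asarray(pop.means), index=list(pop.columns))
        z = (est.params - truth.reindex(est.params.index)) / est.se
        assert (z.abs() < 3).all(), z

    def test_random_choices_give_null_estimates(self, blocked_plan, coding):
        from dcequip.synthetic import PopulationSpec, draw_population, simulate_choices

        cols = tuple(coding.columns) + ("asc",)
        pop = PopulationSpec(kind="normal", columns=cols,
                             means=np.zeros(len(cols)), sds=np.zeros(len(cols)),
                             n_respondents=400, seed=51)
        data = simulate_choices(draw_population(pop), blocked_plan, coding, seed=52)
        est = clogit_fit(data)
        z = est.params / est.se
        # 11 simultaneous z statistics: test each at the 0.1% two-sided
        # level so the family-wise false-alarm rate stays near 1%.
        assert (z.abs() < norm.ppf(1 - 0.0005)).all()
        assert est.loglik >= est.loglik_null

    def test_agrees_with_binary_logit_on_differences(self, homogeneous_data):
        """Independent oracle: a two-alternative conditional logit is a
        binary logit on within-set covariate differences."""
        sm = pytest.importorskip("statsmodels.api")
        _, _, data = homogeneous_data
        df = data.df.copy()
        df["remuneration"] = df["remuneration"] / 10000.0  # common rescale for both fits
        data2 = ResponseDataset(df=df)
        est = clogit_fit(data2)
        wide0 = df[df.alternative_index == 0].set_index(["respondent_id", "set_id"])
        wide1 = df[df.alternative_index == 1].set_index(["respondent_id", "set_id"])
        dx = wide0[data2.covariates] - wide1[data2.covariates]
        y = wide0["chosen"]
        oracle = sm.Logit(y.to_numpy(), dx.to_numpy()).fit(disp=0)
        assert np.allclose(est.params.to_numpy(), oracle.params, atol=1e-5)
        assert est.loglik == pytest.approx(oracle.llf, abs=1e-6)


class TestSimulatedLikelihood:
    def test_zero_sds_equal_clogit_for_any_draw_count(self, homogeneous_data):
        _, _, data = homogeneous_data
        pan = panel_arrays(data)
        cl = clogit_fit(data)
        rand_idx = np.array([2, 5])
        for R in (1, 7, 50):
            draws = halton_normal_draws(pan.n_respondents, R, 2, seed=3)
            ll = msl_loglik(cl.params.to_numpy(), np.zeros(2), pan, draws, rand_idx)
            assert ll == pytest.approx(cl.loglik, abs=1e-9)

    def test_single_zero_draw_equals_clogit_at_means(self, homogeneous_data):
        _, _, data = homogeneous_data
        pan = panel_arrays(data)
        cl = clogit_fit(data)
        draws = np.zeros((pan.n_respondents, 1, 2))
        ll = msl_loglik(cl.params.to_numpy(), np.array([0.4, 0.8]), pan,
                        draws, np.array([2, 5]))
        assert ll == pytest.approx(cl.loglik, abs=1e-9)

    def test_matches_gauss_hermite_quadrature_in_one_dimension(self, homogeneous_data):
        """Oracle: with one normal coefficient the mixing integral can be
        computed by Gauss-Hermite quadrature; MSL at R=10000 must agree
        to three decimals."""
        _, _, data = homogeneous_data
        small = ResponseDataset(
            df=data.df[data.df.respondent_id <= 30].reset_index(drop=True)
        )
        pan = panel_arrays(small)
        cl = clogit_fit(small)
        means = cl.params.to_numpy()
        j = small.covariates.index("p4p")
        sd = 0.9
        draws = halton_normal_draws(pan.n_respondents, 10_000, 1, seed=9)
        ll_msl = msl_loglik(means, np.array([sd]), pan, draws, np.array([j]))
        nodes, weights = np.polynomial.hermite.hermgauss(60)
        ll_quad = 0.0
        for r in small.df.respondent_id.unique():
            g = small.df[small.df.respondent_id == r]
            vals = []
            for z, w in zip(nodes, weights):
                beta = means.copy()
                beta[j] = means[j] + sd * math.sqrt(2) * z
                vals.append(w * sequence_prob(beta, g, small.covariates))
            ll_quad += math.log(sum(vals) / math.sqrt(math.pi))
        assert ll_msl == pytest.approx(ll_quad, abs=1e-3)

    def test_halton_draws_reproducible(self):
        a = halton_normal_draws(10, 20, 3, seed=5)
        b = halton_normal_draws(10, 20, 3, seed=5)
        assert np.array_equal(a, b)
        c = halton_normal_draws(10, 20, 3, seed=6)
        assert not np.array_equal(a, c)


class TestMixedLogit:
    def test_parameter_counts_for_preset_menus(self, coding):
        cols = tuple(coding.columns) + ("asc",)
        assert ModelSpec.mn1(cols).k == 20
        assert ModelSpec.mn2(cols).k == 21
        with pytest.raises(ValueError, match="constant"):
            ModelSpec(columns=cols, random=("asc",))

    def test_all_fixed_spec_reduces_to_clogit(self, homogeneous_data):
        _, _, data = homogeneous_data
        spec = ModelSpec(columns=tuple(data.covariates), random=(), n_draws=5, seed=1)
        est = mxl_fit(data, spec)
        cl = clogit_fit(data)
        assert est.loglik == pytest.approx(cl.loglik, abs=1e-4)
        assert np.allclose(est.means.to_numpy(), cl.params.to_numpy(), atol=1e-3)

    def test_one_random_coefficient_recovery(self, blocked_plan, coding):
        """Mean -0.5, SD 1.0 on one attribute recovered within 3 SEs."""
        from dcequip.synthetic import PopulationSpec, draw_population, simulate_choices

        cols = tuple(coding.columns) + ("asc",)
        means = np.zeros(len(cols))
        sds = np.zeros(len(cols))
        j = cols.index("p4p")
        means[j], sds[j] = -0.5, 1.0
        pop = PopulationSpec(kind="normal", columns=cols, means=means, sds=sds,
                             n_respondents=500, seed=61)
        data = simulate_choices(draw_population(pop), blocked_plan, coding, seed=62)
        spec = ModelSpec(columns=cols, random=("p4p",), n_draws=200, seed=63)
        est = mxl_fit(data, spec)
        assert est.converged
        assert abs(est.means["p4p"] - (-0.5)) < 3 * est.se_means["p4p"]
        assert abs(est.sds["p4p"] - 1.0) < 3 * est.se_sds["p4p"]


class TestConditionalCoefficients:
    def _fixed_estimate(self, columns, means, sds_random, random, n_draws=4000):
        spec = ModelSpec(columns=tuple(columns), random=tuple(random),
                         n_draws=n_draws, seed=17)
        means = pd.Series(means, index=list(columns))
        sds = pd.Series(sds_random, index=list(random))
        nan_m = pd.Series(np.nan, index=means.index)
        nan_s = pd.Series(np.nan, index=sds.index)
        return MixedLogitEstimate(
            means=means, sds=sds, se_means=nan_m, se_sds=nan_s,
            tstat_means=nan_m, tstat_sds=nan_s, loglik=0.0, spec=spec,
            converged=True, message="constructed", n_rows=0, n_respondents=0,
        )

    def _p4p_panel(self, n_sets, chooser):
        """Pairs differing only in p4p (+1 candidate vs -1 comparator)."""
        rows = []
        for r, choice in chooser.items():
            for t in range(n_sets):
                rows.append({"respondent_id": r, "set_id": t, "alternative_index": 0,
                             "chosen": int(choice == 0), "p4p": 1.0})
                rows.append({"respondent_id": r, "set_id": t, "alternative_index": 1,
                             "chosen": int(choice == 1), "p4p": -1.0})
        return ResponseDataset(df=pd.DataFrame(rows))

    def test_zero_sds_collapse_to_population_mean(self, homogeneous_data):
        _, _, data = homogeneous_data
        cols = data.covariates
        est = self._fixed_estimate(cols, np.linspace(-0.5, 0.5, len(cols)),
                                   [0.0], ["p4p"], n_draws=50)
        cond = conditional_coefficients(est, data)
        assert np.allclose(cond.means.to_numpy() - est.means.to_numpy()[None, :], 0.0)

    def test_consistent_p4p_chooser_pulled_above_mean(self):
        data = self._p4p_panel(6, {1: 0, 2: 1})
        est = self._fixed_estimate(["p4p"], [0.1], [1.0], ["p4p"])
        cond = conditional_coefficients(est, data)
        assert cond.means.loc[1, "p4p"] > 0.1
        assert cond.means.loc[2, "p4p"] < 0.1

    def test_matches_dense_grid_posterior_in_one_dimension(self):
        data = self._p4p_panel(5, {1: 0, 2: 1, 3: 0})
        mean, sd = 0.2, 0.8
        est = self._fixed_estimate(["p4p"], [mean], [sd], ["p4p"], n_draws=20_000)
        cond = conditional_coefficients(est, data)
        grid = np.linspace(mean - 6 * sd, mean + 6 * sd, 4001)
        dens = norm.pdf(grid, mean, sd)
        for r in (1, 2, 3):
            g = data.df[data.df.respondent_id == r]
            seq = np.array([sequence_prob(np.array([b]), g, ["p4p"]) for b in grid])
            oracle = float((grid * seq * dens).sum() / (seq * dens).sum())
            assert cond.means.loc[r, "p4p"] == pytest.approx(oracle, abs=1e-2)


class TestShareSign:
    def _est(self, mean, sd):
        cols = ("p4p",)
        spec = ModelSpec(columns=cols, random=("p4p",) if sd else (), n_draws=10, seed=0)
        s = pd.Series([sd], index=["p4p"]) if sd else pd.Series(dtype=float)
        nan = pd.Series(np.nan, index=["p4p"])
        return MixedLogitEstimate(
            means=pd.Series([mean], index=["p4p"]), sds=s, se_means=nan,
            se_sds=s * np.nan, tstat_means=nan, tstat_sds=s * np.nan,
            loglik=0.0, spec=spec, converged=True, message="",
            n_rows=0, n_respondents=0,
        )

    def test_zero_mean_splits_in_half(self):
        assert share_sign(self._est(0.0, 1.0), "p4p")["population"] == pytest.approx(0.5)

    def test_population_share_from_normal_cdf(self):
        # positive share of N(-0.5085, 0.9771^2) is 1 - Phi(0.5085/0.9771)
        res = share_sign(self._est(-0.5085, 0.9771), "p4p", "positive")
        assert res["population"] == pytest.approx(1 - norm.cdf(0.5085 / 0.9771), abs=1e-12)
        assert res["population"] == pytest.approx(0.302, abs=5e-3)

    def test_fixed_coefficient_is_step_function(self):
        assert share_sign(self._est(-0.2, 0.0), "p4p", "positive")["population"] == 0.0
        assert share_sign(self._est(-0.2, 0.0), "p4p", "negative")["population"] == 1.0

    def test_empirical_share_from_conditional_means(self):
        est = self._est(0.3, 1.0)
        from dcequip.estimation import IndividualCoefficients

        frame = pd.DataFrame({"p4p": [0.5, 0.2, 0.1]})
        ind = IndividualCoefficients(means=frame, sim_error=frame * 0)
        assert share_sign(est, "p4p", "positive", ind)["empirical"] == 1.0


class TestLatentClass:
    def test_loglik_matches_hand_computed_toy(self):
        rows = []
        for r, choice in ((1, 0), (2, 1)):
            rows.append({"respondent_id": r, "set_id": 1, "alternative_index": 0,
                         "chosen": int(choice == 0), "x": 1.0})
            rows.append({"respondent_id": r, "set_id": 1, "alternative_index": 1,
                         "chosen": int(choice == 1), "x": 0.0})
        pan = panel_arrays(ResponseDataset(df=pd.DataFrame(rows)))
        coefs = np.array([[1.0], [-1.0]])
        shares = np.array([0.3, 0.7])
        sig = lambda u: 1.0 / (1.0 + math.exp(-u))
        expected = math.log(0.3 * sig(1) + 0.7 * sig(-1)) + math.log(
            0.3 * (1 - sig(1)) + 0.7 * (1 - sig(-1))
        )
        assert lcm_loglik(coefs, shares, pan) == pytest.approx(expected, abs=1e-12)

    def test_duplicate_class_leaves_loglik_unchanged(self, homogeneous_data):
        _, _, data = homogeneous_data
        pan = panel_arrays(data)
        rng = np.random.default_rng(0)
        beta = rng.normal(size=(2, len(pan.columns)), scale=0.3)
        ll2 = lcm_loglik(beta, np.array([0.5, 0.5]), pan)
        beta3 = np.vstack([beta, beta[1]])
        ll3 = lcm_loglik(beta3, np.array([0.5, 0.25, 0.25]), pan)
        assert ll2 == pytest.approx(ll3, abs=1e-10)

    def test_single_class_reduces_to_clogit(self, homogeneous_data):
        _, _, data = homogeneous_data
        cl = clogit_fit(data)
        one = lcm_fit(data, 1, seed=0, n_restarts=1)
        assert one.loglik == pytest.approx(cl.loglik, abs=1e-4)
        assert np.allclose(one.class_coefs.iloc[0].to_numpy(),
                           cl.params.to_numpy(), atol=1e-3)

    def test_em_trace_monotone_and_posterior_rows_sum_to_one(self, two_class_data):
        _, _, data = two_class_data
        est = lcm_fit(data, 2, seed=3, n_restarts=2)
        assert np.all(np.diff(est.ll_trace) >= -1e-8)
        post, avg = posterior_class_probs(est, data)
        assert np.allclose(post.sum(axis=1), 1.0)
        assert avg.sum() == pytest.approx(1.0)
        assert np.all(est.shares[:-1] >= est.shares[1:])  # canonical order

    def test_well_separated_classes_give_near_degenerate_posteriors(self, two_class_data):
        _, _, data = two_class_data
        est = lcm_fit(data, 2, seed=3, n_restarts=2)
        top = est.posterior.to_numpy().max(axis=1)
        assert (top > 0.95).mean() > 0.9


class TestModelSelection:
    def test_choose_class_count_breaks_ties_downward(self):
        assert choose_class_count([2, 3, 4], [5.0, 4.0, 4.0]) == 3
        assert choose_class_count([4], [1.0]) == 4

    def test_information_criteria_reject_bad_inputs(self):
        with pytest.raises(ValueError):
            information_criteria(-10.0, -1, 100)

    def test_sweep_table_shape_and_nondecreasing_loglik(self, two_class_data):
        _, _, data = two_class_data
        small = ResponseDataset(df=data.df[data.df.respondent_id <= 150].reset_index(drop=True))
        table, chosen, fits = select_n_classes(small, [1, 2], seed=5, n_restarts=2)
        assert list(table["n_classes"]) == [1, 2]
        assert table["loglik"].iloc[1] >= table["loglik"].iloc[0] - 1e-6
        assert chosen in (1, 2)
        assert set(fits) == {1, 2}
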