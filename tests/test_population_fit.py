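"""Mixed-effects machinery: lognormal effects, likelihoods, SAEM, RSE."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.integrate import quad

from lumigrowth import (
    CohortDesign,
    LongitudinalDataset,
    PopulationParameters,
    SaemSettings,
    cv_percent_from_omega2,
    fit_lambda,
    generate_cohort,
    individual_log_likelihood,
    individual_parameters,
    marginal_log_likelihood,
    omega2_from_cv_percent,
    saem_fit,
    two_stage_fit,
)
from lumigrowth.population import (
    BIOLUMINESCENCE,
    CALIPER,
    GrowthSubjectModel,
    ScaleSubjectModel,
    _loglik_prop,
    _saem_engine,
    compute_rse,
)
from conftest import CV_A, P0_SIGNAL, TYPICAL_A, TYPICAL_K, TYPICAL_LAM

FAST = SaemSettings(n_explore=150, n_smooth=100)


def zero_var_truth(sigma=0.15):
    return PopulationParameters(
        theta_mu={"a": TYPICAL_A, "K": TYPICAL_K, "lam": TYPICAL_LAM},
        omega2={"a": 0.0, "K": 0.0, "lam": 0.0},
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

class TestIndividualParameters:
    def test_typical_individual(self):
        mu = {"a": 0.4, "K": 4e9}
        assert individual_parameters(mu, {"a": 0.0, "K": 0.0}) == pytest.approx(mu)

    def test_log2_doubles_one_component(self):
        out = individual_parameters({"a": 0.4, "K": 4e9}, {"a": np.log(2.0), "K": 0.0})
        assert out["a"] == pytest.approx(0.8)
        assert out["K"] == pytest.approx(4e9)

    def test_monte_carlo_cv_matches_formula(self):
        # empirical CV of 1e5 lognormal draws must reproduce the published CV
        w2 = omega2_from_cv_percent(CV_A)
        rng = np.random.default_rng(1)
        draws = TYPICAL_A * np.exp(np.sqrt(w2) * rng.standard_normal(100_000))
        cv = 100 * draws.std(ddof=1) / draws.mean()
        assert abs(cv / CV_A - 1) < 0.01


@hyp_settings(max_examples=50, deadline=None, derandomize=True)
@given(cv=st.floats(0.1, 200.0))
def test_cv_omega_round_trip(cv):
    assert cv_percent_from_omega2(omega2_from_cv_percent(cv)) == pytest.approx(
        cv, rel=1e-12
    )


class TestIndividualLogLikelihood:
    def test_closed_form_at_exact_prediction(self):
        f, sigma = 2.0e8, 0.15
        ll = individual_log_likelihood([f], [f], sigma)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) - np.log(sigma * f))

    def test_sigma_tradeoff(self):
        # far from the prediction, a larger sigma helps; at the prediction
        # it only inflates the penalty term
        f = np.array([1e8])
        far, near = np.array([3e8]), np.array([1.0e8])
        assert individual_log_likelihood(far, f, 0.3) > individual_log_likelihood(
            far, f, 0.15
        )
        assert individual_log_likelihood(near, f, 0.3) < individual_log_likelihood(
            near, f, 0.15
        )

    def test_zero_prediction_rejected(self):
        with pytest.raises(ValueError):
            individual_log_likelihood([1.0], [0.0], 0.15)


def test_marginal_likelihood_matches_quadrature_on_toy_model():
    # one subject, one parameter: brute-force integration over the random
    # effect is tractable and pins the importance-sampling estimate
    times = np.array([1.0, 2.0, 4.0])
    base = {"s1": lambda t: 0.1 * t + 0.05}
    model = ScaleSubjectModel(base)
    rng = np.random.default_rng(0)
    lam_true = 2.0
    y = lam_true * base["s1"](times) * (1 + 0.1 * rng.standard_normal(3))
    series = {"s1": (times, y)}
    pop = PopulationParameters(theta_mu={"lam": 2.1}, omega2={"lam": 0.04}, sigma=0.12)

    mu, w2 = np.log(2.1), 0.04
    pred = model.for_subject("s1")

    def integrand(phi):
        f = pred.predict(times, np.array([np.exp(phi)]))
        ll = _loglik_prop(y, f, 0.12)
        lp = -0.5 * np.log(2 * np.pi * w2) - 0.5 * (phi - mu) ** 2 / w2
        return np.exp(ll + lp)

    exact = np.log(quad(integrand, mu - 8 * np.sqrt(w2), mu + 8 * np.sqrt(w2),
                        epsrel=1e-10)[0])
    est = marginal_log_likelihood(pop, series, model, n_samples=4000, seed=3)
    assert est == pytest.approx(exact, abs=0.02 * abs(exact))


# ---------------------------------------------------------------------------
# two-stage baseline
# ---------------------------------------------------------------------------

class TestTwoStage:
    def test_noiseless_identity(self):
        design = CohortDesign(
            truth=zero_var_truth(), sigma_biolum=0.0, sigma_caliper=0.0, seed=4
        )
        data, _ = generate_cohort(design)
        pop, indiv = two_stage_fit(data, design.p0_signal)
        assert pop.theta_mu["a"] == pytest.approx(TYPICAL_A, rel=1e-6)
        assert pop.theta_mu["K"] == pytest.approx(TYPICAL_K, rel=1e-6)

    def test_agrees_with_saem_on_rich_data(self):
        design = CohortDesign(sigma_biolum=0.05, sigma_caliper=0.05, seed=6)
        data, _ = generate_cohort(design)
        pop, _ = two_stage_fit(data, design.p0_signal)
        fit = saem_fit(data, design.p0_signal, settings=FAST, compute_se=False)
        for name in ("a", "K"):
            assert abs(pop.theta_mu[name] / fit.estimates.theta_mu[name] - 1) < 0.10

    def test_flat_signal_subject_excluded_run_continues(self):
        design = CohortDesign(n_subjects=5, seed=2)
        data, _ = generate_cohort(design)
        days = np.asarray(design.observation_days, float)
        flat = pd.DataFrame(
            {
                "subject": "flat",
                "time": days,
                "observable": BIOLUMINESCENCE,
                "value": P0_SIGNAL * 0.8,
            }
        )
        data2 = LongitudinalDataset(pd.concat([data.frame, flat], ignore_index=True))
        with pytest.warns(UserWarning, match="flat"):
            pop, indiv = two_stage_fit(data2, design.p0_signal)
        assert "flat" not in indiv.index
        assert len(indiv) == 5


# ---------------------------------------------------------------------------
# SAEM
# ---------------------------------------------------------------------------

class TestSaem:
    def test_degenerate_recovery_noiseless_cohort(self):
        design = CohortDesign(
            truth=zero_var_truth(), sigma_biolum=0.0, sigma_caliper=0.0, seed=2
        )
        data, _ = generate_cohort(design)
        fit = saem_fit(data, design.p0_signal, settings=FAST, compute_se=False)
        assert fit.converged
        assert abs(fit.estimates.theta_mu["a"] / TYPICAL_A - 1) < 0.01
        assert abs(fit.estimates.theta_mu["K"] / TYPICAL_K - 1) < 0.01

    def test_reproducible_given_seed(self):
        design = CohortDesign(n_subjects=6, seed=13)
        data, _ = generate_cohort(design)
        st_ = SaemSettings(n_explore=80, n_smooth=60, seed=7)
        f1 = saem_fit(data, design.p0_signal, settings=st_, compute_se=False)
        f2 = saem_fit(data, design.p0_signal, settings=st_, compute_se=False)
        assert f1.estimates.theta_mu == f2.estimates.theta_mu
        assert np.array_equal(f1.loglik_trace, f2.loglik_trace)

    def test_too_few_subjects_rejected(self):
        design = CohortDesign(n_subjects=3, seed=1)
        data, _ = generate_cohort(design)
        frame = data.frame[data.frame["subject"].isin(["m01", "m02"])]
        with pytest.raises(ValueError):
            saem_fit(LongitudinalDataset(frame), design.p0_signal)

    def test_beats_two_stage_in_marginal_likelihood(self):
        # maximum likelihood should not lose to the naive baseline; allow one
        # seed to fail on Monte-Carlo noise
        wins = 0
        for seed in range(5):
            design = CohortDesign(n_subjects=8, seed=20 + seed)
            data, _ = generate_cohort(design)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pop_ts, _ = two_stage_fit(data, design.p0_signal)
                fit = saem_fit(data, design.p0_signal, settings=FAST, compute_se=False)
            series = data.subject_series(BIOLUMINESCENCE)
            model = GrowthSubjectModel(design.p0_signal)
            ll_saem = marginal_log_likelihood(fit, n_samples=600, seed=seed)
            ll_ts = marginal_log_likelihood(pop_ts, series, model, n_samples=600,
                                            seed=seed)
            wins += ll_saem >= ll_ts - 0.5
        assert wins >= 4


# ---------------------------------------------------------------------------
# stage-2 lambda fit
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def noiseless_unit_lambda():
    truth = PopulationParameters(
        theta_mu={"a": TYPICAL_A, "K": TYPICAL_K, "lam": 1.0},
        omega2={"a": 0.0, "K": 0.0, "lam": 0.0},
        sigma=0.15,
    )
    design = CohortDesign(
        truth=truth, sigma_biolum=0.0, sigma_caliper=0.0, seed=3, n_subjects=6
    )
    data, _ = generate_cohort(design)
    stage1 = saem_fit(data, design.p0_signal, settings=FAST, compute_se=False)
    return design, data, stage1


class TestFitLambda:
    def test_unit_lambda_recovered_exactly(self, noiseless_unit_lambda):
        design, data, stage1 = noiseless_unit_lambda
        fit2 = fit_lambda(stage1, data, conv=design.conversion,
                          settings=FAST, compute_se=False)
        assert fit2.estimates.theta_mu["lam"] == pytest.approx(1.0, rel=1e-3)

    def test_lambda_scales_with_caliper_values(self, noiseless_unit_lambda):
        design, data, stage1 = noiseless_unit_lambda
        frame = data.frame.copy()
        mask = frame["observable"] == CALIPER
        frame.loc[mask, "value"] *= 3.0
        scaled = LongitudinalDataset(frame)
        fit2 = fit_lambda(stage1, scaled, conv=design.conversion,
                          settings=FAST, compute_se=False)
        assert fit2.estimates.theta_mu["lam"] == pytest.approx(3.0, rel=1e-3)

    def test_joint_mode_agrees_with_sequential(self, noiseless_unit_lambda):
        # the one-shot (a, K, lambda) fit is an alternative route to the
        # same estimand; on clean data the two must coincide
        from lumigrowth import joint_fit

        design, data, stage1 = noiseless_unit_lambda
        fit2 = fit_lambda(stage1, data, conv=design.conversion,
                          settings=FAST, compute_se=False)
        jf = joint_fit(data, design.p0_signal, conv=design.conversion,
                       settings=FAST, compute_se=False)
        assert jf.converged
        assert jf.estimates.theta_mu["lam"] == pytest.approx(
            fit2.estimates.theta_mu["lam"], rel=0.02
        )
        assert jf.estimates.theta_mu["a"] == pytest.approx(
            stage1.estimates.theta_mu["a"], rel=0.02
        )

    def test_missing_caliper_records_rejected(self, noiseless_unit_lambda):
        design, data, stage1 = noiseless_unit_lambda
        biolum_only = LongitudinalDataset(
            data.frame[data.frame["observable"] == BIOLUMINESCENCE]
        )
        with pytest.raises(ValueError, match="caliper"):
            fit_lambda(stage1, biolum_only, conv=design.conversion)


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def _toy_constant_series(n_subj, n_obs, mu_lam, w2, sigma, seed):
    """Subjects observe a constant times a lognormal individual level."""
    rng = np.random.default_rng(seed)
    times = np.linspace(1, n_obs, n_obs)
    series = {}
    for i in range(n_subj):
        lam_i = mu_lam * np.exp(np.sqrt(w2) * rng.standard_normal())
        y = lam_i * (1 + sigma * rng.standard_normal(n_obs))
        series[f"s{i}"] = (times, np.abs(y))
    return series


def _toy_model():
    class ConstantBase(dict):
        def __missing__(self, key):
            return lambda t: np.ones_like(t)

    return ScaleSubjectModel(ConstantBase())


class TestComputeRse:
    def test_matches_closed_form_on_near_linear_toy(self):
        # y_ij = lam_i*(1+eps): on the log scale this is the one-way
        # random-effects ANOVA model with SE(mu) = sqrt((w2 + s2/n)/N)
        n_subj, n_obs, w2, sigma = 30, 8, 0.04, 0.1
        series = _toy_constant_series(n_subj, n_obs, 2.0, w2, sigma, seed=5)
        init = PopulationParameters(
            theta_mu={"lam": 2.0}, omega2={"lam": w2}, sigma=sigma
        )
        st_ = SaemSettings(n_explore=200, n_smooth=150, seed=11, rse_samples=1500)
        fit = _saem_engine(series, _toy_model(), init, st_)
        rse = compute_rse(fit)
        w2_hat = fit.estimates.omega2["lam"]
        s2_hat = fit.estimates.sigma**2
        expected = 100 * np.sqrt((w2_hat + s2_hat / n_obs) / n_subj)
        assert rse["lam"] == pytest.approx(expected, rel=0.05)

    def test_rse_shrinks_when_cohort_doubled(self):
        # information additivity, in expectation over seeds
        deltas = []
        for seed in range(6):
            st_ = SaemSettings(n_explore=120, n_smooth=80, seed=seed, rse_samples=300)
            init = PopulationParameters(
                theta_mu={"lam": 2.0}, omega2={"lam": 0.04}, sigma=0.1
            )
            rses = []
            for n_subj in (12, 24):
                series = _toy_constant_series(n_subj, 6, 2.0, 0.04, 0.1, seed=100 + seed)
                fit = _saem_engine(series, _toy_model(), init, st_)
                rses.append(compute_rse(fit, seed=seed)["lam"])
            deltas.append(rses[1] - rses[0])
        assert np.mean(deltas) < 0
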