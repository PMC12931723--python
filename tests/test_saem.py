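"""SAEM engine: closed-form cross-checks, EBEs, likelihood, BICc."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal

from gutpkpd.data import Dataset, ResponseSeries, SubjectRecord
from gutpkpd.errmodels import ErrorModel
from gutpkpd.models import CurveBoundModel
from gutpkpd.saem import (FitResult, PopulationModel, SAEMFitter, bicc,
                          bicc_from_fit, empirical_bayes, fit_saem,
                          importance_sampling_loglik, shrink_random_effects)

TIMES = np.array([0.5, 1.0, 2.0, 4.0, 8.0])


def make_dataset(values_by_subject, times=TIMES, response="plasma"):
    subjects = []
    for i, vals in enumerate(values_by_subject):
        obs = {response: ResponseSeries(times, vals,
                                        np.zeros(len(times), bool),
                                        np.full(len(times), np.nan))}
        subjects.append(SubjectRecord(f"S{i:03d}", "arm", obs, []))
    return Dataset(subjects)


def linear_builder(ds):
    return CurveBoundModel(ds, lambda th, t: th[:, 0] * t, ("slope",))


def loglinear_builder(ds):
    return CurveBoundModel(ds, lambda th, t: np.log(th[:, 0]) * np.ones_like(t),
                           ("level",))


def simulate_linear(rng, n_subj, mu, omega, sigma, times=TIMES):
    theta = mu * np.exp(rng.standard_normal(n_subj) * omega)
    return [theta[i] * times + rng.standard_normal(len(times)) * sigma
            for i in range(n_subj)], theta


class TestSAEMAgainstClosedForms:
    def test_single_parameter_linear_model_matches_wls(self, rng):
        # truth has no interindividual variability, so the marginal MLE of
        # the slope is ordinary least squares on the pooled data
        vals, _ = simulate_linear(rng, 20, mu=2.0, omega=0.0, sigma=0.3)
        ds = make_dataset(vals)
        t_all = np.tile(TIMES, 20)
        y_all = np.concatenate(vals)
        wls = float((t_all * y_all).sum() / (t_all * t_all).sum())
        init = PopulationModel({"slope": 1.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.5)})
        fit = fit_saem(linear_builder, init, ds, n_burn=150, n_smooth=150,
                       seed=3, compute_fim=False)
        assert fit.mu["slope"] == pytest.approx(wls, rel=0.02)

    def test_degenerate_truth_recovered_within_2pct(self, rng):
        vals, _ = simulate_linear(rng, 12, mu=1.7, omega=0.0, sigma=1e-3)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 1.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.1)})
        fit = fit_saem(linear_builder, init, ds, n_burn=120, n_smooth=80,
                       seed=5, compute_fim=False)
        assert fit.mu["slope"] == pytest.approx(1.7, rel=0.02)
        assert fit.omega["slope"] < 0.05

    def test_bit_reproducible_given_seed(self, rng):
        vals, _ = simulate_linear(rng, 8, mu=2.0, omega=0.2, sigma=0.3)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 1.5}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.5)})
        kw = dict(n_burn=40, n_smooth=30, seed=11, compute_fim=True)
        f1 = fit_saem(linear_builder, init, ds, **kw)
        f2 = fit_saem(linear_builder, init, ds, **kw)
        assert f1.mu == f2.mu
        assert f1.omega == f2.omega
        assert np.array_equal(f1.ebe_mean, f2.ebe_mean)

    def test_non_finite_prediction_names_the_subject(self, rng):
        vals, _ = simulate_linear(rng, 3, 2.0, 0.1, 0.2)
        ds = make_dataset(vals)

        def nan_builder(d):
            return CurveBoundModel(
                d, lambda th, t: np.where(th[:, 0] > 0, np.nan, 1.0) * t,
                ("slope",))

        init = PopulationModel({"slope": 2.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.5)})
        with pytest.raises(RuntimeError, match="S000"):
            fit_saem(nan_builder, init, ds, n_burn=5, n_smooth=5, seed=0)

    def test_needs_two_subjects(self):
        ds = make_dataset([np.ones(len(TIMES))])
        init = PopulationModel({"slope": 1.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.5)})
        with pytest.raises(ValueError):
            SAEMFitter(linear_builder, init).fit(ds)


class TestEmpiricalBayes:
    def fit_linear(self, rng, vals):
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.3)})
        fit = fit_saem(linear_builder, init, ds, n_burn=100, n_smooth=80,
                       seed=7, compute_fim=False)
        return ds, fit

    def test_subject_without_observations_gets_population_value(self, rng):
        vals, _ = simulate_linear(rng, 6, 2.0, 0.3, 0.2)
        ds, fit = self.fit_linear(rng, vals)
        empty = SubjectRecord("EMPTY", "arm", {}, [])
        ds2 = Dataset(ds.subjects + [empty])
        theta = empirical_bayes(fit, ds2, fit.model.__class__ and
                                linear_builder(ds2))
        assert theta[-1, 0] == pytest.approx(fit.mu["slope"], rel=1e-6)

    def test_omega_zero_pins_to_population_value(self, rng):
        vals, _ = simulate_linear(rng, 6, 2.0, 0.3, 0.2)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.0},
                               {"plasma": ErrorModel("constant", 0.3)},
                               no_re=("slope",))
        fit = fit_saem(linear_builder, init, ds, n_burn=60, n_smooth=40,
                       seed=9, compute_fim=False)
        theta = empirical_bayes(fit)
        assert np.allclose(theta[:, 0], fit.mu["slope"])

    def test_rich_data_approaches_individual_mle(self, rng):
        times = np.linspace(0.25, 10.0, 120)
        theta_true = 2.6
        vals = [theta_true * times + 0.2 * rng.standard_normal(len(times)),
                1.4 * times + 0.2 * rng.standard_normal(len(times))]
        ds = make_dataset(vals, times=times)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.4},
                               {"plasma": ErrorModel("constant", 0.2)})
        fit = fit_saem(linear_builder, init, ds, n_burn=100, n_smooth=80,
                       seed=13, compute_fim=False)
        theta = empirical_bayes(fit)
        mle = minimize_scalar(
            lambda th: ((vals[0] - th * times) ** 2).sum(),
            bounds=(0.1, 10.0), method="bounded").x
        assert theta[0, 0] == pytest.approx(mle, rel=0.02)


class TestImportanceSampling:
    def test_no_random_effects_gives_exact_loglik(self, rng):
        vals, _ = simulate_linear(rng, 5, 2.0, 0.0, 0.3)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.0},
                               {"plasma": ErrorModel("constant", 0.3)},
                               no_re=("slope",))
        fit = fit_saem(linear_builder, init, ds, n_burn=40, n_smooth=30,
                       seed=1, compute_fim=False)
        ll, se = importance_sampling_loglik(fit, n_samples=10, seed=2)
        # direct computation, no integral
        from scipy.stats import norm
        direct = sum(norm.logpdf(v, fit.mu["slope"] * TIMES,
                                 fit.errors["plasma"].sigma_inter).sum()
                     for v in vals)
        assert ll == pytest.approx(direct, rel=1e-10)
        assert se == 0.0

    def test_matches_analytic_gaussian_marginal(self, rng):
        # y_ij = log(level_i) + eps with level_i = mu*exp(b_i): the marginal
        # of y_i is multivariate normal with compound-symmetric covariance
        mu, omega, sigma = 3.0, 0.4, 0.25
        n_subj, n_t = 12, len(TIMES)
        vals = [np.log(mu) + omega * rng.standard_normal()
                + sigma * rng.standard_normal(n_t) for _ in range(n_subj)]
        ds = make_dataset(vals)
        init = PopulationModel({"level": mu}, {"level": omega},
                               {"plasma": ErrorModel("constant", sigma)})
        # evaluate the likelihood at the INITIAL values (no fitting needed):
        fit = fit_saem(loglinear_builder, init, ds, n_burn=5, n_smooth=5,
                       seed=3, compute_fim=False, freeze=("level",))
        fit.mu["level"], fit.omega["level"] = mu, omega
        fit.errors["plasma"] = ErrorModel("constant", sigma)
        # prior-scale proposal centered at zero: unbiased and simple
        fit.ebe_mean = np.zeros((n_subj, 1))
        fit.ebe_var = np.full((n_subj, 1), omega ** 2)
        ll, se = importance_sampling_loglik(fit, n_samples=4000, seed=4)
        cov = sigma ** 2 * np.eye(n_t) + omega ** 2 * np.ones((n_t, n_t))
        direct = sum(multivariate_normal.logpdf(v, np.full(n_t, np.log(mu)),
                                                cov) for v in vals)
        assert abs(ll - direct) < 3 * max(se, 1e-3)

    def test_se_shrinks_like_sqrt_n(self, rng):
        vals, _ = simulate_linear(rng, 10, 2.0, 0.3, 0.3)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.3)})
        fit = fit_saem(linear_builder, init, ds, n_burn=80, n_smooth=60,
                       seed=5, compute_fim=False)
        _, se1 = importance_sampling_loglik(fit, n_samples=800, seed=6)
        _, se2 = importance_sampling_loglik(fit, n_samples=3200, seed=7)
        assert se2 < se1
        assert se1 / se2 == pytest.approx(2.0, rel=0.5)


class TestBicc:
    def test_hand_computed_value(self):
        val = bicc(-100.0, 20, 200, 3, 2)
        assert val == pytest.approx(200.0 + 3 * np.log(20) + 2 * np.log(200))

    def test_fewer_parameters_win_at_equal_loglik(self):
        small = bicc(-500.0, 30, 400, 2, 2)
        big = bicc(-500.0, 30, 400, 4, 3)
        assert small < big

    def test_no_random_effects_reduces_to_classical_bic(self):
        assert bicc(-50.0, 10, 80, 0, 4) == pytest.approx(
            100.0 + 4 * np.log(80))

    def test_counts_from_fit(self, rng):
        vals, _ = simulate_linear(rng, 6, 2.0, 0.2, 0.3)
        ds = make_dataset(vals)
        init = PopulationModel({"slope": 2.0}, {"slope": 0.3},
                               {"plasma": ErrorModel("constant", 0.3)})
        fit = fit_saem(linear_builder, init, ds, n_burn=40, n_smooth=30,
                       seed=1, compute_fim=False)
        importance_sampling_loglik(fit, n_samples=200, seed=2)
        val = bicc_from_fit(fit)
        # one RE parameter (mu+omega -> log N), error sigma -> log n_obs
        assert val == pytest.approx(-2 * fit.loglik + 2 * np.log(6)
                                    + 1 * np.log(30))


class TestShrinkRandomEffects:
    def make_fit(self, omega, rse):
        return FitResult(
            param_names=("a",), mu={"a": 1.0}, omega={"a": omega},
            errors={}, no_re=(), rse={"omega_a": rse}, cov=None,
            eta_names=("mu_a", "omega_a"), ebe_mean=np.zeros((1, 1)),
            ebe_var=np.ones((1, 1)), trace={}, converged=True, flags=[],
            seed=0, n_subjects=1, n_obs=1)

    @pytest.mark.parametrize("omega,rse,removed", [
        (0.05, 180.0, True),   # small and ill-estimated: removed
        (0.5, 20.0, False),    # large: retained
        (0.05, 15.0, False),   # small but precise: retained (both required)
    ])
    def test_rule_conjunction(self, omega, rse, removed):
        pm, gone = shrink_random_effects(self.make_fit(omega, rse))
        assert (("a" in gone) == removed)
        assert (pm.omega["a"] == 0.0) == removed
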