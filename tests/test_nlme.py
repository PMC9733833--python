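"""Estimation engine: marginal likelihood, OFV, fitting, EBEs, residuals."""

import math

import numpy as np
import pytest

from valpop import (
    ErrorModel,
    ModelSpec,
    Observation,
    OmegaSpec,
    Regimen,
    Subject,
    cwres,
    empirical_bayes_eta,
    fit,
    generate_cohort,
    ofv,
    predict_trough,
    shrinkage,
    simulate_from_model,
    subject_marginal_loglik,
)
from valpop.cohort import CohortConfig
from valpop.io import dataset_from_subjects
from valpop.nlme import LikelihoodKernel, _model_params

from conftest import make_observations

LOG_2PI = math.log(2 * math.pi)


def simple_model(omega=0.2, sigma=10.0):
    return ModelSpec(
        theta={"theta_cl": 0.2, "theta_v": 3.6},
        covariate_terms=[],
        omega=OmegaSpec(omega),
        error=ErrorModel(kind="additive", sigma_add=sigma),
    )


def toy_subjects(n=5, seed=0, omega=0.2, sigma=8.0, n_obs=3):
    """Small cohort drawn from simple_model for oracle comparisons."""
    rng = np.random.default_rng(seed)
    model = simple_model(omega, sigma)
    subs, obs = [], []
    for i in range(n):
        s = Subject(
            id=f"T{i}",
            age_y=float(rng.uniform(1, 12)),
            weight_kg=float(rng.uniform(10, 40)),
            regimen=Regimen(float(rng.choice([125, 250, 375])), 12.0),
        )
        eta = rng.normal(0, omega)
        for _ in range(n_obs):
            dv = predict_trough(model, s, eta) + rng.normal(0, sigma)
            obs.append(Observation(s.id, 12.0, max(dv, 1.0)))
        subs.append(s)
    return model, subs, obs


def brute_force_marginal_loglik(model, subject, observations, n_grid=100_000):
    """Dense trapezoid integration over eta in [-6w, 6w]: the independent
    oracle for the adaptive-quadrature engine.  Works directly from the
    closed-form single-subject prediction, not the engine's kernel."""
    from valpop.structural import PKParameters, steady_state_conc, typical_clearance

    w = model.omega.omega_cl
    sigma = model.error.sigma_add
    etas = np.linspace(-6 * w, 6 * w, n_grid)
    tvcl = model.typical_cl(
        {"AGE": np.array([subject.age_y])}
    )[0] if model.covariate_terms else model.theta["theta_cl"]
    log_joint = -0.5 * (LOG_2PI + 2 * math.log(w)) - etas**2 / (2 * w**2)
    for o in observations:
        f = np.array(
            [
                steady_state_conc(
                    PKParameters(tvcl * math.exp(e), model.theta["theta_v"],
                                 model.ka_fixed_h),
                    subject.regimen,
                    o.time_after_dose_h,
                )
                for e in etas[:: n_grid // 2000 or 1]
            ]
        )
        f = np.interp(etas, etas[:: n_grid // 2000 or 1], f)
        log_joint += -0.5 * (
            LOG_2PI + 2 * math.log(sigma) + ((o.conc_mg_L - f) / sigma) ** 2
        )
    m = log_joint.max()
    return m + math.log(np.trapezoid(np.exp(log_joint - m), etas))


class TestSubjectMarginalLoglik:
    def test_omega_zero_single_obs_zero_residual(self, toy_subject):
        model = simple_model(omega=0.0, sigma=1.0)
        dv = predict_trough(model, toy_subject, 0.0)
        ll = subject_marginal_loglik(model, make_observations(toy_subject, dv), toy_subject)
        assert ll == pytest.approx(-0.5 * LOG_2PI, abs=1e-12)

    def test_doubling_sigma_with_zero_residuals(self, toy_subject):
        model1 = simple_model(omega=0.0, sigma=2.0)
        model2 = simple_model(omega=0.0, sigma=4.0)
        dv = predict_trough(model1, toy_subject, 0.0)
        obs = make_observations(toy_subject, [dv] * 4)
        ll1 = subject_marginal_loglik(model1, obs, toy_subject)
        ll2 = subject_marginal_loglik(model2, obs, toy_subject)
        assert ll2 - ll1 == pytest.approx(-4 * math.log(2), abs=1e-12)

    def test_quadrature_matches_brute_force_integration(self):
        model, subs, obs = toy_subjects(n=5, seed=3)
        for s in subs:
            s_obs = [o for o in obs if o.subject_id == s.id]
            agq = subject_marginal_loglik(model, s_obs, s, n_nodes=41)
            brute = brute_force_marginal_loglik(model, s, s_obs)
            assert agq == pytest.approx(brute, rel=1e-6)

    def test_no_observations_rejected(self, toy_subject):
        with pytest.raises(ValueError):
            subject_marginal_loglik(simple_model(), [], toy_subject)


class TestOFV:
    def test_single_subject_is_minus_two_loglik(self, toy_subject):
        model = simple_model()
        obs = make_observations(toy_subject, [60.0, 70.0])
        ds = dataset_from_subjects([toy_subject], obs)
        ll = subject_marginal_loglik(model, obs, toy_subject)
        assert ofv(model, ds) == pytest.approx(-2 * ll, rel=1e-12)

    def test_additive_over_subjects(self):
        model, subs, obs = toy_subjects(n=6, seed=4)
        whole = ofv(model, dataset_from_subjects(subs, obs))
        half1 = ofv(
            model,
            dataset_from_subjects(
                subs[:3], [o for o in obs if o.subject_id in {s.id for s in subs[:3]}]
            ),
        )
        half2 = ofv(
            model,
            dataset_from_subjects(
                subs[3:], [o for o in obs if o.subject_id in {s.id for s in subs[3:]}]
            ),
        )
        assert whole == pytest.approx(half1 + half2, rel=1e-12)

    def test_omega_zero_closed_form(self, toy_subject):
        sigma = 9.0
        model = simple_model(omega=0.0, sigma=sigma)
        pred = predict_trough(model, toy_subject, 0.0)
        dvs = [pred + 3.0, pred - 5.0, pred]
        ds = dataset_from_subjects([toy_subject], make_observations(toy_subject, dvs))
        expected = sum(
            math.log(2 * math.pi * sigma**2) + (dv - pred) ** 2 / sigma**2 for dv in dvs
        )
        assert ofv(model, ds) == pytest.approx(expected, rel=1e-12)

    def test_engines_agree_on_well_behaved_data(self):
        model, subs, obs = toy_subjects(n=20, seed=5, omega=0.25, n_obs=4)
        ds = dataset_from_subjects(subs, obs)
        assert abs(ofv(model, ds, engine="agq") - ofv(model, ds, engine="foce")) < 1.0


class TestFit:
    def test_zero_noise_recovers_generating_parameters(self):
        gen = simple_model(omega=0.0, sigma=0.0)
        rng = np.random.default_rng(7)
        subs, obs = [], []
        for i in range(25):
            s = Subject(
                id=f"Z{i}", age_y=float(rng.uniform(1, 12)),
                weight_kg=20.0, regimen=Regimen(float(rng.choice([100, 200, 400])), 12.0),
            )
            t = float(rng.uniform(9, 12))
            dv = None
            m = simple_model(omega=0.0, sigma=1.0)
            from valpop.structural import PKParameters, steady_state_conc

            dv = steady_state_conc(
                PKParameters(0.2, 3.6, 1.9), s.regimen, t
            )
            obs.append(Observation(s.id, t, dv))
            subs.append(s)
        ds = dataset_from_subjects(subs, obs)
        template = simple_model(omega=0.0, sigma=0.1)
        fr = fit(
            template, ds,
            inits={"theta_cl": 0.3, "theta_v": 5.0},
            fixed={"omega_cl", "sigma_add"},
            compute_rse=False, compute_ebes=False,
        )
        assert fr.converged
        assert fr.estimates["theta_cl"] == pytest.approx(0.2, rel=1e-3)
        assert fr.estimates["theta_v"] == pytest.approx(3.6, rel=1e-2)

    def test_aic_bic_identities(self, final_fit):
        p = final_fit.n_parameters
        assert final_fit.aic == pytest.approx(final_fit.ofv + 2 * p, rel=1e-12)
        assert final_fit.bic == pytest.approx(
            final_fit.ofv + p * math.log(final_fit.n_obs), rel=1e-12
        )

    def test_multistart_reaches_same_ofv(self, small_cohort, final_model_spec):
        inits_list = [
            {"theta_cl": 0.15, "theta_v": 2.0, "omega_cl": 0.1, "sigma_add": 8.0},
            {"theta_cl": 0.30, "theta_v": 6.0, "omega_cl": 0.3, "sigma_add": 16.0},
            {"theta_cl": 0.214, "theta_v": 3.63, "omega_cl": 0.169, "sigma_add": 11.9},
        ]
        ofvs = []
        for ii in inits_list:
            fr = fit(final_model_spec, small_cohort, inits=ii,
                     compute_rse=False, compute_ebes=False)
            assert fr.converged
            ofvs.append(fr.ofv)
        assert max(ofvs) - min(ofvs) < 0.1

    def test_unknown_init_rejected(self, small_cohort, final_model_spec):
        with pytest.raises(KeyError):
            fit(final_model_spec, small_cohort, inits={"theta_zz": 1.0})

    def test_rse_reported_for_identified_parameters(self, study_cohort, final_model_spec):
        fr = fit(final_model_spec, study_cohort, compute_rse=True, compute_ebes=False)
        assert fr.hessian_pd
        assert 0 < fr.rse_pct["theta_cl"] < 30
        assert 0 < fr.rse_pct["sigma_add"] < 30


class TestEmpiricalBayes:
    def test_no_observations_gives_prior_mode(self, toy_subject):
        assert empirical_bayes_eta(simple_model(), toy_subject, []) == 0.0

    def test_omega_zero_gives_zero(self, toy_subject):
        obs = make_observations(toy_subject, [80.0])
        assert empirical_bayes_eta(simple_model(omega=0.0), toy_subject, obs) == 0.0

    def test_matches_grid_search_maximizer(self, toy_subject):
        model = simple_model(omega=0.25, sigma=6.0)
        obs = make_observations(toy_subject, [40.0, 47.0, 43.0])
        ebe = empirical_bayes_eta(model, toy_subject, obs)
        grid = np.linspace(-1.5, 1.5, 120_001)
        dens = np.zeros_like(grid)
        for k, e in enumerate(grid):
            f = predict_trough(model, toy_subject, e)
            dens[k] = (
                -sum((o.conc_mg_L - f) ** 2 for o in obs) / (2 * 6.0**2)
                - e**2 / (2 * 0.25**2)
            )
        assert ebe == pytest.approx(grid[np.argmax(dens)], abs=1e-4)


class TestShrinkage:
    def test_fully_shrunk(self):
        eta_shr, _ = shrinkage(np.zeros(50), omega_cl=0.2)
        assert eta_shr == pytest.approx(100.0)

    def test_unshrunk_when_sd_equals_omega(self):
        rng = np.random.default_rng(0)
        e = rng.normal(0, 1, 2000)
        e = 0.2 * (e - e.mean()) / e.std(ddof=1)
        eta_shr, _ = shrinkage(e, omega_cl=0.2)
        assert eta_shr == pytest.approx(0.0, abs=1e-9)

    def test_omega_zero_undefined(self):
        eta_shr, eps_shr = shrinkage(np.zeros(10), omega_cl=0.0)
        assert eta_shr is None and eps_shr is None

    def test_rich_data_low_shrinkage(self):
        cfg = CohortConfig(n_subjects=30, obs_per_subject_probs={20: 1.0})
        ds = generate_cohort(cfg, seed=21)
        from valpop.datasets import final_model

        fr = fit(final_model(), ds, compute_rse=False)
        assert fr.eta_shrinkage_pct < 15.0


class TestCWRES:
    def test_omega_zero_reduces_to_weighted_residual(self, toy_subject):
        sigma = 7.0
        model = simple_model(omega=0.0, sigma=sigma)
        pred = predict_trough(model, toy_subject, 0.0)
        dvs = [pred + 7.0, pred - 14.0]
        ds = dataset_from_subjects([toy_subject], make_observations(toy_subject, dvs))
        recs = cwres(model, None, ds)
        assert [r.cwres for r in recs] == pytest.approx([1.0, -2.0], abs=1e-9)
        assert [r.pred for r in recs] == pytest.approx([pred, pred])

    def test_standard_normal_under_true_model(self, final_model_spec, study_cohort):
        sim = simulate_from_model(study_cohort, final_model_spec, seed=17)
        recs = cwres(final_model_spec, None, sim)
        cw = np.array([r.cwres for r in recs])
        assert abs(cw.mean()) < 0.15
        assert 0.85 < cw.std(ddof=1) < 1.15
        assert np.mean(np.abs(cw) <= 2.0) >= 0.93


class TestKernelInternals:
    def test_conditional_mode_has_zero_gradient(self, study_cohort, final_model_spec):
        kern = LikelihoodKernel(study_cohort, final_model_spec)
        params = _model_params(final_model_spec)
        mode, h = kern.conditional_mode(params)
        d = 1e-5
        grad = (kern._penalized(params, mode + d) - kern._penalized(params, mode - d)) / (
            2 * d
        )
        assert np.max(np.abs(grad)) < 1e-4
        assert np.all(h > 0)
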