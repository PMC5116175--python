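"""Mixed-effects estimation: joint likelihood closed forms, the Laplace
approximation against numerical quadrature, degenerate reductions, and
model selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

import lactopk as lk
from lactopk.model import (DoseEvent, PKParams, milk_cumulative_closed,
                           plasma_conc_closed)
from lactopk.nlme import (PopulationModel, _SubjectData, compare_models,
                          default_initials, fit_population, foce_objective,
                          individual_neg2ll, laplace_neg2ll, subject_data)


def one_obs_subject(theta, t=48.0, y=None):
    doses = [DoseEvent(0.0, 2.2e8)]
    f = plasma_conc_closed(theta, doses, np.array([t]))[0]
    return _SubjectData(sid="s1", study="market",
                        dose_times=np.array([0.0]), dose_amts=np.array([2.2e8]),
                        t_plasma=np.array([t]),
                        y_plasma=np.array([f if y is None else y]),
                        t_milk=np.empty(0), y_milk=np.empty(0)), f


def gh_oracle(pop, sd, n_nodes=40):
    """-2 log marginal likelihood by mode-centred Gauss-Hermite quadrature
    (1 or 2 free etas), independent of the Laplace path."""
    d = sum(1 for v in pop.omega.values() if v > 0)
    joint = lambda e: individual_neg2ll(pop, sd, np.asarray(e, dtype=float))
    res = minimize(joint, np.zeros(d), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    c = res.x
    m0 = res.fun
    # per-dimension curvature for the quadrature scale
    h = 1e-3
    scale = np.empty(d)
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        curv = (joint(c + e) - 2 * m0 + joint(c - e)) / h ** 2  # of -2LL
        scale[i] = np.sqrt(2.0 / max(curv, 1e-12))
    u, w = np.polynomial.hermite.hermgauss(n_nodes)
    if d == 1:
        vals = np.array([joint(c + scale * ui) for ui in u])
        I = scale[0] * np.sum(w * np.exp(-0.5 * (vals - m0) + u ** 2))
    else:
        I = 0.0
        for ui, wi in zip(u, w):
            for uj, wj in zip(u, w):
                e = c + scale * np.array([ui, uj])
                I += wi * wj * np.exp(-0.5 * (joint(e) - m0) + ui ** 2 + uj ** 2)
        I *= scale[0] * scale[1]
    return m0 - 2.0 * np.log(I)


class TestJointLikelihood:
    def test_single_exact_observation_closed_form(self, theta_ref):
        sd, f = one_obs_subject(theta_ref)
        pop = PopulationModel(theta=theta_ref, omega={},
                              sigma={"plasma_conc": 0.3})
        val = individual_neg2ll(pop, sd, np.zeros(6))
        assert val == pytest.approx(np.log(2 * np.pi) + np.log(0.3 ** 2 * f ** 2),
                                    rel=1e-12)

    def test_prior_term_added_for_free_eta(self, theta_ref):
        sd, f = one_obs_subject(theta_ref)
        pop = PopulationModel(theta=theta_ref, omega={"Cl": 0.5},
                              sigma={"plasma_conc": 0.3})
        eta = np.array([0.2])
        base_pop = PopulationModel(theta=theta_ref, omega={},
                                   sigma={"plasma_conc": 0.3})
        with_eta = individual_neg2ll(pop, sd, eta)
        # subtracting the prior contribution must leave the data term at eta
        prior = eta[0] ** 2 / 0.5 + np.log(2 * np.pi * 0.5)
        full_eta = np.zeros(6)
        full_eta[1] = eta[0]  # Cl position in the 2cpt ordering
        data_term = individual_neg2ll(base_pop, sd, full_eta)
        assert with_eta == pytest.approx(data_term + prior, rel=1e-12)

    def test_proportional_scaling_shift(self, theta_ref):
        # scaling y and f by s shifts the proportional -2LL by 2 n log s
        sd, f = one_obs_subject(theta_ref, y=None)
        sd_scaled = _SubjectData(sid="s", study="market",
                                 dose_times=sd.dose_times,
                                 dose_amts=sd.dose_amts * 10.0,
                                 t_plasma=sd.t_plasma,
                                 y_plasma=sd.y_plasma * 10.0,
                                 t_milk=sd.t_milk, y_milk=sd.y_milk)
        pop = PopulationModel(theta=theta_ref, omega={},
                              sigma={"plasma_conc": 0.3})
        v1 = individual_neg2ll(pop, sd, np.zeros(6))
        v2 = individual_neg2ll(pop, sd_scaled, np.zeros(6))
        assert v2 - v1 == pytest.approx(2 * 1 * np.log(10.0), rel=1e-10)


class TestLaplaceVsQuadrature:
    @pytest.mark.parametrize("omega", [{"Cl": 0.2}, {"V": 0.3, "Cl": 0.2}])
    def test_laplace_within_2pct_of_quadrature(self, pop_ref, small_lactating_ds,
                                               omega):
        sd = subject_data(small_lactating_ds)[0]
        pop = PopulationModel(theta=pop_ref.theta, omega=omega,
                              sigma={"plasma_conc": 0.3, "milk_cumamount": 0.1})
        lap, _ = laplace_neg2ll(pop, sd)
        q = gh_oracle(pop, sd)
        assert lap == pytest.approx(q, rel=0.02)


class TestFoceObjective:
    def test_reduces_to_pooled_at_zero_omega(self, pop_ref, small_lactating_ds):
        pop = PopulationModel(theta=pop_ref.theta, omega={},
                              sigma={"plasma_conc": 0.3, "milk_cumamount": 0.1})
        sds = subject_data(small_lactating_ds)
        pooled = sum(individual_neg2ll(pop, sd, np.zeros(6)) for sd in sds)
        assert foce_objective(pop, sds) == pooled

    def test_subject_order_invariance(self, pop_ref, small_lactating_ds):
        pop = PopulationModel(theta=pop_ref.theta, omega={"Cl": 0.2},
                              sigma={"plasma_conc": 0.3, "milk_cumamount": 0.1})
        sds = subject_data(small_lactating_ds)
        assert foce_objective(pop, sds) == pytest.approx(
            foce_objective(pop, sds[::-1]), rel=1e-12)


class TestFitPopulation:
    def test_pooled_single_subject_matches_direct_curve_fit(self, pop_ref):
        # a typical (eta = 0) subject keeps the single-subject ELS problem
        # well conditioned; with extreme absorption draws it is multimodal
        from lactopk.dataset import StudyDataset
        from lactopk.generate import generate_study
        pop_typ = PopulationModel(theta=pop_ref.theta, omega={},
                                  sigma=pop_ref.sigma)
        ds = generate_study("singledose_lactating", pop_typ, seed=3,
                            residual=True)
        ds1 = StudyDataset(subjects=[ds.subjects[0]])
        init = default_initials(ds1, "2cpt")
        init = PopulationModel(theta=init.theta, omega={},
                               sigma={"plasma_conc": 0.485,
                                      "milk_cumamount": 0.0234})
        fit = fit_population(ds1, init=init, fit_omega=False, fit_sigma=False,
                             maxiter=2000, outer_tol=1e-16, fd_step=1e-7)
        # independent oracle: extended least squares written from scratch
        sd = subject_data(ds1)[0]
        doses = [DoseEvent(t, a) for t, a in zip(sd.dose_times, sd.dose_amts)]

        def els(logtheta):
            th = PKParams(**dict(zip(init.param_names, np.exp(logtheta))))
            fp = plasma_conc_closed(th, doses, sd.t_plasma)
            fm = milk_cumulative_closed(th, doses, sd.t_milk)
            out = 0.0
            for y, f, sig in ((sd.y_plasma, fp, 0.485), (sd.y_milk, fm, 0.0234)):
                var = (sig * f) ** 2
                out += np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var)
            return out

        x0 = np.log(fit.estimates.theta_array()) + 0.05
        res = minimize(els, x0, method="Nelder-Mead",
                       options={"xatol": 1e-11, "fatol": 1e-13,
                                "maxiter": 40000, "maxfev": 40000})
        assert fit.estimates.theta_array() == pytest.approx(np.exp(res.x),
                                                            rel=1e-4)

    def test_aic_bic_identities(self, pop_ref, small_lactating_ds):
        fit = fit_population(small_lactating_ds, maxiter=3)
        assert fit.aic == pytest.approx(fit.neg2ll + 2 * fit.n_params)
        assert fit.bic == pytest.approx(fit.neg2ll
                                        + fit.n_params * np.log(fit.n_obs))

    def test_proportional_beats_additive_on_proportional_data(self, pop_ref):
        from lactopk.generate import generate_study
        ds = generate_study("market", pop_ref, seed=9, residual=True)
        fits = []
        for em in ("proportional", "additive"):
            fits.append(fit_population(
                ds, error_models={"plasma_conc": em, "milk_cumamount": em},
                maxiter=40, dataset_tag="em"))
        aic = {f.estimates.error_model["plasma_conc"]: f.aic for f in fits}
        assert aic["proportional"] < aic["additive"]


class TestCompareModels:
    def _fake_fit(self, aic_target, structure="2cpt", tag="x", theta=None):
        pop = PopulationModel(theta=theta, omega={}, sigma={"plasma_conc": 0.3},
                              structure=structure)
        from lactopk.nlme import FitResult
        return FitResult(estimates=pop, neg2ll=aic_target - 2 * 7, n_obs=100,
                         n_params=7, etas={}, converged=True, n_outer_iter=1,
                         dataset_tag=tag)

    def test_lowest_aic_selected(self, theta_ref):
        fits = [self._fake_fit(a, theta=theta_ref) for a in (104.0, 100.0, 130.0)]
        df = compare_models(fits)
        assert df.loc[0, "aic"] == pytest.approx(100.0 + 0)
        assert df.loc[0, "selected"]
        assert not df["selected"][1:].any()

    def test_single_fit_selected(self, theta_ref):
        df = compare_models([self._fake_fit(50.0, theta=theta_ref)])
        assert df.loc[0, "selected"]

    def test_mismatched_datasets_rejected(self, theta_ref):
        f1 = self._fake_fit(100.0, tag="a", theta=theta_ref)
        f2 = self._fake_fit(101.0, tag="b", theta=theta_ref)
        with pytest.raises(ValueError, match="dataset"):
            compare_models([f1, f2])

    def test_two_compartments_win_on_biphasic_data(self, pop_ref):
        # dense plasma sampling resolves the distribution phase
        from lactopk.generate import generate_study
        ds = generate_study("market", pop_ref, seed=5, residual=True)
        f2 = fit_population(ds, structure="2cpt", maxiter=40, dataset_tag="m")
        f1 = fit_population(ds, structure="1cpt", maxiter=40, dataset_tag="m")
        df = compare_models([f1, f2])
        assert df.loc[0, "structure"] == "2cpt"
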