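"""Mixed-effects machinery: likelihood, estimation, SEs, post hoc etas."""

import numpy as np
import pytest

from dorpk import nlme
from dorpk.structural import ThetaVector
from dorpk.synthetic import SimulationConfig, simulate_trial
from dorpk.trial_data import AnalysisConfig, DosingRegimen, PKRecord, Subject
from helpers import conc_superposition

ANA = AnalysisConfig()


def plain_model(tvcl=5.66, tvv=150.0, tvka=1.0, omega=(0.22, 0.12, 0.40), sigma=0.20):
    """Covariate-free population model (betas null)."""
    return nlme.PopulationModel(
        theta=ThetaVector(tvcl, tvv, tvka),
        omega2=tuple(w * w for w in omega),
        sigma_prop=sigma,
    )


def simulate_plain(n, seed, schedule="rich", omega=(0.22, 0.12, 0.40), sigma=0.20):
    cfg = SimulationConfig(
        n_subjects=n, seed=seed, schedule=schedule,
        true_model=plain_model(omega=omega, sigma=sigma),
    )
    rec, subs, _, truth = simulate_trial(cfg, ANA)
    return cfg, rec, subs, truth


BETA_FIX = ("beta_wt_v", "beta_hiv_v", "beta_age_cl")


class TestMarginalLikelihood:
    def test_zero_omega_reduces_to_residual_likelihood(self):
        _, rec, subs, _ = simulate_plain(4, seed=3, omega=(0.2, 0.2, 0.2))
        m0 = plain_model(omega=(0.0, 0.0, 0.0))
        got = nlme.marginal_neg2ll(m0, rec, subs, ANA)
        # independent: residual -2LL at typical values, superposition model
        design = nlme.build_design(rec, subs, ANA)
        tot = 0.0
        for k in range(design.y.size):
            f = conc_superposition(
                design.u[k], design.n_dose[k], 5.66, 150.0, 1.0, design.dose, design.tau
            )
            var = (0.20 * f) ** 2
            tot += (design.y[k] - f) ** 2 / var + np.log(2 * np.pi * var)
        assert abs(got - tot) / abs(tot) < 1e-10

    def test_duplicating_subjects_doubles_the_objective(self):
        _, rec, subs, _ = simulate_plain(6, seed=4, schedule="sparse")
        m = plain_model()
        base = nlme.marginal_neg2ll(m, rec, subs, ANA)
        rec2 = rec + [
            PKRecord(r.subject_id + "x", r.time, r.amt, r.dv, r.evid, r.mdv, r.time_after_dose)
            for r in rec
        ]
        subs2 = subs + [
            Subject(s.subject_id + "x", s.weight, s.age, s.status, s.group) for s in subs
        ]
        double = nlme.marginal_neg2ll(m, rec2, subs2, ANA)
        assert abs(double - 2 * base) / abs(2 * base) < 1e-9

    def test_objective_invariant_to_subject_ordering(self):
        _, rec, subs, _ = simulate_plain(5, seed=5, schedule="sparse")
        m = plain_model()
        base = nlme.marginal_neg2ll(m, rec, subs, ANA)
        order = [3, 1, 4, 0, 2]
        subs_p = [subs[i] for i in order]
        rec_p = []
        for s in subs_p:
            rec_p += [r for r in rec if r.subject_id == s.subject_id]
        assert np.isclose(nlme.marginal_neg2ll(m, rec_p, subs_p, ANA), base, rtol=1e-10)

    def test_objective_invariant_to_time_unit_rescaling(self):
        """Hours -> minutes with CL, V, ka, tau rescaled consistently leaves
        the likelihood unchanged (concentrations are the same numbers)."""
        _, rec, subs, _ = simulate_plain(4, seed=6, schedule="sparse")
        m = plain_model()
        base = nlme.marginal_neg2ll(m, rec, subs, ANA)
        rec_min = [
            PKRecord(r.subject_id, r.time * 60, r.amt, r.dv, r.evid, r.mdv,
                     None if r.time_after_dose is None else r.time_after_dose * 60)
            for r in rec
        ]
        ana_min = AnalysisConfig(regimen=DosingRegimen(tau=24 * 60))
        m_min = nlme.PopulationModel(
            theta=ThetaVector(5.66 / 60, 150.0, 1.0 / 60),
            omega2=m.omega2,
            sigma_prop=m.sigma_prop,
        )
        assert np.isclose(nlme.marginal_neg2ll(m_min, rec_min, subs, ana_min), base, rtol=1e-8)


class TestFit:
    def test_noiseless_rich_data_identifies_theta(self):
        cfg, rec, subs, _ = simulate_plain(50, seed=7, omega=(0, 0, 0), sigma=1e-4)
        init = nlme.PopulationModel(
            theta=ThetaVector(4.0, 110.0, 1.4), omega2=(0.0, 0.0, 0.0), sigma_prop=1e-4
        )
        fit = nlme.fit_population(init, rec, subs, ANA, fix=BETA_FIX + ("sigma_prop",))
        est = nlme.model_to_dict(fit.model)
        for name, truth in (("tvcl", 5.66), ("tvv", 150.0), ("tvka", 1.0)):
            assert abs(est[name] - truth) / truth < 0.005, name

    def test_fitted_optimum_beats_random_parameter_points(self):
        cfg, rec, subs, _ = simulate_plain(20, seed=8)
        init = plain_model(4.5, 120.0, 1.3, omega=(0.3, 0.3, 0.3), sigma=0.3)
        fit = nlme.fit_population(init, rec, subs, ANA, fix=BETA_FIX)
        rng = np.random.default_rng(1)
        for _ in range(20):
            jitter = np.exp(rng.uniform(-0.5, 0.5, 5))
            m = plain_model(
                5.66 * jitter[0], 150.0 * jitter[1], 1.0 * jitter[2],
                omega=(0.22 * jitter[3], 0.12 * jitter[3], 0.40 * jitter[3]),
                sigma=0.2 * jitter[4],
            )
            assert fit.neg2ll <= nlme.marginal_neg2ll(m, rec, subs, ANA) + 1e-6

    def test_degenerate_inputs_raise(self):
        _, rec, subs, _ = simulate_plain(4, seed=9)
        with pytest.raises(ValueError):
            nlme.fit_population(plain_model(), rec[:10], subs[:1], ANA)
        flat = [
            PKRecord(r.subject_id, r.time, r.amt, 100.0 if r.evid == 0 else None,
                     r.evid, r.mdv, r.time_after_dose)
            for r in rec
        ]
        with pytest.raises(ValueError, match="degenerate"):
            nlme.fit_population(plain_model(), flat, subs, ANA)


class TestStandardErrors:
    def test_doubling_data_shrinks_se_by_sqrt2(self):
        _, rec, subs, _ = simulate_plain(40, seed=10)
        fix = BETA_FIX + ("omega2_cl", "omega2_v", "omega2_ka", "sigma_prop")
        init = plain_model(5.0, 140.0, 1.1)
        fit1 = nlme.fit_population(init, rec, subs, ANA, fix=fix)
        se1 = nlme.standard_errors(fit1, rec, subs, ANA)
        rec2 = rec + [
            PKRecord(r.subject_id + "x", r.time, r.amt, r.dv, r.evid, r.mdv, r.time_after_dose)
            for r in rec
        ]
        subs2 = subs + [
            Subject(s.subject_id + "x", s.weight, s.age, s.status, s.group) for s in subs
        ]
        fit2 = nlme.fit_population(init, rec2, subs2, ANA, fix=fix)
        se2 = nlme.standard_errors(fit2, rec2, subs2, ANA)
        for name in ("tvcl", "tvv", "tvka"):
            ratio = se2[name] / se1[name]
            assert abs(ratio - 1 / np.sqrt(2)) < 0.15 * (1 / np.sqrt(2)), (name, ratio)

    def test_se_shrinks_with_residual_noise(self):
        ses = []
        for sigma in (0.2, 0.1, 0.05):
            _, rec, subs, _ = simulate_plain(30, seed=11, omega=(0, 0, 0), sigma=sigma)
            init = nlme.PopulationModel(
                theta=ThetaVector(5.0, 140.0, 1.1), omega2=(0, 0, 0), sigma_prop=sigma
            )
            fit = nlme.fit_population(init, rec, subs, ANA, fix=BETA_FIX + ("sigma_prop",))
            ses.append(nlme.standard_errors(fit, rec, subs, ANA)["tvcl"])
        assert ses[0] > ses[1] > ses[2]

    def test_one_parameter_toy_matches_hand_curvature(self):
        """With only log(TVCL) free and no random effects, the SE must equal
        the inverse square-root curvature of an independently coded -logL."""
        _, rec, subs, _ = simulate_plain(2, seed=12, omega=(0, 0, 0), sigma=0.2)
        fix = tuple(n for n in nlme.PARAM_NAMES if n != "tvcl")
        init = nlme.PopulationModel(
            theta=ThetaVector(5.0, 150.0, 1.0), omega2=(0, 0, 0), sigma_prop=0.2
        )
        fit = nlme.fit_population(init, rec, subs, ANA, fix=fix)
        se = nlme.standard_errors(fit, rec, subs, ANA)["tvcl"]

        design = nlme.build_design(rec, subs, ANA)

        def negll(log_tvcl):
            cl = np.exp(log_tvcl)
            tot = 0.0
            for k in range(design.y.size):
                f = conc_superposition(
                    design.u[k], design.n_dose[k], cl, 150.0, 1.0, design.dose, design.tau
                )
                var = (0.2 * f) ** 2
                tot += 0.5 * ((design.y[k] - f) ** 2 / var + np.log(2 * np.pi * var))
            return tot

        x = np.log(fit.model.theta.tvcl)
        h = 1e-4
        curv = (negll(x + h) - 2 * negll(x) + negll(x - h)) / h**2
        se_hand = fit.model.theta.tvcl / np.sqrt(curv)  # delta method to natural scale
        assert abs(se - se_hand) / se_hand < 1e-3


class TestEmpiricalBayes:
    def test_zero_observation_subject_returns_typical_values(self):
        _, rec, subs, _ = simulate_plain(3, seed=13, schedule="sparse")
        ghost = Subject("GHOST", 70.0, 45.0)
        rec_g = rec + [PKRecord("GHOST", 0.0, amt=234880.0, evid=1, mdv=1)]
        m = plain_model()
        ebes = nlme.empirical_bayes(m, rec_g, subs + [ghost], ANA)
        i = ebes.subject_ids.index("GHOST")
        assert ebes.no_observations[i]
        assert np.allclose(ebes.eta[i], 0.0)
        assert np.isclose(ebes.cl[i], 5.66) and np.isclose(ebes.v[i], 150.0)

    def test_noiseless_limit_recovers_individual_truth(self):
        cfg, rec, subs, truth = simulate_plain(10, seed=14, sigma=1e-4)
        m = plain_model(sigma=1e-4)
        ebes = nlme.empirical_bayes(m, rec, subs, ANA)
        assert np.max(np.abs(ebes.cl - truth.cl) / truth.cl) < 0.01
        assert np.max(np.abs(ebes.v - truth.v) / truth.v) < 0.01
        assert np.max(np.abs(ebes.ka - truth.ka) / truth.ka) < 0.01


class TestShrinkage:
    def test_all_zero_etas_mean_full_shrinkage(self):
        ebes = nlme.EBEResult(
            subject_ids=[str(i) for i in range(20)],
            eta=np.zeros((20, 3)),
            cl=np.ones(20), v=np.ones(20), ka=np.ones(20),
            no_observations=np.zeros(20, bool),
        )
        s = nlme.eta_shrinkage(ebes, plain_model())
        assert all(np.isclose(v, 100.0) for v in s.values())

    def test_prior_samples_show_no_shrinkage(self):
        rng = np.random.default_rng(2)
        m = plain_model()
        eta = rng.normal(0, 1, (1000, 3)) * np.sqrt(m.omega2)
        ebes = nlme.EBEResult(
            subject_ids=[str(i) for i in range(1000)], eta=eta,
            cl=np.ones(1000), v=np.ones(1000), ka=np.ones(1000),
            no_observations=np.zeros(1000, bool),
        )
        s = nlme.eta_shrinkage(ebes, m)
        assert all(abs(v) < 10.0 for v in s.values())

    def test_zero_omega_reports_not_applicable(self):
        m = plain_model(omega=(0.22, 0.0, 0.40))
        ebes = nlme.EBEResult(
            subject_ids=["a", "b"], eta=np.zeros((2, 3)),
            cl=np.ones(2), v=np.ones(2), ka=np.ones(2),
            no_observations=np.zeros(2, bool),
        )
        s = nlme.eta_shrinkage(ebes, m)
        assert s["eta_v"] is None and s["eta_cl"] is not None

    def test_sparse_sampling_inflates_ka_shrinkage(self):
        m = plain_model()
        _, rec_r, subs_r, _ = simulate_plain(40, seed=15, schedule="rich")
        _, rec_s, subs_s, _ = simulate_plain(40, seed=15, schedule="sparse")
        rich = nlme.empirical_bayes(m, rec_r, subs_r, ANA).shrinkage["eta_ka"]
        # single trough per subject: keep only the week-4 predose sample
        seen = set()
        rec_1 = []
        for r in rec_s:
            if r.evid == 1 or not r.usable_for_fitting:
                rec_1.append(r)
            elif r.subject_id not in seen and r.time_after_dose == 24.0:
                seen.add(r.subject_id)
                rec_1.append(r)
        sparse = nlme.empirical_bayes(m, rec_1, subs_s, ANA).shrinkage["eta_ka"]
        assert sparse > rich


class TestReplicateRecovery:
    def test_tvcl_recovery_and_wald_coverage_across_replicates(self):
        """Across 12 seeded rich-design replicates (60 subjects each) the
        median relative error of typical CL/F stays below 5% and the 95%
        Wald interval covers the truth in at least 10 of 12."""
        fix = BETA_FIX
        omega = (0.30, 0.25, 0.40)  # well inside the interior at this n
        errors, covered = [], 0
        for rep in range(12):
            _, rec, subs, _ = simulate_plain(60, seed=100 + rep, omega=omega)
            init = plain_model(4.5, 120.0, 1.3, omega=(0.35, 0.35, 0.35), sigma=0.25)
            fit = nlme.fit_population(init, rec, subs, ANA, fix=fix)
            se = nlme.standard_errors(fit, rec, subs, ANA)
            est = fit.model.theta.tvcl
            errors.append(abs(est - 5.66) / 5.66)
            if se is not None and abs(est - 5.66) <= 1.96 * se["tvcl"]:
                covered += 1
        assert np.median(errors) < 0.05
        assert covered >= 10


def test_residual_table_columns_and_consistency():
    _, rec, subs, _ = simulate_plain(5, seed=16, schedule="sparse")
    m = plain_model()
    tab = nlme.residual_table(m, rec, subs, ANA)
    assert set(tab.columns) >= {"ID", "DV", "PRED", "IPRED", "IWRES"}
    assert len(tab) == sum(r.usable_for_fitting for r in rec)
    assert np.all(tab["IPRED"] > 0)
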