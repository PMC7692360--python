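"""Mixed-effects objective, fitting, model comparison and bootstrap."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from dexpk.model_core import DEFAULT_THETA, DoseEvent, PKParameters, concentrations
from dexpk.synthetic_data import (
    DEFAULT_OMEGA,
    DEFAULT_RESIDUAL,
    OmegaSpec,
    PopulationDataset,
    ResidualSpec,
    design_library,
    simulate_trial,
)
from dexpk.estimation import (
    FitConfig,
    bootstrap,
    empirical_bayes,
    fit,
    lrt,
    objective,
    shrinkage,
    stratified_resample,
    variance_decomposition,
)


def _els_m2ll(ds, theta, residual):
    """Extended-least-squares -2LL of the fixed-effects model (no BSV)."""
    from dexpk.model_core import individual_parameters

    total = 0.0
    for s in ds.subjects:
        p = individual_parameters(theta, s.covariates)
        f = concentrations(p, s.events, s.obs_times)
        g2 = f**2 * residual.theta_ruv_cv**2 + residual.theta_ruv_sd**2
        total += np.sum((s.dv - f) ** 2 / g2 + np.log(2 * np.pi * g2))
    return total


class TestObjective:
    def test_zero_omega_reduces_to_els(self, small_trial):
        omega = OmegaSpec(omega2={})
        got = objective(small_trial, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        want = _els_m2ll(small_trial, DEFAULT_THETA, DEFAULT_RESIDUAL)
        assert got == pytest.approx(want, abs=1e-6)

    def test_matches_gauss_hermite_quadrature(self, adult_trial_one_eta):
        # single eta on CL, few observations: Laplace vs 64-node adaptive
        # Gauss-Hermite marginalisation through the interpreted kinetics
        ds, omega, residual = adult_trial_one_eta
        sub = ds.subjects[0]
        sub.obs_times = sub.obs_times[:3]
        sub.dv = sub.dv[:3]
        single = PopulationDataset(subjects=[sub])
        got = objective(single, DEFAULT_THETA, omega, residual)

        from dexpk.model_core import individual_parameters

        typ = individual_parameters(DEFAULT_THETA, sub.covariates)
        om2 = omega.omega2["cl"]
        cv2, sd2 = residual.theta_ruv_cv**2, residual.theta_ruv_sd**2

        def loglik(eta):
            p = PKParameters(
                cl=typ.cl * np.exp(eta), v1=typ.v1, v2=typ.v2, v3=typ.v3, q2=typ.q2, q3=typ.q3
            )
            f = concentrations(p, sub.events, sub.obs_times)
            g2 = f * f * cv2 + sd2
            return -0.5 * np.sum((sub.dv - f) ** 2 / g2 + np.log(2 * np.pi * g2))

        neg_joint = lambda e: -(loglik(e) - 0.5 * e * e / om2)
        mode = minimize_scalar(neg_joint, bounds=(-4, 4), method="bounded",
                               options={"xatol": 1e-10}).x
        curv = (neg_joint(mode + 1e-4) - 2 * neg_joint(mode) + neg_joint(mode - 1e-4)) / 1e-8
        nodes, weights = np.polynomial.hermite.hermgauss(64)
        scale = np.sqrt(2.0 / curv)
        logvals = np.array(
            [loglik(mode + scale * x) - 0.5 * (mode + scale * x) ** 2 / om2 for x in nodes]
        )
        log_terms = logvals + nodes**2 + np.log(weights)
        m = log_terms.max()
        log_integral = m + np.log(np.sum(np.exp(log_terms - m))) + np.log(scale)
        ref = -2.0 * (log_integral - 0.5 * np.log(2 * np.pi * om2))
        assert abs(got - ref) < 0.5

    def test_truth_beats_perturbed(self):
        ds = simulate_trial(
            DEFAULT_THETA, DEFAULT_OMEGA, DEFAULT_RESIDUAL, design_library(), 50, seed=21
        )
        omega = OmegaSpec(omega2={k: DEFAULT_OMEGA.omega2[k] for k in ("cl", "v1", "v3")})
        at_truth = objective(ds, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        perturbed = DEFAULT_THETA.replace(cl_std=0.897 * 1.5, v1_std=25.2 * 1.5)
        at_perturbed = objective(ds, perturbed, omega, DEFAULT_RESIDUAL)
        assert at_truth < at_perturbed

    def test_invariant_to_subject_order(self, small_trial):
        omega = OmegaSpec(omega2={"cl": 0.1, "v1": 0.3})
        a = objective(small_trial, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        shuffled = PopulationDataset(subjects=list(reversed(small_trial.subjects)))
        b = objective(shuffled, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        assert a == pytest.approx(b, abs=1e-8)

    def test_invariant_to_time_rescaling(self, small_trial):
        # hours instead of minutes with consistently rescaled clearances
        omega = OmegaSpec(omega2={"cl": 0.1})
        a = objective(small_trial, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        import copy

        scaled = copy.deepcopy(small_trial)
        for s in scaled.subjects:
            s.obs_times = np.asarray(s.obs_times) / 60.0
            s.events = [
                DoseEvent(start=ev.start / 60.0, duration=ev.duration / 60.0,
                          rate=ev.rate * 60.0 if ev.duration > 0 else ev.rate)
                for ev in s.events
            ]
        theta_h = DEFAULT_THETA.replace(
            cl_std=0.897 * 60, q2_std=1.68 * 60, q3_std=0.62 * 60
        )
        b = objective(scaled, theta_h, omega, DEFAULT_RESIDUAL)
        assert a == pytest.approx(b, rel=1e-9)

    def test_rejects_noise_free_residual(self, small_trial):
        with pytest.raises(ValueError):
            objective(
                small_trial, DEFAULT_THETA, OmegaSpec(omega2={}),
                ResidualSpec(theta_ruv_cv=0.0, theta_ruv_sd=0.0),
            )


class TestFit:
    def test_recovers_theta_from_noise_free_data(self):
        # deterministic inverse problem: no BSV, no residual noise
        omega = OmegaSpec(omega2={})
        clean = ResidualSpec(theta_ruv_cv=0.0, theta_ruv_sd=0.0)
        ds = simulate_trial(DEFAULT_THETA, omega, clean, design_library(["cortinez"]), 10, seed=2)
        init = DEFAULT_THETA.replace(cl_std=0.897 * 1.3, v1_std=25.2 * 0.7)
        config = FitConfig(
            theta_names=("cl_std", "v1_std"), estimate_omega=False,
            estimate_residual_cv=False, compute_ci=False,
            fd_step=1e-6, gtol=1e-8,
        )
        # tiny assumed error: the weighting's log-variance term displaces the
        # optimum from exact interpolation by O(cv^2)
        res = fit(ds, (init, omega, ResidualSpec(theta_ruv_cv=0.01)), config)
        assert res.theta.cl_std == pytest.approx(0.897, rel=1e-3)
        assert res.theta.v1_std == pytest.approx(25.2, rel=1e-3)

    def test_recovers_typical_values_with_bsv(self):
        omega_gen = OmegaSpec(omega2={"cl": 0.358**2, "v1": 0.5**2})
        ds = simulate_trial(
            DEFAULT_THETA, omega_gen, DEFAULT_RESIDUAL, design_library(["rolle", "cortinez"]), 40, seed=8
        )
        init = DEFAULT_THETA.replace(cl_std=0.897 * 1.5, v1_std=25.2 * 0.6)
        config = FitConfig(theta_names=("cl_std", "v1_std"), compute_ci=False)
        res = fit(ds, (init, OmegaSpec(omega2={"cl": 0.1, "v1": 0.1}), ResidualSpec(theta_ruv_cv=0.3)), config)
        assert res.converged
        assert res.theta.cl_std == pytest.approx(0.897, rel=0.15)
        assert res.theta.v1_std == pytest.approx(25.2, rel=0.3)
        assert 0 <= res.shrinkage_pct["cl"] <= 100

    def test_tm50_not_estimable_on_adults(self):
        # adults only: every PMA is far above TM50, the maturation plateau
        ds = simulate_trial(
            DEFAULT_THETA, OmegaSpec(omega2={"cl": 0.1}), DEFAULT_RESIDUAL,
            design_library(["rolle"]), 20, seed=13,
        )
        config = FitConfig(theta_names=("cl_std", "tm50"), estimate_omega=False,
                           estimate_residual_cv=False)
        res = fit(ds, (DEFAULT_THETA, OmegaSpec(omega2={"cl": 0.1}), DEFAULT_RESIDUAL), config)
        se = res.theta_se.get("tm50", float("nan"))
        rel_ci_width = (
            (res.theta_ci["tm50"][1] - res.theta_ci["tm50"][0]) / res.theta.tm50
            if "tm50" in res.theta_ci
            else float("nan")
        )
        assert np.isnan(se) or rel_ci_width > 1.0

    def test_nested_model_never_worse(self):
        # the maturation covariate was used in generation: adding it cannot
        # raise the optimal -2LL
        ds = simulate_trial(
            DEFAULT_THETA, OmegaSpec(omega2={"cl": 0.13}), DEFAULT_RESIDUAL,
            design_library(["potts"]), 30, seed=31,
        )
        omega0 = OmegaSpec(omega2={"cl": 0.1})
        resid0 = ResidualSpec(theta_ruv_cv=0.25)
        reduced_cfg = FitConfig(theta_names=("cl_std",), compute_ci=False)
        # reduced model: maturation absent (MF pinned at ~1 via tiny TM50)
        no_mat = DEFAULT_THETA.replace(tm50=1e-6)
        res_reduced = fit(ds, (no_mat, omega0, resid0), reduced_cfg)
        full_cfg = FitConfig(theta_names=("cl_std", "tm50"), compute_ci=False)
        res_full = fit(ds, (DEFAULT_THETA.replace(tm50=30.0), omega0, resid0), full_cfg)
        assert res_full.obj <= res_reduced.obj + 0.1
        decision = lrt(res_reduced.obj, res_full.obj, 1)
        assert decision.delta_obj > 0


class TestLrt:
    def test_threshold_boundary(self):
        assert lrt(100.0, 96.15, 1).significant  # delta 3.85
        assert not lrt(100.0, 96.16, 1).significant  # delta 3.84 exactly: strict
        assert lrt(100.0, 96.16, 1).threshold == pytest.approx(3.8415, abs=1e-3)

    def test_two_df_threshold(self):
        assert lrt(10.0, 0.0, 2).threshold == pytest.approx(stats.chi2.ppf(0.95, 2), rel=1e-12)
        assert lrt(10.0, 0.0, 2).threshold == pytest.approx(5.99, abs=0.005)

    def test_negative_delta_warns(self):
        with pytest.warns(UserWarning, match="optimisation failure"):
            lrt(100.0, 101.0, 1)


class TestShrinkage:
    def test_fully_informative(self):
        omega2 = 0.16
        ebe = np.array([-1.0, 1.0]) * np.sqrt(omega2) / np.sqrt(2)  # sample SD = omega
        assert shrinkage(ebe, omega2) == pytest.approx(0.0, abs=1e-9)

    def test_no_information(self):
        assert shrinkage(np.zeros(10), 0.16) == pytest.approx(100.0)

    def test_zero_omega_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(shrinkage(np.array([0.1, -0.1]), 0.0))

    def test_sparser_design_shrinks_more(self):
        omega = OmegaSpec(omega2={"cl": 0.358**2})
        rich = simulate_trial(DEFAULT_THETA, omega, DEFAULT_RESIDUAL,
                              design_library(["cortinez"]), 30, seed=17)
        import copy

        sparse = copy.deepcopy(rich)
        for s in sparse.subjects:  # keep only the two earliest samples,
            s.obs_times = s.obs_times[:2]  # which carry little CL information
            s.dv = s.dv[:2]
        ebe_rich = empirical_bayes(rich, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        ebe_sparse = empirical_bayes(sparse, DEFAULT_THETA, omega, DEFAULT_RESIDUAL)
        assert shrinkage(ebe_sparse["cl"], omega.omega2["cl"]) > shrinkage(
            ebe_rich["cl"], omega.omega2["cl"]
        )


class TestVarianceDecomposition:
    @pytest.mark.parametrize(
        "ppvt2, bsvr2, bsvp2, ratio",
        [
            (0.861, 0.140, 0.721, 0.8374),
            (0.861, 0.114, 0.747, 0.8676),
            (0.5, 0.5, 0.0, 0.0),
        ],
    )
    def test_values(self, ppvt2, bsvr2, bsvp2, ratio):
        vd = variance_decomposition(ppvt2, bsvr2)
        assert vd.bsvp2 == pytest.approx(bsvp2, abs=1e-9)
        assert vd.ratio == pytest.approx(ratio, abs=5e-4)

    def test_clamps_excess_random_variance(self):
        with pytest.warns(UserWarning, match="clamped"):
            vd = variance_decomposition(0.5, 0.6)
        assert vd.ratio == 0.0

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            variance_decomposition(0.0, 0.1)
        with pytest.raises(ValueError):
            variance_decomposition(0.5, -0.1)


class TestBootstrap:
    def test_identical_subjects_give_zero_width_ci(self):
        omega = OmegaSpec(omega2={})
        clean = ResidualSpec(theta_ruv_cv=0.0, theta_ruv_sd=0.0)
        base = simulate_trial(DEFAULT_THETA, omega, clean, design_library(["talke"]), 1, seed=3)
        clones = PopulationDataset(subjects=[base.subjects[0]] * 6)
        config = FitConfig(theta_names=("cl_std",), estimate_omega=False,
                           estimate_residual_cv=False, compute_ci=False)
        res = bootstrap(
            clones, 3, seed=0,
            initial_values=(DEFAULT_THETA.replace(cl_std=1.2), omega, ResidualSpec(theta_ruv_cv=0.05)),
            config=config,
        )
        lo, hi = res.ci95["cl_std"]
        assert hi - lo < 1e-6
        assert res.n_converged == 3

    def test_stratified_resampling_preserves_counts(self, small_trial):
        rng = np.random.default_rng(0)
        counts = {k: len(v) for k, v in small_trial.by_study().items()}
        for _ in range(5):
            rep = stratified_resample(small_trial, rng)
            assert {k: len(v) for k, v in rep.by_study().items()} == counts

    def test_rejects_zero_reps(self, small_trial):
        with pytest.raises(ValueError):
            bootstrap(small_trial, 0, 0, (DEFAULT_THETA, OmegaSpec(omega2={"cl": 0.1}), DEFAULT_RESIDUAL))
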