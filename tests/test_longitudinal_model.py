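"""Mixed-model fitting: recovery, invariances, and oracle agreement.

The package's REML/ML optimizer is checked against statsmodels MixedLM (an
independent implementation) on fixed fixtures, and against the generating
truth in simulation.
"""

import numpy as np
import pandas as pd
import pytest

from cvrsearch.longitudinal_model import (
    RandomSlopeModel,
    center_time,
    fit_lmm,
    group_separation,
    lrt_random_correlation,
    repeatability_percent,
)


def simulate_frame(
    n_subjects=30,
    beta=(0.2, 0.01, 0.05, 0.03),
    sigma_b0=0.05,
    sigma_b1=0.02,
    rho=0.5,
    sigma_eps=0.03,
    visits=3,
    seed=0,
):
    """Draw observations directly from the trajectory model."""
    rng = np.random.default_rng(seed)
    cov = np.array(
        [[sigma_b0**2, rho * sigma_b0 * sigma_b1],
         [rho * sigma_b0 * sigma_b1, sigma_b1**2]]
    )
    rows = []
    for j in range(n_subjects):
        dx = float(j >= n_subjects // 2)
        t = np.sort(rng.uniform(0.0, 3.0, visits))
        u = rng.multivariate_normal([0.0, 0.0], cov)
        tc = t - t.mean()
        y = (
            beta[0] + beta[1] * tc + beta[2] * dx + beta[3] * tc * dx
            + u[0] + u[1] * tc + rng.normal(0, sigma_eps, visits)
        )
        for ti, yi in zip(t, y):
            rows.append(dict(subject_id=f"s{j:03d}", scan_time=ti, log_value=yi,
                             group="CI" if dx else "CU"))
    return pd.DataFrame(rows)


class TestCenterTime:
    def test_times_centred_per_subject(self):
        df = pd.DataFrame(
            dict(subject_id=["a", "a"], scan_time=[70.0, 71.5],
                 log_value=[0.1, 0.2], group=["CU", "CU"])
        )
        frame = center_time(df)
        np.testing.assert_allclose(sorted(frame.frame["time"]), [-0.75, 0.75])
        assert abs(frame.frame.groupby("subject_id")["time"].mean()).max() < 1e-12

    def test_shift_invariance(self):
        df = simulate_frame(n_subjects=6, seed=1)
        shifted = df.copy()
        shifted.loc[shifted.subject_id == "s000", "scan_time"] += 10.0
        f0, f1 = center_time(df), center_time(shifted)
        pd.testing.assert_frame_equal(f0.frame, f1.frame)

    def test_missing_group_label_rejected(self):
        df = simulate_frame(n_subjects=4).drop(columns="group")
        with pytest.raises(ValueError, match="group"):
            center_time(df, groups={"s000": "CU"})


class TestFitRecovery:
    def test_noise_free_data_interpolated_exactly(self):
        df = simulate_frame(n_subjects=10, sigma_b0=0, sigma_b1=0, rho=0,
                            sigma_eps=1e-12, beta=(1.0, 0.05, 0.0, 0.02), seed=2)
        fit = fit_lmm(center_time(df))
        np.testing.assert_allclose(fit.beta, [1.0, 0.05, 0.0, 0.02], atol=1e-6)
        assert fit.sigma_eps < 1e-5
        assert np.max(np.abs(fit.resid)) < 1e-6
        assert repeatability_percent(fit) < 1e-3

    def test_simulation_recovery_within_monte_carlo_error(self):
        # moderate replicate count; bias must stay within 3 MC standard errors
        truth = np.array([0.2, 0.01, 0.05, 0.03])
        estimates = []
        for rep in range(40):
            df = simulate_frame(n_subjects=120, seed=100 + rep)
            fit = fit_lmm(center_time(df))
            assert fit.converged
            estimates.append(fit.beta)
        est = np.asarray(estimates)
        bias = est.mean(axis=0) - truth
        mcse = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(bias) < 3 * mcse + 1e-12)

    def test_variance_components_recovered(self):
        df = simulate_frame(n_subjects=400, visits=4, seed=5)
        fit = fit_lmm(center_time(df))
        assert fit.sigma_b0 == pytest.approx(0.05, rel=0.3)
        assert fit.sigma_eps == pytest.approx(0.03, rel=0.15)
        assert -1 <= fit.rho <= 1

    def test_metric_time_shift_invariance(self):
        df = simulate_frame(n_subjects=30, seed=3)
        shifted = df.copy()
        shifted["scan_time"] += np.where(shifted.subject_id == "s003", 7.3, 0.0)
        f0 = fit_lmm(center_time(df))
        f1 = fit_lmm(center_time(shifted))
        assert group_separation(f0) == pytest.approx(group_separation(f1), rel=1e-6)
        assert repeatability_percent(f0) == pytest.approx(repeatability_percent(f1), rel=1e-6)
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-6)


class TestStatsmodelsOracle:
    @pytest.mark.parametrize("reml", [True, False])
    def test_loglik_and_beta_agree_on_fixture(self, reml):
        import statsmodels.formula.api as smf

        df = simulate_frame(n_subjects=30, seed=42)
        frame = center_time(df).frame
        fit = fit_lmm(center_time(df), reml=reml)
        sm = smf.mixedlm(
            "y ~ time * dx", frame, groups=frame["subject_id"], re_formula="~time"
        ).fit(reml=reml, method="lbfgs")
        assert fit.loglik == pytest.approx(sm.llf, abs=1e-4)
        np.testing.assert_allclose(fit.beta, sm.fe_params.values, atol=1e-4)
        np.testing.assert_allclose(fit.cov_re, sm.cov_re.values, atol=1e-4)

    def test_loglik_agrees_on_two_visit_heavy_design(self):
        import statsmodels.formula.api as smf

        df = simulate_frame(n_subjects=25, visits=2, sigma_b1=0.005, seed=9)
        frame = center_time(df).frame
        fit = fit_lmm(center_time(df))
        sm = smf.mixedlm(
            "y ~ time * dx", frame, groups=frame["subject_id"], re_formula="~time"
        ).fit(reml=True, method="lbfgs")
        assert fit.loglik >= sm.llf - 1e-4  # never worse than the oracle's optimum


class TestGroupSeparation:
    def test_sign_conventions(self):
        df = simulate_frame(n_subjects=60, beta=(0.2, 0.01, 0.0, 0.04),
                            sigma_eps=0.02, seed=6)
        fit = fit_lmm(center_time(df))
        t = group_separation(fit)
        assert t > 0
        flipped = df.assign(log_value=-df.log_value)
        t_neg = group_separation(fit_lmm(center_time(flipped)))
        assert t_neg == pytest.approx(-t, rel=1e-6)

    def test_equal_slopes_give_near_zero_t(self):
        df = simulate_frame(n_subjects=80, beta=(0.2, 0.02, 0.05, 0.0), seed=7)
        assert abs(group_separation(fit_lmm(center_time(df)))) < 3.0


class TestRepeatability:
    def test_matches_planted_residual_scale(self):
        df = simulate_frame(n_subjects=150, visits=6, sigma_eps=0.02, seed=8)
        fit = fit_lmm(center_time(df))
        # many visits -> little shrinkage; ~2% error
        assert repeatability_percent(fit) == pytest.approx(2.0, rel=0.2)

    def test_invariant_to_global_biomarker_scaling(self):
        df = simulate_frame(n_subjects=30, seed=10)
        f0 = fit_lmm(center_time(df))
        f1 = fit_lmm(center_time(df.assign(log_value=df.log_value + np.log(37.0))))
        assert repeatability_percent(f0) == pytest.approx(repeatability_percent(f1), abs=1e-8)


class TestCorrelationLrt:
    def test_chi2_nonnegative_by_nesting(self):
        df = simulate_frame(n_subjects=40, rho=0.0, seed=11)
        chi2, dof, p = lrt_random_correlation(center_time(df))
        assert chi2 >= 0 and dof == 1 and 0 <= p <= 1

    def test_detects_strong_correlation(self):
        hits = 0
        for rep in range(25):
            df = simulate_frame(n_subjects=200, rho=0.8, sigma_b1=0.03,
                                visits=4, seed=200 + rep)
            chi2, _, p = lrt_random_correlation(center_time(df))
            hits += p < 0.05
        assert hits >= 20  # power > 80%

    def test_type_i_error_near_nominal(self):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            df = simulate_frame(n_subjects=100, rho=0.0, sigma_b1=0.03,
                                visits=4, seed=500 + rep)
            _, _, p = lrt_random_correlation(center_time(df))
            hits += p < 0.05
        # near-boundary chi2(1) reference is slightly conservative
        assert hits <= np.ceil(0.05 * n_rep + 3 * np.sqrt(n_rep * 0.05 * 0.95))


class TestSimulateMethod:
    def test_model_simulate_round_trips_variances(self):
        df = simulate_frame(n_subjects=300, visits=4, seed=12)
        frame = center_time(df).frame
        model = RandomSlopeModel(
            frame["subject_id"].to_numpy(), frame["time"].to_numpy(), frame["dx"].to_numpy()
        )
        rng = np.random.default_rng(0)
        cov = np.array([[0.05**2, 0.0], [0.0, 0.02**2]])
        y = model.simulate(np.array([0.2, 0.01, 0.05, 0.03]), cov, 0.02, rng)
        refit = model.fit(y)
        assert refit.sigma_eps == pytest.approx(0.02, rel=0.15)
        assert refit.sigma_b0 == pytest.approx(0.05, rel=0.25)
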