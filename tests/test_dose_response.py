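"""Probit fitting, LCp intervals, Abbott correction and the decay fit."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from cutox.dose_response import (Lc50Estimate, ToxicityTrial, abbott_correct,
                                 fit_probit, fit_time_decay, lc_p,
                                 read_trial_csv, write_trial_csv)

from conftest import random_trial


class TestFitProbit:
    def test_symmetric_design_puts_lc50_at_middle_dose(self, symmetric_trial):
        # 0/10, 5/10, 10/10 at log-equispaced doses: the probit line must
        # cross 0.5 exactly at the middle dose.
        fit = fit_probit(symmetric_trial, 96.0)
        est = lc_p(fit, 0.5)
        assert est.point == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("factor", [10.0, 0.2, 3.7])
    def test_dose_scale_equivariance(self, factor):
        trial = random_trial(11)
        scaled = ToxicityTrial(
            concentrations=tuple(c * factor for c in trial.concentrations),
            n_exposed=trial.n_exposed, times_h=trial.times_h,
            deaths=trial.deaths)
        est = lc_p(fit_probit(trial, 96.0), 0.5)
        est_s = lc_p(fit_probit(scaled, 96.0), 0.5)
        assert est_s.point == pytest.approx(est.point * factor, rel=1e-8)
        assert fit_probit(scaled, 96.0).beta == pytest.approx(
            fit_probit(trial, 96.0).beta, rel=1e-8)

    def test_matches_statsmodels_glm(self):
        # Independent cross-check: binomial GLM with probit link.
        sm = pytest.importorskip("statsmodels.api")
        trial = random_trial(3)
        fit = fit_probit(trial, 96.0)
        y = trial.deaths[:, 0]
        n = np.asarray(trial.n_exposed)
        X = sm.add_constant(np.log10(trial.concentrations))
        glm = sm.GLM(np.column_stack([y, n - y]), X,
                     family=sm.families.Binomial(sm.families.links.Probit()))
        res = glm.fit()
        assert fit.alpha == pytest.approx(res.params[0], abs=1e-5)
        assert fit.beta == pytest.approx(res.params[1], abs=1e-5)

    def test_mle_beats_local_grid(self):
        # Likelihood at the reported MLE is >= likelihood on a grid around it.
        trial = random_trial(8)
        fit = fit_probit(trial, 96.0)
        x = np.log10(trial.concentrations)
        y, n = trial.deaths[:, 0], np.asarray(trial.n_exposed)

        def ll(a, b):
            p = np.clip(norm.cdf(a + b * x), 1e-12, 1 - 1e-12)
            return np.sum(y * np.log(p) + (n - y) * np.log1p(-p))

        grid_ll = max(
            ll(fit.alpha + da, fit.beta + db)
            for da in np.linspace(-0.5, 0.5, 21)
            for db in np.linspace(-0.5, 0.5, 21))
        assert fit.loglik >= grid_ll - 1e-9

    def test_separated_grid_is_flagged(self):
        trial = ToxicityTrial(
            concentrations=(0.1, 0.2, 1.0, 2.0),
            n_exposed=(10.0,) * 4, times_h=(96.0,),
            deaths=np.array([[0.0], [0.0], [10.0], [10.0]]))
        fit = fit_probit(trial, 96.0)
        assert fit.separation
        assert not fit.converged

    def test_rejects_uninformative_trials(self):
        dead = ToxicityTrial(
            concentrations=(0.1, 1.0), n_exposed=(10.0, 10.0),
            times_h=(96.0,), deaths=np.array([[10.0], [10.0]]))
        with pytest.raises(ValueError, match="all-dead|partial"):
            fit_probit(dead, 96.0)
        single = ToxicityTrial(
            concentrations=(1.0,), n_exposed=(10.0,), times_h=(96.0,),
            deaths=np.array([[5.0]]))
        with pytest.raises(ValueError, match="2 dosed groups"):
            fit_probit(single, 96.0)

    def test_refuses_uncorrected_control_mortality(self):
        trial = ToxicityTrial(
            concentrations=(0.1, 1.0, 10.0), n_exposed=(10.0,) * 3,
            times_h=(96.0,), deaths=np.array([[1.0], [5.0], [9.0]]),
            control_n=10.0, control_deaths=(2.0,))
        with pytest.raises(ValueError, match="abbott"):
            fit_probit(trial, 96.0)


class TestLcP:
    @staticmethod
    def make_fit(alpha, beta):
        from cutox.dose_response import ProbitFit

        return ProbitFit(alpha=alpha, beta=beta, cov=np.eye(2) * 1e-2,
                         loglik=0.0, converged=True, n_doses=5, time_h=96.0)

    def test_closed_form_point(self):
        # alpha=0, beta=2: the line crosses Phi^-1(0.5)=0 at log10 dose 0.
        assert lc_p(self.make_fit(0.0, 2.0), 0.5).point == pytest.approx(1.0)

    def test_point_is_root_of_fitted_curve(self):
        fit = fit_probit(random_trial(21), 96.0)
        est = lc_p(fit, 0.5)
        root = brentq(lambda d: fit.predict(d) - 0.5, 1e-6, 1e6)
        assert est.point == pytest.approx(root, rel=1e-9)

    def test_monotone_in_p(self):
        fit = fit_probit(random_trial(13), 96.0)
        points = [lc_p(fit, p).point for p in (0.1, 0.25, 0.5, 0.75, 0.9)]
        assert np.all(np.diff(points) > 0)

    @pytest.mark.parametrize("method", ["delta", "fieller"])
    def test_ci_brackets_point(self, method):
        for seed in (2, 9, 31):
            est = lc_p(fit_probit(random_trial(seed), 96.0), 0.5, method=method)
            assert est.ci_low <= est.point <= est.ci_high
            assert est.ci_low > 0

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            lc_p(self.make_fit(0.0, 2.0), 0.0)
        with pytest.raises(ValueError, match="slope"):
            lc_p(self.make_fit(0.0, -1.0), 0.5)


class TestAbbott:
    def make_trial(self, control_deaths):
        return ToxicityTrial(
            concentrations=(0.1, 1.0), n_exposed=(10.0, 10.0),
            times_h=(96.0,), deaths=np.array([[6.0], [8.0]]),
            control_n=10.0, control_deaths=control_deaths)

    def test_zero_control_is_identity(self):
        trial = self.make_trial((0.0,))
        assert abbott_correct(trial) is trial

    def test_arithmetic(self):
        # control 2/10, treatment 6/10 -> (0.6 - 0.2)/0.8 = 0.5
        corrected = abbott_correct(self.make_trial((2.0,)))
        assert corrected.deaths[0, 0] == pytest.approx(5.0)
        assert corrected.control_deaths == (0.0,)

    def test_complete_control_mortality_rejected(self):
        with pytest.raises(ValueError, match="control"):
            abbott_correct(self.make_trial((10.0,)))

    def test_correction_preserves_zero_control_fit(self):
        trial = random_trial(17)
        with_control = ToxicityTrial(
            concentrations=trial.concentrations, n_exposed=trial.n_exposed,
            times_h=trial.times_h, deaths=trial.deaths,
            control_n=10.0, control_deaths=(0.0,))
        f1 = fit_probit(with_control, 96.0)
        f2 = fit_probit(abbott_correct(with_control), 96.0)
        assert (f1.alpha, f1.beta) == (f2.alpha, f2.beta)

    def test_corrected_counts_stay_cumulative(self):
        trial = ToxicityTrial(
            concentrations=(0.5, 1.0), n_exposed=(10.0, 10.0),
            times_h=(24.0, 48.0),
            deaths=np.array([[2.0, 3.0], [5.0, 7.0]]),
            control_n=10.0, control_deaths=(1.0, 3.0))
        corrected = abbott_correct(trial)
        assert np.all(np.diff(corrected.deaths, axis=1) >= 0)


class TestTimeDecay:
    def test_noiseless_recovery(self):
        t = np.array([24.0, 48.0, 72.0, 96.0])
        fit = fit_time_decay(list(zip(t, 2.0 * np.exp(-0.01 * t))))
        assert fit.amplitude == pytest.approx(2.0, rel=1e-10)
        assert fit.rate == pytest.approx(0.01, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_ols(self):
        # Simple-regression formulas on the ln scale, to 1e-10.
        pairs = [(24.0, 1.039), (48.0, 0.792), (72.0, 0.734), (96.0, 0.655)]
        t = np.array([p[0] for p in pairs])
        ly = np.log([p[1] for p in pairs])
        sxx = np.sum((t - t.mean()) ** 2)
        slope = np.sum((t - t.mean()) * (ly - ly.mean())) / sxx
        intercept = ly.mean() - slope * t.mean()
        fit = fit_time_decay(pairs)
        assert fit.rate == pytest.approx(-slope, abs=1e-10)
        assert fit.amplitude == pytest.approx(np.exp(intercept), abs=1e-10)

    def test_accepts_estimate_objects(self):
        ests = [Lc50Estimate(time_h=t, p=0.5, point=v, ci_low=v, ci_high=v)
                for t, v in [(24, 1.0), (48, 0.8), (72, 0.7), (96, 0.6)]]
        assert fit_time_decay(ests).n_points == 4

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError, match="3"):
            fit_time_decay([(24.0, 1.0), (48.0, 0.5)])
        with pytest.raises(ValueError, match="positive"):
            fit_time_decay([(24.0, 1.0), (48.0, -0.5), (72.0, 0.3)])


class TestTrialIO:
    def test_csv_round_trip(self, tmp_path, study_design, study_truth):
        from cutox.synthetic import simulate_trial

        trial = simulate_trial(study_design, study_truth, 42)
        path = tmp_path / "trial.csv"
        write_trial_csv(trial, path)
        back = read_trial_csv(path)
        assert back.concentrations == trial.concentrations
        assert np.array_equal(back.deaths, trial.deaths)
        assert back.control_deaths == trial.control_deaths

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            ToxicityTrial(concentrations=(1.0, 2.0), n_exposed=(10.0, 10.0),
                          times_h=(24.0, 48.0),
                          deaths=np.array([[3.0, 2.0], [5.0, 5.0]]))
        with pytest.raises(ValueError, match="positive"):
            ToxicityTrial(concentrations=(-1.0, 2.0), n_exposed=(10.0, 10.0),
                          times_h=(24.0,), deaths=np.zeros((2, 1)))
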