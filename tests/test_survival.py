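"""Parametric survival families, likelihoods, fitting and schedules."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from bmicohort.survival import (
    EstimationError,
    FitResult,
    N_PARAMS,
    ParametricModel,
    TransitionSchedule,
    build_schedule,
    fit_parametric,
    log_likelihood,
    select_family,
    survival_function,
    yearly_tp,
)
from bmicohort.states import InvalidInputError
from bmicohort.synthetic import simulate_survival_records

LN = ParametricModel("lognormal", [3.16, 1.22])


class TestSurvivalFunction:
    def test_s0_is_one_for_all_families(self):
        params = {
            "exponential": [0.1], "weibull": [-2.0, 1.5], "lognormal": [1.0, 0.8],
            "loglogistic": [1.0, 0.5], "gompertz": [0.05, 0.02],
            "gengamma": [1.0, 0.8, 0.5],
        }
        for fam, p in params.items():
            m = ParametricModel(fam, p)
            assert survival_function(m, 0.0) == 1.0
            s = m.sf(np.linspace(0, 50, 200))
            assert np.all(np.diff(s) <= 1e-12), fam  # non-increasing
            assert np.all((s >= 0) & (s <= 1)), fam

    def test_lognormal_closed_form(self):
        # S(1) = 1 - Phi(-3.16/1.22), high-precision normal CDF
        expected = float(special.ndtr(3.16 / 1.22))
        assert survival_function(LN, 1.0) == pytest.approx(expected, abs=1e-12)
        assert survival_function(LN, 1.0) == pytest.approx(0.99520, abs=5e-6)

    def test_exponential_closed_form(self):
        m = ParametricModel("exponential", [0.1])
        assert survival_function(m, 10.0) == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            survival_function(LN, -0.5)

    def test_gengamma_nests_lognormal_and_weibull(self):
        t = np.linspace(0.1, 30, 50)
        ln = ParametricModel("lognormal", [2.0, 0.9]).sf(t)
        gg_ln = ParametricModel("gengamma", [2.0, 0.9, 1e-8]).sf(t)
        assert np.allclose(ln, gg_ln, atol=1e-6)
        # weibull(b0, p) corresponds to gengamma kappa = 1, sigma = 1/p,
        # mu = -b0/p
        b0, p = -2.0, 1.5
        wb = ParametricModel("weibull", [b0, p]).sf(t)
        gg_wb = ParametricModel("gengamma", [-b0 / p, 1 / p, 1.0]).sf(t)
        assert np.allclose(wb, gg_wb, atol=1e-10)


class TestYearlyTP:
    def test_published_child_sequence(self):
        """lognormal(3.16, 1.22) from entry age 2 gives 0.49/1.70/2.46%…"""
        ps = [yearly_tp(LN, 2, a) for a in range(2, 12)]
        assert ps[0] == pytest.approx(0.0048, abs=2e-4)
        assert ps[1] == pytest.approx(0.0170, abs=2e-4)
        assert ps[2] == pytest.approx(0.0246, abs=2e-4)
        assert np.mean(ps) == pytest.approx(0.0272, abs=2e-4)

    def test_no_event_mass_gives_zero(self):
        m = ParametricModel("exponential", [0.0])
        assert yearly_tp(m, 2, 50) == 0.0

    def test_probabilities_in_unit_interval_and_telescoping(self):
        """Survivorship after T cycles from the tp sequence equals S(T)."""
        for fam, p in [("weibull", [-4.5, 1.85]), ("gompertz", [0.04, 0.00141]),
                       ("lognormal", [3.16, 1.22])]:
            m = ParametricModel(fam, p)
            ages = np.arange(20, 60)
            tps = np.array([yearly_tp(m, 20, a) for a in ages])
            assert np.all((tps >= 0) & (tps <= 1))
            surv = np.prod(1 - tps)
            assert surv == pytest.approx(float(m.sf(40.0)), rel=1e-10)


class TestLogLikelihood:
    def test_exponential_event_closed_form(self):
        lam = 0.3
        m = ParametricModel("exponential", [lam])
        got = log_likelihood(m, [0.0], [1.0], [True])
        assert got == pytest.approx(np.log(lam) - lam, rel=1e-12)

    def test_truncation_reduces_to_exposure(self):
        lam = 0.2
        m = ParametricModel("exponential", [lam])
        got = log_likelihood(m, [2.0], [5.0], [False])
        assert got == pytest.approx(-3 * lam, rel=1e-12)

    def test_lognormal_against_quadrature_oracle(self):
        """Density and survival terms agree with numerical integration of f."""
        m = ParametricModel("lognormal", [1.2, 0.7])
        rng = np.random.default_rng(5)
        entry = rng.uniform(0, 1, 100)
        exit = entry + rng.uniform(0.5, 8, 100)
        event = rng.random(100) < 0.5

        def pdf(t):
            return np.exp(-0.5 * ((np.log(t) - 1.2) / 0.7) ** 2) / (
                t * 0.7 * np.sqrt(2 * np.pi)
            )

        def sf_num(t):
            val, _ = integrate.quad(pdf, t, np.inf, limit=200)
            return val

        oracle = 0.0
        for e, x, ev in zip(entry, exit, event):
            oracle += np.log(pdf(x)) if ev else np.log(sf_num(x))
            if e > 0:
                oracle -= np.log(sf_num(e))
        got = log_likelihood(m, entry, exit, event)
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            log_likelihood(LN, [2.0], [2.0], [True])


class TestFitting:
    def test_exponential_mle_closed_form(self):
        """Fitted rate equals events / total at-risk exposure exactly."""
        rec = pd.DataFrame({
            "entry": [0.0, 1.0, 0.0, 2.0],
            "exit": [3.0, 4.0, 2.0, 6.0],
            "event": [True, False, True, True],
        })
        fit = fit_parametric(rec, "exponential", 0.0)
        exposure = (rec.exit - rec.entry).sum()
        assert fit.model.params[0] == pytest.approx(3 / exposure, rel=1e-5)

    def test_lognormal_parameter_recovery(self):
        rec = simulate_survival_records(5000, LN, seed=42)
        fit = fit_parametric(rec, "lognormal", 0.0)
        assert fit.model.params[0] == pytest.approx(3.16, abs=0.06)
        assert fit.model.params[1] == pytest.approx(1.22, abs=0.06)
        # covariance is available and positive on the diagonal
        assert fit.model.cov is not None
        assert np.all(np.diag(fit.model.cov) > 0)

    def test_all_censored_raises(self):
        rec = pd.DataFrame({"entry": [0.0] * 5, "exit": [2.0] * 5, "event": [False] * 5})
        with pytest.raises(EstimationError):
            fit_parametric(rec, "weibull", 0.0)

    def test_aic_bic_identity(self):
        rec = simulate_survival_records(400, LN, seed=1)
        for fam in ("exponential", "lognormal"):
            fit = fit_parametric(rec, fam, 0.0)
            k = N_PARAMS[fam]
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k, rel=1e-12)
            assert fit.bic == pytest.approx(
                -2 * fit.loglik + k * np.log(fit.n_records), rel=1e-12
            )

    def test_matches_lifelines_left_truncated_fit(self):
        """Independent cross-check: lifelines' lognormal MLE with entry times."""
        lifelines = pytest.importorskip("lifelines")
        rec = simulate_survival_records(2000, LN, seed=9)
        fit = fit_parametric(rec, "lognormal", 0.0)
        lf = lifelines.LogNormalFitter().fit(
            rec.exit, rec.event, entry=rec.entry
        )
        assert fit.model.params[0] == pytest.approx(lf.mu_, abs=1e-3)
        assert fit.model.params[1] == pytest.approx(lf.sigma_, abs=1e-3)


class TestSelection:
    def _fit(self, aic, family="weibull"):
        params = {1: [0.5], 2: [0.0, 1.0], 3: [0.0, 1.0, 0.5]}[N_PARAMS[family]]
        return FitResult(ParametricModel(family, params),
                         loglik=0.0, aic=aic, bic=aic, n_records=10, n_events=5)

    def test_minimal_aic_wins(self):
        fits = [self._fit(100.0), self._fit(98.0, "lognormal"), self._fit(103.0, "gompertz")]
        assert select_family(fits).aic == 98.0

    def test_tie_broken_by_fewer_params(self):
        fits = [self._fit(98.0, "gengamma"), self._fit(98.0, "weibull")]
        assert select_family(fits).model.family == "weibull"

    def test_all_failed_raises(self):
        bad = self._fit(100.0)
        bad.converged = False
        with pytest.raises(EstimationError):
            select_family([bad])


class TestSchedule:
    def test_child_band_decade_means_match_published(self, default_models):
        sched = build_schedule(default_models)
        # women NW->OW ages 2..11 mean = 2.72 %
        ages = np.arange(2, 12)
        v = [sched.probability("female", 1, a) for a in ages]
        assert np.mean(v) == pytest.approx(0.0272, abs=5e-4)
        v = [sched.probability("female", 2, a) for a in ages]
        assert np.mean(v) == pytest.approx(0.0285, abs=5e-4)

    def test_band_splice_at_13_and_20(self, default_models):
        sched = build_schedule(default_models)
        assert sched.band_of(12) == "child"
        assert sched.band_of(13) == "adolescent"
        assert sched.band_of(19) == "adolescent"
        assert sched.band_of(20) == "adult"
        assert sched.provenance[("female", 1, "child")] == "lognormal"
        assert sched.provenance[("female", 1, "adolescent")] == "weibull"

    def test_missing_cell_raises_with_name(self, default_models):
        broken = dict(default_models)
        del broken[("female", 3, "adult")]
        with pytest.raises(Exception, match="OB1-OB2"):
            build_schedule(broken)

    def test_roundtrip_through_csv(self, default_models, tmp_path):
        sched = build_schedule(default_models)
        path = tmp_path / "sched.csv"
        sched.to_csv(path)
        back = TransitionSchedule.from_csv(path)
        for key, v in sched.probs.items():
            assert np.allclose(back.probs[key], v)


class TestSerialization:
    def test_model_roundtrip_with_covariance(self, default_models, tmp_path):
        from bmicohort.survival import load_models, save_models
        models = dict(default_models)
        key = ("female", 1, "child")
        m = models[key]
        models[key] = ParametricModel(m.family, m.params,
                                      np.array([[0.01, 0.001], [0.001, 0.02]]))
        path = tmp_path / "models.json"
        save_models(models, path)
        back = load_models(path)
        assert back.keys() == models.keys()
        assert np.allclose(back[key].params, models[key].params)
        assert np.allclose(back[key].cov, models[key].cov)
        assert back[("male", 4, "adult")].family == "gompertz"
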