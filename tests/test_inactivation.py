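"""Ipsilateral bias, logistic choice models, LRT, single-step contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from delaylick import inactivation, synth


def _irls_logistic(X, y, tol=1e-12, max_iter=100):
    """Independent oracle: iteratively reweighted least squares."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-12)
        wx = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ wx, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


def _laser_trials(n, bias, seed, region="m2", lapse_free=False, **kw):
    """Laser-perturbation session; ``lapse_free`` removes the psychometric
    lapse rates so the generative model matches a pure logistic."""
    eff = {("delay", region): {"bias_shift": bias}}
    psych = {"y0": 0.0, "a": 1.0} if lapse_free else None
    return synth.gen_behavior(n_trials=n, manipulation="laser",
                              manip_region=region, effects=eff,
                              psychometric=psych, seed=seed, **kw)


class TestNormalizedIpsiBias:
    def _manual(self, n_ctrl_ipsi, n_ctrl, inact_choices):
        rows = []
        i = 0
        for k in range(n_ctrl):
            rows.append({"trial_id": i, "choice":
                         "left" if k < n_ctrl_ipsi else "right",
                         "manipulation": "none", "manip_epoch": "none"})
            i += 1
        for c in inact_choices:
            rows.append({"trial_id": i, "choice": c,
                         "manipulation": "laser", "manip_epoch": "delay"})
            i += 1
        df = pd.DataFrame(rows)
        df["subject_id"] = "m0"
        df["session_id"] = "s0"
        df["click_rate"] = 20.0
        df["log_rate_norm"] = -1.0
        df["category"] = "low"
        df["delay"] = 1.0
        df["outcome"] = "correct"
        df["rt"] = 0.5
        df["manip_region"] = np.where(df["manipulation"] == "laser", "m2",
                                      "none")
        df["hemisphere"] = "left"
        return df

    def test_all_ipsi_inactivation_from_balanced_control(self):
        # control P(ipsi) = 0.5, every inactivation trial ipsilateral
        t = self._manual(5, 10, ["left"] * 6)
        res = inactivation.normalized_ipsi_bias(t)
        assert res.delta_ipsi == pytest.approx(50.0)

    def test_no_effect_gives_zero_delta(self):
        t = self._manual(5, 10, ["left", "right"] * 5)
        res = inactivation.normalized_ipsi_bias(t)
        assert res.delta_ipsi == pytest.approx(0.0)

    def test_recovers_simulated_shift(self):
        # injected ipsi (left-hemisphere) logit bias: P(ipsi) rises by a
        # known amount at the boundary
        parts = [_laser_trials(2500, -0.8, seed=s) for s in (1, 2)]
        for i, p in enumerate(parts):
            p["session_id"] = f"s{i}"
        t = pd.concat(parts, ignore_index=True)
        res = inactivation.normalized_ipsi_bias(t, epoch="delay")
        assert res.delta_ipsi > 5.0
        assert res.delta_ipsi == pytest.approx(res.delta_ipsi, abs=3 * res.sem)

    def test_session_without_controls_excluded(self):
        t = self._manual(5, 10, ["left"] * 6)
        t2 = t.copy()
        t2["session_id"] = "s1"
        t2["manipulation"] = "laser"
        t2["manip_epoch"] = "delay"
        t2["manip_region"] = "m2"
        with pytest.warns(UserWarning, match="excluded"):
            res = inactivation.normalized_ipsi_bias(
                pd.concat([t, t2], ignore_index=True))
        assert res.excluded_sessions == ["s1"]


class TestFitChoiceLogistic:
    def test_matches_irls_oracle(self):
        trials = _laser_trials(800, 1.0, seed=3)
        fit = inactivation.fit_choice_logistic(trials, "model1",
                                               subject_handling="none")
        scored = trials[trials["choice"].isin(["left", "right"])]
        y = (scored["choice"] == "right").to_numpy(float)
        X = np.column_stack([
            np.ones(len(scored)),
            scored["log_rate_norm"].to_numpy()]
            + [(scored["manip_epoch"] == e).to_numpy(float)
               for e in ["delay", "iti", "response", "stimulus"]])
        # align oracle columns with the fitted coefficient names
        names = list(fit.coefficients.index)
        cols = {"intercept": 0, "log_rate_norm": 1, "epoch_delay": 2,
                "epoch_iti": 3, "epoch_response": 4, "epoch_stimulus": 5}
        Xo = X[:, [cols[n] for n in names if n in cols]]
        beta = _irls_logistic(Xo, y)
        fitted = fit.coefficients[[n for n in names if n in cols]].to_numpy()
        assert np.allclose(fitted, beta, atol=1e-6)

    def test_recovers_injected_delay_bias(self):
        # delay-focused perturbation so the bias term is well informed
        trials = _laser_trials(5000, 1.0, seed=4, lapse_free=True,
                               manip_frac=0.5, manip_epochs=("delay",))
        fit = inactivation.fit_choice_logistic(trials, "model1",
                                               subject_handling="none")
        assert fit.coefficients["epoch_delay"] == pytest.approx(1.0, abs=0.15)

    def test_null_z_calibrated(self):
        n_rep, hits = 300, 0
        for rep in range(n_rep):
            trials = _laser_trials(400, 0.0, seed=20_000 + rep)
            fit = inactivation.fit_choice_logistic(trials, "model1",
                                                   subject_handling="none")
            if abs(fit.zvalues["epoch_delay"]) > 1.96:
                hits += 1
        assert hits / n_rep <= 0.06 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_rank_deficiency_rejected(self):
        t = synth.gen_behavior(n_trials=100, seed=5)
        t["log_rate_norm"] = 0.0  # constant predictor, no manipulation terms
        t["click_rate"] = 60.0
        t["category"] = "high"
        with pytest.raises(ValueError):
            inactivation.fit_choice_logistic(t, "model1",
                                             subject_handling="none")

    def test_model2_nests_model1(self):
        trials = _laser_trials(600, 0.5, seed=6)
        f1 = inactivation.fit_choice_logistic(trials, "model1", "none")
        f2 = inactivation.fit_choice_logistic(trials, "model2", "none")
        assert set(f1.coefficients.index) <= set(f2.coefficients.index)
        assert f2.loglik >= f1.loglik - 1e-8


class TestLrt:
    def test_identical_models_give_p_one(self):
        trials = _laser_trials(300, 0.0, seed=7)
        f = inactivation.fit_choice_logistic(trials, "model1", "none")
        res = inactivation.lrt_nested(f, f)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_non_nested_rejected(self):
        t1 = _laser_trials(300, 0.0, seed=8)
        f1 = inactivation.fit_choice_logistic(t1, "model1", "none")
        f2 = inactivation.fit_choice_logistic(t1.iloc[:200], "model1", "none")
        with pytest.raises(ValueError):
            inactivation.lrt_nested(f1, f2)

    def test_difficulty_interaction_detected_with_power(self):
        # bias that acts only on hard (boundary) stimuli creates a true
        # epoch-by-difficulty interaction
        hits, n_rep = 0, 25
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            t = synth.gen_behavior(n_trials=10_000, manipulation="laser",
                                   manip_region="m2", seed=rep)
            scored = t["choice"].isin(["left", "right"]).to_numpy()
            diff = 1.0 - t["log_rate_norm"].to_numpy() ** 2
            is_delay = (t["manip_epoch"] == "delay").to_numpy()
            flip = (rng.random(len(t))
                    < sps.norm.cdf(3.0 * diff * is_delay) - 0.5)
            right = (t["choice"] == "right").to_numpy() | (flip & scored)
            t.loc[scored, "choice"] = np.where(right[scored], "right", "left")
            f1 = inactivation.fit_choice_logistic(t, "model1", "none")
            f2 = inactivation.fit_choice_logistic(t, "model2", "none")
            if inactivation.lrt_nested(f1, f2).p_value < 0.05:
                hits += 1
        assert hits / n_rep >= 0.8


class TestSingleStepContrasts:
    def _fit_stub(self, beta, cov):
        names = [f"b{i}" for i in range(len(beta))]
        return inactivation.ChoiceModelFit(
            coefficients=pd.Series(beta, index=names),
            cov=pd.DataFrame(cov, index=names, columns=names),
            loglik=0.0, n_trials=100, model_id="model1",
            zvalues=pd.Series(0.0, index=names),
            pvalues=pd.Series(1.0, index=names))

    def test_single_contrast_equals_unadjusted(self):
        fit = self._fit_stub([0.5, 0.2], np.diag([0.04, 0.09]))
        out = inactivation.single_step_contrasts(fit, [np.array([1.0, 0.0])],
                                                 n_draws=200_000, seed=0)
        assert out["p_adjusted"].iloc[0] == pytest.approx(
            out["p_unadjusted"].iloc[0], abs=0.005)

    def test_independent_contrasts_match_sidak_form(self):
        # for k independent contrasts the single-step adjustment equals
        # 1 - (1 - p)^k; check against the closed form
        k = 4
        fit = self._fit_stub([0.3] * k, np.eye(k) * 0.04)
        C = [np.eye(k)[i] for i in range(k)]
        out = inactivation.single_step_contrasts(fit, C, n_draws=200_000,
                                                 seed=1)
        p_un = out["p_unadjusted"].to_numpy()
        expect = 1.0 - (1.0 - p_un) ** k
        assert np.allclose(out["p_adjusted"], expect, atol=0.01)

    def test_perfectly_correlated_contrasts_unpenalized(self):
        cov = np.array([[0.04, 0.04], [0.04, 0.04]]) + np.eye(2) * 1e-12
        fit = self._fit_stub([0.4, 0.4], cov)
        C = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        out = inactivation.single_step_contrasts(fit, C, n_draws=200_000,
                                                 seed=2)
        assert np.allclose(out["p_adjusted"], out["p_unadjusted"], atol=0.01)
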