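"""Perturbation effects on choice: ipsilateral bias and logistic models.

Choice on each trial is modeled as a logistic function of the normalized
log click rate, the perturbation epoch and region, and (model 2) their
three-way interaction with stimulus difficulty.  Difficulty is
``1 - x_norm**2`` with the normalized log click rate scaled to [-1, 1], so
boundary stimuli are hardest.  The original crossed random-effect structure
is approximated by fixed per-subject intercepts plus cluster-robust (by
subject) covariance; this keeps fits deterministic and dependency-light.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .containers import validate_trials
from .stats import TestResult

__all__ = ["BiasEstimate", "ChoiceModelFit", "normalized_ipsi_bias",
           "fit_choice_logistic", "lrt_nested", "single_step_contrasts"]

log = logging.getLogger(__name__)


@dataclass
class BiasEstimate:
    """Mean ipsilateral-bias change (percentage points) across trials."""

    delta_ipsi: float
    sem: float
    n_trials: int
    excluded_sessions: list[str] = field(default_factory=list)


@dataclass
class ChoiceModelFit:
    coefficients: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_trials: int
    model_id: str
    zvalues: pd.Series
    pvalues: pd.Series
    flags: list[str] = field(default_factory=list)


def normalized_ipsi_bias(trials: pd.DataFrame,
                         epoch: str | None = None,
                         region: str | None = None) -> BiasEstimate:
    """Session-normalized ipsilateral bias of perturbation trials.

    Per session, the mean P(lick ipsi) on control trials is subtracted from
    each perturbation trial's ipsi indicator (ipsi = choice toward the
    perturbed hemisphere); trials are then concatenated across sessions and
    the mean ± s.e.m. across trials is returned in percentage points.
    Sessions without control trials are excluded with a warning.  ``epoch``
    and ``region`` restrict which perturbation trials are counted.
    """
    validate_trials(trials)
    scored = trials[trials["outcome"].isin(["correct", "error"])].copy()
    is_manip = scored["manipulation"] != "none"
    if epoch is not None:
        is_manip &= scored["manip_epoch"] == epoch
    if region is not None:
        is_manip &= scored["manip_region"] == region

    ipsi = np.where(scored["hemisphere"] == "bilateral", np.nan,
                    (scored["choice"] == scored["hemisphere"]).astype(float))
    scored = scored.assign(_ipsi=ipsi, _manip=is_manip)

    deltas, excluded = [], []
    for sid, g in scored.groupby("session_id"):
        ctrl = g[g["manipulation"] == "none"]
        if len(ctrl) == 0 or g["_manip"].sum() == 0:
            excluded.append(str(sid))
            continue
        base = ctrl["_ipsi"].mean()
        deltas.append(g.loc[g["_manip"], "_ipsi"].to_numpy() - base)
    if excluded:
        warnings.warn(f"sessions without control/perturbation trials "
                      f"excluded: {excluded}")
    if not deltas:
        raise ValueError("no session with both control and perturbation trials")
    d = 100.0 * np.concatenate(deltas)
    return BiasEstimate(
        delta_ipsi=float(np.mean(d)),
        sem=float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.nan,
        n_trials=len(d), excluded_sessions=excluded)


def _design(trials: pd.DataFrame, model_id: str,
            subject_handling: str = "fixed") -> tuple[pd.DataFrame, np.ndarray]:
    scored = trials[trials["choice"].isin(["left", "right"])].copy()
    if len(scored) < 2 or scored["choice"].nunique() < 2:
        raise ValueError("need >=2 scored trials with both choices")
    y = (scored["choice"] == "right").to_numpy(float)

    X = pd.DataFrame({"log_rate_norm": scored["log_rate_norm"].to_numpy()},
                     index=scored.index)
    ep = pd.get_dummies(scored["manip_epoch"], prefix="epoch", dtype=float)
    rg = pd.get_dummies(scored["manip_region"], prefix="region", dtype=float)
    ep = ep.drop(columns=[c for c in ep.columns if c.endswith("_none")],
                 errors="ignore")
    rg = rg.drop(columns=[c for c in rg.columns if c.endswith("_none")],
                 errors="ignore")
    X = pd.concat([X, ep, rg], axis=1)
    for e in ep.columns:
        for r in rg.columns:
            col = ep[e] * rg[r]
            if col.any():
                X[f"{e}:{r}"] = col
    if model_id == "model2":
        diff = 1.0 - scored["log_rate_norm"].to_numpy() ** 2
        X["difficulty"] = diff
        for c in list(ep.columns) + list(rg.columns):
            X[f"{c}:difficulty"] = X[c] * diff
        for e in ep.columns:
            for r in rg.columns:
                key = f"{e}:{r}"
                if key in X:
                    X[f"{key}:difficulty"] = X[key] * diff
    elif model_id != "model1":
        raise ValueError("model_id must be 'model1' or 'model2'")

    if subject_handling == "fixed" and scored["subject_id"].nunique() > 1:
        subj = pd.get_dummies(scored["subject_id"], prefix="subj", dtype=float)
        X = pd.concat([X, subj.iloc[:, 1:]], axis=1)
    X.insert(0, "intercept", 1.0)

    # drop aliased (rank-deficient) columns, keeping the earliest
    Xv = X.to_numpy()
    _, Rr = np.linalg.qr(Xv)
    keep = np.abs(np.diag(Rr)) > 1e-8 * max(1.0, np.abs(Rr).max())
    if keep.sum() < 2:
        raise ValueError("design matrix is rank deficient beyond repair")
    dropped = [c for c, k in zip(X.columns, keep) if not k]
    if dropped:
        log.info("dropping aliased design columns: %s", dropped)
        X = X.loc[:, keep]
    X["_subject"] = scored["subject_id"].to_numpy()
    return X, y


def fit_choice_logistic(trials: pd.DataFrame, model_id: str = "model1",
                        subject_handling: str = "fixed") -> ChoiceModelFit:
    """Maximum-likelihood logistic fit of choice on stimulus and perturbation.

    ``subject_handling``: "fixed" adds per-subject intercepts and reports
    cluster-robust (by subject) covariance; "none" fits a plain GLM.
    Separation (divergent coefficients) triggers a ridge-stabilized refit,
    flagged on the result.
    """
    validate_trials(trials)
    X, y = _design(trials, model_id, subject_handling)
    groups = X.pop("_subject")

    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit()
            if np.any(np.abs(res.params) > 15):
                raise ValueError("separation suspected")
        except Exception:
            flags.append("separation: ridge-stabilized (L2) refit reported")
            res = model.fit_regularized(alpha=1e-3, L1_wt=0.0)
            res = model.fit(start_params=res.params, maxiter=25)

    if subject_handling == "fixed" and groups.nunique() > 1 and not flags:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(cov_type="cluster",
                            cov_kwds={"groups": groups.to_numpy()})
        flags.append("cluster-robust covariance by subject")

    cov = pd.DataFrame(np.asarray(res.cov_params()),
                       index=X.columns, columns=X.columns)
    z = res.params / np.sqrt(np.diag(cov))
    return ChoiceModelFit(
        coefficients=pd.Series(res.params, index=X.columns),
        cov=cov,
        loglik=float(model.loglike(np.asarray(res.params))),
        n_trials=len(y),
        model_id=model_id,
        zvalues=pd.Series(z, index=X.columns),
        pvalues=pd.Series(2 * sps.norm.sf(np.abs(z)), index=X.columns),
        flags=flags)


def lrt_nested(fit_small: ChoiceModelFit, fit_big: ChoiceModelFit) -> TestResult:
    """Likelihood-ratio test of two nested fits on the same trials."""
    small_terms = set(fit_small.coefficients.index)
    big_terms = set(fit_big.coefficients.index)
    if not small_terms <= big_terms or fit_small.n_trials != fit_big.n_trials:
        raise ValueError("models are not nested on the same trials")
    df = len(big_terms) - len(small_terms)
    stat = 2.0 * (fit_big.loglik - fit_small.loglik)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 else float(sps.chi2.sf(stat, df))
    return TestResult(statistic=float(stat), p_value=p,
                      method="likelihood-ratio test", extra={"df": df})


def single_step_contrasts(fit: ChoiceModelFit,
                          contrasts: list[np.ndarray] | dict[str, np.ndarray],
                          n_draws: int = 100_000,
                          seed: int | None = 0) -> pd.DataFrame:
    """Single-step (max-|z|) multiplicity adjustment for linear contrasts.

    Each contrast c gives z = c'beta / sqrt(c'Vc); the joint null of the z
    vector is simulated from the multivariate normal implied by the fit's
    covariance, and the adjusted p-value is P(max_j |z*_j| >= |z_obs,i|).
    With one contrast this reduces to the unadjusted two-sided normal p.
    """
    if isinstance(contrasts, dict):
        names = list(contrasts)
        C = np.array([np.asarray(contrasts[k], float) for k in names])
    else:
        C = np.array([np.asarray(c, float) for c in contrasts])
        names = [f"c{i}" for i in range(len(C))]
    V = fit.cov.to_numpy()
    beta = fit.coefficients.to_numpy()
    cv = C @ V @ C.T
    se = np.sqrt(np.diag(cv))
    if np.any(se <= 0) or not np.all(np.isfinite(cv)):
        raise ValueError("singular covariance for the requested contrasts")
    z = (C @ beta) / se
    corr = cv / np.outer(se, se)
    # draws from the joint null of the contrast z-statistics
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(se)))
    zstar = rng.standard_normal((n_draws, len(se))) @ L.T
    maxabs = np.abs(zstar).max(axis=1)
    p_adj = np.array([(np.sum(maxabs >= abs(zi)) + 1) / (n_draws + 1)
                      for zi in z])
    return pd.DataFrame({
        "contrast": names,
        "estimate": C @ beta,
        "z": z,
        "p_unadjusted": 2 * sps.norm.sf(np.abs(z)),
        "p_adjusted": np.minimum(1.0, p_adj),
    }).set_index("contrast")
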