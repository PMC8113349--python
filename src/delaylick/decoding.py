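"""Population decoding of choice/sensory information and its link to RT.

The decoder is an L2-regularized linear maximum-margin classifier (C = 1)
on epoch-averaged ΔF/F population vectors.  Cross-validation draws a random
90% training / 10% test split 100 times; training classes are balanced by
subsampling the majority class so the hyperplane is not biased toward the
more frequent choice.  Leave-one-out decoding classifies each trial with a
model trained on all remaining trials (balanced), yielding a per-trial 0/1
correctness used to relate delay-period choice information to response
time, including via a linear mixed model with subject-level random effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import LinearSVC

from .containers import EpochResponse

__all__ = ["DecodeResult", "RtLinkFit", "cv_decode", "loo_decode",
           "rt_link", "fit_rt_lmm"]

MAX_RT_S = 2.5


def _labels(er: EpochResponse, mode: str) -> np.ndarray:
    if mode == "choice":
        return (er.trials["choice"] == "right").to_numpy()
    if mode == "sensory":
        return (er.trials["category"] == "high").to_numpy()
    raise ValueError("mode must be 'choice' or 'sensory'")


class _CenteredSVM:
    """Linear max-margin classifier on train-mean-centered features.

    Centering makes the decoder invariant to a common offset of all
    responses (the regularized intercept otherwise couples to the mean).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.mean_ = X.mean(axis=0)
        self.clf = LinearSVC(C=1.0, max_iter=20000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf.fit(X - self.mean_, y)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(X - self.mean_)


def _fit_svm(X: np.ndarray, y: np.ndarray) -> _CenteredSVM:
    return _CenteredSVM(X, y)


def _balance(idx: np.ndarray, y: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Subsample the majority class among ``idx`` to equal class counts."""
    pos = idx[y[idx]]
    neg = idx[~y[idx]]
    m = min(pos.size, neg.size)
    if m == 0:
        raise ValueError("a class is absent from the training set")
    pos = rng.choice(pos, size=m, replace=False)
    neg = rng.choice(neg, size=m, replace=False)
    out = np.concatenate([pos, neg])
    assert y[out].sum() == (~y[out]).sum()  # balanced by construction
    return out


@dataclass
class DecodeResult:
    accuracy_mean: dict[str, float]
    accuracy_sem: dict[str, float]
    per_resample: dict[str, np.ndarray]
    shuffle_mean: dict[str, float] = field(default_factory=dict)
    shuffle_per_resample: dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = "choice"
    n_resamples: int = 100


def cv_decode(er: EpochResponse, mode: str = "choice",
              n_resamples: int = 100, train_frac: float = 0.9,
              standardize: bool = False, with_shuffle: bool = True,
              seed: int | None = None) -> DecodeResult:
    """Cross-validated linear decoding per behavioral epoch.

    Each resample draws ``train_frac`` of trials for training (balanced
    between classes by subsampling) and tests on the remainder; accuracy is
    the held-out fraction correct, summarized as mean ± s.e.m. over
    resamples.  A shuffled-label control (labels permuted once per
    resample) is computed with the identical procedure.
    """
    y = _labels(er, mode)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >=2 trials per class")
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = max(2, int(round(train_frac * n)))

    acc_mean, acc_sem, per_rs = {}, {}, {}
    sh_mean, sh_rs = {}, {}
    for j, ep in enumerate(er.epochs):
        X = er.dff[:, :, j]
        ok = ~np.isnan(X).any(axis=1)
        Xe, ye = X[ok], y[ok]
        if standardize:
            mu, sd = Xe.mean(0), Xe.std(0)
            Xe = (Xe - mu) / np.where(sd > 0, sd, 1.0)
        ne = len(ye)
        nt = min(n_train, ne - 1)
        accs = np.empty(n_resamples)
        shs = np.empty(n_resamples)
        for r in range(n_resamples):
            perm = rng.permutation(ne)
            tr, te = perm[:nt], perm[nt:]
            trb = _balance(tr, ye, rng)
            clf = _fit_svm(Xe[trb], ye[trb])
            accs[r] = float(np.mean(clf.predict(Xe[te]) == ye[te]))
            if with_shuffle:
                ysh = rng.permutation(ye)
                try:
                    trb = _balance(tr, ysh, rng)
                except ValueError:
                    shs[r] = np.nan
                    continue
                clf = _fit_svm(Xe[trb], ysh[trb])
                shs[r] = float(np.mean(clf.predict(Xe[te]) == ysh[te]))
        acc_mean[ep] = float(accs.mean())
        acc_sem[ep] = float(accs.std(ddof=1) / np.sqrt(n_resamples))
        per_rs[ep] = accs
        if with_shuffle:
            sh_mean[ep] = float(np.nanmean(shs))
            sh_rs[ep] = shs
    return DecodeResult(accuracy_mean=acc_mean, accuracy_sem=acc_sem,
                        per_resample=per_rs, shuffle_mean=sh_mean,
                        shuffle_per_resample=sh_rs, mode=mode,
                        n_resamples=n_resamples)


def loo_decode(er: EpochResponse, mode: str = "choice",
               epoch: str = "delay", seed: int | None = None) -> np.ndarray:
    """Leave-one-out decoding: 0/1 correctness per trial for one epoch."""
    y = _labels(er, mode)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need >=2 trials per class")
    rng = np.random.default_rng(seed)
    j = er.epochs.index(epoch)
    X = er.dff[:, :, j]
    n = len(y)
    out = np.full(n, np.nan)
    idx = np.arange(n)
    for i in range(n):
        if np.isnan(X[i]).any():
            continue
        tr = idx[(idx != i) & ~np.isnan(X).any(axis=1)]
        trb = _balance(tr, y, rng)
        clf = _fit_svm(X[trb], y[trb])
        out[i] = float(clf.predict(X[i:i + 1])[0] == y[i])
    return out


@dataclass
class RtLinkFit:
    pearson_r: dict[str, float]
    pearson_p: dict[str, float]
    binned: pd.DataFrame | None = None
    fixed_effects: pd.DataFrame | None = None
    random_structure: str = ""
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def rt_link(loo_outcomes: np.ndarray, trials: pd.DataFrame,
            n_bins: int = 5) -> RtLinkFit:
    """Relate per-trial decoding correctness to response time.

    Per session, trials with RT in [0, 2.5] s are split at RT quantiles
    into ``n_bins`` bins (20-percentile bins by default); per-bin mean
    decoding accuracy, mean RT and mean delay are computed.  Pearson r and
    its t-test p (df = n - 2) are reported both across all binned points
    pooled over sessions and across per-bin session means (the two natural
    readings of a bins-by-sessions design).
    """
    lo = np.asarray(loo_outcomes, dtype=float)
    if len(lo) != len(trials):
        raise ValueError("loo_outcomes must align with the trial table")
    rt = trials["rt"].to_numpy(float)
    delay = trials["delay"].to_numpy(float)
    sess = trials["session_id"].to_numpy()
    ok = ~np.isnan(lo) & ~np.isnan(rt) & (rt >= 0) & (rt <= MAX_RT_S)
    if ok.sum() < n_bins:
        raise ValueError("not enough trials with valid RT")
    rows = []
    for sid in pd.unique(sess[ok]):
        m_s = ok & (sess == sid)
        r = rt[m_s]
        if np.unique(r).size < n_bins:
            raise ValueError("degenerate RT distribution within a session")
        q = pd.qcut(r, n_bins, labels=False, duplicates="drop")
        for b in np.unique(q):
            m = q == b
            rows.append({"session_id": sid, "bin": int(b),
                         "mean_rt": float(r[m].mean()),
                         "mean_delay": float(delay[m_s][m].mean()),
                         "mean_accuracy": float(lo[m_s][m].mean())})
    binned = pd.DataFrame(rows)

    def _corr(x, yv):
        if np.std(x) == 0 or np.std(yv) == 0:
            return np.nan, np.nan
        r, p = sps.pearsonr(x, yv)
        return float(r), float(p)

    r_pool, p_pool = _corr(binned["mean_rt"], binned["mean_accuracy"])
    bymean = binned.groupby("bin")[["mean_rt", "mean_accuracy"]].mean()
    r_mean, p_mean = _corr(bymean["mean_rt"], bymean["mean_accuracy"])
    return RtLinkFit(
        pearson_r={"pooled": r_pool, "session_means": r_mean},
        pearson_p={"pooled": p_pool, "session_means": p_mean},
        binned=binned)


def fit_rt_lmm(trials: pd.DataFrame, loo_outcomes: np.ndarray,
               covariates: tuple[str, ...] = ("delay", "decode"),
               extra: pd.DataFrame | None = None,
               random_slopes: bool = False) -> RtLinkFit:
    """Linear mixed model of RT on delay, decoding correctness and extras.

    Fixed effects are the requested covariates ("delay" and "decode" map to
    the trial delay and the per-trial leave-one-out correctness;
    "performance" to the correct/error indicator; any other name must be a
    column of ``extra``).  Subjects contribute random intercepts (and
    random slopes when requested) fitted by maximum likelihood; a singular
    random-effect covariance triggers an automatic fall back to the
    intercept-only structure, recorded in ``notes``.
    """
    import statsmodels.formula.api as smf

    lo = np.asarray(loo_outcomes, dtype=float)
    rt = trials["rt"].to_numpy(float)
    data = pd.DataFrame({
        "rt": rt,
        "delay": trials["delay"].to_numpy(float),
        "decode": lo,
        "performance": (trials["outcome"] == "correct").astype(float).to_numpy(),
        "subject": trials["subject_id"].to_numpy(),
    })
    if extra is not None:
        for c in extra.columns:
            data[c] = extra[c].to_numpy()
    use = [c for c in covariates]
    missing = [c for c in use if c not in data.columns]
    if missing:
        raise ValueError(f"unknown covariates: {missing}")
    data = data.dropna(subset=["rt"] + use)
    if data["subject"].nunique() < 2:
        raise ValueError("need >=2 subjects for random effects")
    if not np.all(np.isfinite(data[use].to_numpy())):
        raise ValueError("non-finite predictor values")

    formula = "rt ~ " + " + ".join(use)
    notes: list[str] = []
    re_formula = ("~" + " + ".join(use)) if random_slopes else "~1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, data, groups=data["subject"],
                         re_formula=re_formula)
        try:
            res = md.fit(reml=False)
            singular = (np.any(~np.isfinite(np.asarray(res.cov_re)))
                        or np.any(np.diag(np.asarray(res.cov_re)) < 1e-10))
        except Exception:
            res, singular = None, True
        if singular and re_formula != "~1":
            notes.append("singular random-effect covariance; fell back to "
                         "random intercepts only")
            md = smf.mixedlm(formula, data, groups=data["subject"],
                             re_formula="~1")
            res = md.fit(reml=False)
        elif res is None:
            md = smf.mixedlm(formula, data, groups=data["subject"],
                             re_formula="~1")
            res = md.fit(reml=False)

    fe_names = [n for n in res.params.index if n in ["Intercept"] + use]
    cov_re = np.atleast_2d(np.asarray(res.cov_re))
    if np.all(np.diag(cov_re) < 1e-8):
        # at the zero-variance boundary the ML fixed effects are OLS; the
        # mixed-model solver is unreliable there, so refit plainly
        notes.append("random-effect variance at zero; fixed effects from OLS")
        import statsmodels.api as sm_api
        Xo = sm_api.add_constant(data[use])
        ols = sm_api.OLS(data["rt"], Xo).fit()
        fe = pd.DataFrame({
            "estimate": ols.params.to_numpy(),
            "se": ols.bse.to_numpy(),
            "p_value": ols.pvalues.to_numpy(),
        }, index=["Intercept"] + use)
    else:
        fe = pd.DataFrame({
            "estimate": res.params[fe_names],
            "se": res.bse[fe_names],
            "p_value": res.pvalues[fe_names],
        })
    return RtLinkFit(
        pearson_r={}, pearson_p={}, fixed_effects=fe,
        random_structure=("intercept+slopes" if (random_slopes and not notes)
                          else "intercept"),
        converged=bool(res.converged), notes=notes)
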