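"""Mode-effect estimators: unadjusted, IPW, and multiple imputation.

All three estimate the same contrast - mean score in the mobile-web arm
minus the telephone arm - on respondent data (unadjusted) or on the full
randomized sample with nonresponse adjusted under MAR (IPW, MI).

* Unadjusted: respondent arm means with Welch (unequal-variance) t
  inference.
* IPW: Hajek-weighted respondent means with weights 1/pi-hat from a
  main-effects logistic response-propensity model; the standard error comes
  from the stacked M-estimation sandwich over the logistic score equations
  and the two weighted-mean estimating equations, so uncertainty in the
  estimated weights is propagated.
* MI: Bayesian linear-regression imputation of missing scores from the
  stratification variables, fit within each arm (draws of the residual
  variance from its scaled inverse-chi-square posterior and of the
  coefficients from their conditional Gaussian posterior, then
  posterior-predictive draws for the missing outcomes), pooled over copies
  by Rubin's rules. An additive arm-specific delta applied to every imputed
  value turns the same machinery into the MNAR delta-adjustment estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .dataset import ARM_LEVELS, STRATA_FACTORS, as_frame
from .errors import EstimationError
from .synthetic import MOBILE_WEB, TELEPHONE

DEFAULT_PROPENSITY_FACTORS = ("arm",) + STRATA_FACTORS
_MAX_ABS_LOGIT_COEF = 15.0


@dataclass
class EstimateResult:
    """One arm contrast with its inference.

    ``difference`` is mobile web minus telephone, in points on the 0-100
    score scale. ``df`` is the t reference's degrees of freedom where one is
    used (Welch, Rubin); None means the normal reference.
    """

    outcome: str
    method: str
    difference: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_analyzed: int
    m_imputations: Optional[int] = None
    df: Optional[float] = None

    @property
    def ci95(self) -> Tuple[float, float]:
        return (self.ci_low, self.ci_high)

    @property
    def significant(self) -> bool:
        return self.ci_low > 0.0 or self.ci_high < 0.0


def _interval(diff: float, se: float, df: Optional[float]):
    if se <= 0:
        raise EstimationError("non-positive standard error")
    if df is None or not np.isfinite(df):
        crit = stats.norm.ppf(0.975)
        p = 2.0 * stats.norm.sf(abs(diff) / se)
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(diff) / se, df)
    return diff - crit * se, diff + crit * se, float(p)


def _arm_values(df: pd.DataFrame, outcome: pd.Series, arm: str) -> np.ndarray:
    mask = (df["arm"] == arm) & df["responded"].astype(bool) & outcome.notna()
    return outcome[mask].to_numpy(dtype=float)


def unadjusted_difference(data, outcome: pd.Series, name: Optional[str] = None) -> EstimateResult:
    """Respondent-only arm contrast with Welch two-sample inference."""
    df = as_frame(data)
    y_t = _arm_values(df, outcome, TELEPHONE)
    y_m = _arm_values(df, outcome, MOBILE_WEB)
    if len(y_t) < 2 or len(y_m) < 2:
        raise EstimationError("need at least 2 respondents per arm")
    diff = float(y_m.mean() - y_t.mean())
    v_t, v_m = y_t.var(ddof=1) / len(y_t), y_m.var(ddof=1) / len(y_m)
    se = float(np.sqrt(v_t + v_m))
    # Welch-Satterthwaite df; degenerate only if both sample variances are 0
    denom = v_t**2 / (len(y_t) - 1) + v_m**2 / (len(y_m) - 1)
    if denom == 0.0:
        welch_df = float(len(y_t) + len(y_m) - 2)
        if se == 0.0:
            # exact symmetry: no evidence against equality
            return EstimateResult(
                name or outcome.name or "score", "unadjusted", 0.0, 0.0, 0.0, 0.0,
                1.0, len(y_t) + len(y_m), df=welch_df,
            )
    else:
        welch_df = float((v_t + v_m) ** 2 / denom)
    lo, hi, p = _interval(diff, se, welch_df)
    return EstimateResult(
        name or outcome.name or "score", "unadjusted", diff, se, lo, hi, p,
        len(y_t) + len(y_m), df=welch_df,
    )


# --------------------------------------------------------------------------
# IPW

@dataclass
class PropensityFit:
    """Fitted logistic response-propensity model.

    ``pi`` aligns with the trial frame's index over all randomized patients;
    ``weights`` (1/pi) is defined for respondents only.
    """

    params: pd.Series
    pi: pd.Series
    weights: pd.Series
    exog: np.ndarray
    exog_names: Sequence[str]
    index: pd.Index
    factors: Sequence[str]


def _propensity_design(df: pd.DataFrame, factors: Sequence[str]):
    # reference-coded dummies with an explicit intercept
    rhs = patsy.dmatrix(
        "1 + " + " + ".join(f"C({f})" for f in factors), df, return_type="dataframe"
    )
    return rhs.to_numpy(dtype=float), list(rhs.columns)


def fit_response_propensity(data, factors: Sequence[str] = DEFAULT_PROPENSITY_FACTORS) -> PropensityFit:
    """MLE logistic fit of response on main effects of ``factors``.

    Raises EstimationError naming the offending factor on separation
    (a factor level with all or no respondents) or on rank deficiency.
    """
    import statsmodels.api as sm

    df = as_frame(data)
    r = df["responded"].astype(bool)
    if r.all() or not r.any():
        raise EstimationError("response indicator is constant; propensity model is undefined")
    for f in factors:
        tab = df.groupby(f, observed=True)["responded"].agg(["sum", "size"])
        bad = tab[(tab["sum"] == 0) | (tab["sum"] == tab["size"])]
        if len(bad):
            raise EstimationError(
                f"separation: factor {f!r} level(s) {list(bad.index)} have all-or-none response"
            )
    X, names = _propensity_design(df, factors)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError(
            f"rank-deficient propensity design over factors {tuple(factors)}"
        )
    res = sm.GLM(r.to_numpy(dtype=float), X, family=sm.families.Binomial()).fit()
    if np.max(np.abs(res.params)) > _MAX_ABS_LOGIT_COEF:
        raise EstimationError("propensity fit diverged (quasi-separation)")
    pi = pd.Series(res.predict(X), index=df.index, name="pi")
    if not ((pi > 0) & (pi < 1)).all():
        raise EstimationError("fitted response probabilities not strictly in (0, 1)")
    w = (1.0 / pi)[r]
    return PropensityFit(
        params=pd.Series(res.params, index=names),
        pi=pi,
        weights=w,
        exog=X,
        exog_names=names,
        index=df.index,
        factors=tuple(factors),
    )


def unit_propensity_fit(data) -> PropensityFit:
    """Degenerate fit with all response probabilities 1 (weights 1).

    Useful when every randomized patient responded, where the weighted
    analysis is defined but the logistic model is not.
    """
    df = as_frame(data)
    pi = pd.Series(1.0, index=df.index, name="pi")
    r = df["responded"].astype(bool)
    return PropensityFit(
        params=pd.Series(dtype=float), pi=pi, weights=(1.0 / pi)[r],
        exog=np.zeros((len(df), 0)), exog_names=[], index=df.index, factors=(),
    )


def ipw_difference(data, outcome: pd.Series, fit: Optional[PropensityFit] = None,
                   name: Optional[str] = None) -> EstimateResult:
    """Hajek IPW arm contrast with a stacked M-estimation sandwich SE.

    The estimating equations stack the logistic score with the two weighted
    arm means, so the variance accounts for the weights being estimated.
    """
    df = as_frame(data)
    if fit is None:
        fit = fit_response_propensity(df)
    pi = fit.pi.reindex(df.index).to_numpy(dtype=float)
    r = df["responded"].astype(bool).to_numpy()
    y = outcome.reindex(df.index).to_numpy(dtype=float)
    if np.isnan(y[r]).any():
        raise EstimationError("outcome missing for a respondent")
    w = np.where(r, 1.0 / pi, 0.0)
    if not np.isfinite(w).all():
        raise EstimationError("non-finite inverse-probability weight")
    X = fit.exog
    k = X.shape[1]
    mus = {}
    for arm in (TELEPHONE, MOBILE_WEB):
        a = (df["arm"] == arm).to_numpy()
        sw = np.sum(w[a & r])
        if sw <= 0:
            raise EstimationError(f"no weighted respondents in arm {arm}")
        mus[arm] = float(np.sum(w[a & r] * y[a & r]) / sw)
    diff = mus[MOBILE_WEB] - mus[TELEPHONE]

    # psi_i = (score_i, psi_tel_i, psi_mob_i); A = sum(-d psi / d theta)
    y0 = np.where(r, y, 0.0)
    resid_t = np.where(
        (df["arm"] == TELEPHONE).to_numpy() & r, w * (y0 - mus[TELEPHONE]), 0.0
    )
    resid_m = np.where(
        (df["arm"] == MOBILE_WEB).to_numpy() & r, w * (y0 - mus[MOBILE_WEB]), 0.0
    )
    score = X * (r.astype(float) - pi)[:, None]
    psi = np.column_stack([score, resid_t, resid_m])
    B = psi.T @ psi

    A = np.zeros((k + 2, k + 2))
    A[:k, :k] = X.T @ (X * (pi * (1 - pi))[:, None])
    A[k, :k] = (resid_t * (1 - pi)) @ X
    A[k + 1, :k] = (resid_m * (1 - pi)) @ X
    A[k, k] = np.sum(w[(df["arm"] == TELEPHONE).to_numpy() & r])
    A[k + 1, k + 1] = np.sum(w[(df["arm"] == MOBILE_WEB).to_numpy() & r])
    Ainv = np.linalg.solve(A, np.eye(k + 2))
    V = Ainv @ B @ Ainv.T
    c = np.zeros(k + 2)
    c[k], c[k + 1] = -1.0, 1.0
    se = float(np.sqrt(c @ V @ c))
    lo, hi, p = _interval(diff, se, None)
    return EstimateResult(
        name or outcome.name or "score", "ipw", diff, se, lo, hi, p, int(r.sum())
    )


# --------------------------------------------------------------------------
# Multiple imputation

@dataclass
class ImputedSet:
    """m completed copies of one outcome vector.

    ``completed`` has shape (m, n) aligned to ``index``; observed entries are
    identical across copies, missing entries are posterior-predictive draws
    plus the arm's delta.
    """

    completed: np.ndarray
    index: pd.Index
    missing: np.ndarray
    delta: Tuple[float, float]
    m: int
    outcome: str


def _imputation_design(sub: pd.DataFrame, predictors: Sequence[str]):
    if not predictors:
        return np.ones((len(sub), 1)), ["Intercept"]
    rhs = patsy.dmatrix(
        "1 + " + " + ".join(f"C({f})" for f in predictors), sub, return_type="dataframe"
    )
    X = rhs.to_numpy(dtype=float)
    keep = ~np.all(X == 0.0, axis=0)  # drop levels absent from this arm
    return X[:, keep], [c for c, k in zip(rhs.columns, keep) if k]


def impute_outcomes(data, outcome: pd.Series, m: int = 50,
                    delta: Tuple[float, float] = (0.0, 0.0), seed: int = 0,
                    predictors: Sequence[str] = STRATA_FACTORS,
                    clip: bool = False) -> ImputedSet:
    """Bayesian linear-regression imputation, fit within each arm.

    The random draws are independent of ``delta`` (the shift is added after
    drawing), so two calls with the same seed and different deltas share
    their base draws - the common-random-numbers property the sensitivity
    grid relies on. ``clip`` bounds imputed values to [0, 100]; off by
    default because clipping breaks the additive-shift identity.
    """
    if m < 2:
        raise EstimationError("need at least 2 imputations")
    df = as_frame(data)
    y = outcome.reindex(df.index).to_numpy(dtype=float)
    r = df["responded"].astype(bool).to_numpy() & ~np.isnan(y)
    completed = np.tile(np.where(r, y, np.nan), (m, 1))
    arm_seeds = np.random.SeedSequence(seed).spawn(len(ARM_LEVELS))
    deltas = {TELEPHONE: float(delta[0]), MOBILE_WEB: float(delta[1])}
    for arm, child in zip((TELEPHONE, MOBILE_WEB), arm_seeds):
        rng = np.random.default_rng(child)
        a = (df["arm"] == arm).to_numpy()
        obs, mis = a & r, a & ~r
        if obs.sum() == 0:
            raise EstimationError(f"no respondents in arm {arm}")
        X_all, _ = _imputation_design(df[a], predictors)
        obs_in_a = r[a]
        X_obs, X_mis = X_all[obs_in_a], X_all[~obs_in_a]
        n_obs, p = X_obs.shape
        if n_obs <= p:
            raise EstimationError(
                f"arm {arm}: {n_obs} respondents cannot support {p} regression parameters"
            )
        XtX = X_obs.T @ X_obs
        try:
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"arm {arm}: singular imputation design") from exc
        beta_hat = XtX_inv @ (X_obs.T @ y[obs])
        rss = float(np.sum((y[obs] - X_obs @ beta_hat) ** 2))
        nu = n_obs - p
        L = np.linalg.cholesky(XtX_inv)
        for j in range(m):
            sigma2 = rss / rng.chisquare(nu)
            beta_j = beta_hat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
            if mis.sum():
                draws = X_mis @ beta_j + np.sqrt(sigma2) * rng.standard_normal(mis.sum())
                draws = draws + deltas[arm]
                if clip:
                    draws = np.clip(draws, 0.0, 100.0)
                completed[j, mis] = draws
    if np.isnan(completed).any():
        raise EstimationError("imputation left missing entries unfilled")
    return ImputedSet(
        completed=completed,
        index=df.index,
        missing=~r,
        delta=(deltas[TELEPHONE], deltas[MOBILE_WEB]),
        m=int(m),
        outcome=str(outcome.name or "score"),
    )


def rubin_pool(estimates: Sequence[float], variances: Sequence[float],
               outcome: str = "score", method: str = "mi",
               n_analyzed: int = 0) -> EstimateResult:
    """Combine per-copy estimates by Rubin's rules.

    T = W + (1 + 1/m) B with the classical df (m-1)(1 + W/((1+1/m)B))^2.
    B = 0 with W > 0 collapses to the normal reference; B = W = 0 is
    degenerate and raises.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) < 2:
        raise EstimationError("need matching per-copy estimates and variances, m >= 2")
    m = len(q)
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if T <= 0.0:
        raise EstimationError("degenerate pooled variance (W = B = 0)")
    if B == 0.0:
        df = np.inf
    else:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    se = float(np.sqrt(T))
    lo, hi, p = _interval(qbar, se, None if np.isinf(df) else df)
    return EstimateResult(
        outcome, method, qbar, se, lo, hi, p, int(n_analyzed),
        m_imputations=m, df=None if np.isinf(df) else float(df),
    )


def _copy_difference(df: pd.DataFrame, y: np.ndarray) -> Tuple[float, float]:
    """Arm-mean difference and its Welch-type variance on one completed copy."""
    est, var = {}, {}
    for arm in (TELEPHONE, MOBILE_WEB):
        v = y[(df["arm"] == arm).to_numpy()]
        est[arm] = v.mean()
        var[arm] = v.var(ddof=1) / len(v)
    return float(est[MOBILE_WEB] - est[TELEPHONE]), float(var[TELEPHONE] + var[MOBILE_WEB])


def mi_difference(data, outcome: pd.Series, m: int = 50, seed: int = 0,
                  delta: Tuple[float, float] = (0.0, 0.0),
                  predictors: Sequence[str] = STRATA_FACTORS,
                  name: Optional[str] = None) -> EstimateResult:
    """MI-adjusted arm contrast over all randomized patients.

    Imputes missing scores (with the optional delta shift), takes the
    unweighted arm-mean difference per completed copy, and pools by Rubin's
    rules. ``delta=(0,0)`` is the MAR analysis.
    """
    df = as_frame(data)
    imputed = impute_outcomes(df, outcome, m=m, delta=delta, seed=seed,
                              predictors=predictors)
    ests, variances = zip(*(_copy_difference(df, imputed.completed[j]) for j in range(m)))
    res = rubin_pool(ests, variances, outcome=name or imputed.outcome, method="mi",
                     n_analyzed=len(df))
    return res
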