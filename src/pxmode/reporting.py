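"""Descriptive tables, subgroup analyses, and the power helper.

Covers the secondary outputs around the main mode-effect estimates: the
response-rate table by mode and participant characteristic with chi-square
tests, subgroup estimates with interaction tests, the per-group sample-size
requirement for a two-sample t-test, and assembly of the headline results
table (arm means and the three adjusted/unadjusted differences per outcome).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .dataset import FACTOR_LEVELS, STRATA_FACTORS, as_frame
from .errors import EstimationError, ValidationError
from .estimation import (
    EstimateResult,
    fit_response_propensity,
    impute_outcomes,
    ipw_difference,
    mi_difference,
    unadjusted_difference,
)
from .scoring import DOMAINS, OUTCOME_NAMES, outcome_series, score_dataset
from .synthetic import MOBILE_WEB, TELEPHONE

SUBGROUP_VARIABLES = ("sex", "age_group", "care_field")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (matches conventional table formatting)."""
    scale = 10.0**ndigits
    # pre-round at 6 extra decimals so binary representation error does not
    # flip a decimal tie (e.g. 2.045 stored as 2.04499...)
    v = round(abs(x) * scale, 6)
    return math.copysign(math.floor(v + 0.5), x) / scale


def chi_square_mode_response(n_resp_tel: int, n_tel: int,
                             n_resp_mob: int, n_mob: int) -> Tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    mode-by-response table."""
    counts = (n_resp_tel, n_tel, n_resp_mob, n_mob)
    if any(c < 0 for c in counts):
        raise ValidationError("counts must be nonnegative")
    if n_resp_tel > n_tel or n_resp_mob > n_mob:
        raise ValidationError("respondents cannot exceed randomized")
    table = np.array(
        [[n_resp_tel, n_tel - n_resp_tel], [n_resp_mob, n_mob - n_resp_mob]]
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("undefined test: a margin of the 2x2 table is zero")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


@dataclass
class ResponseRateTable:
    """Response rates by characteristic level and mode.

    ``table`` has one row per (characteristic, level) plus a Total row, with
    respondents/randomized counts and percentages for all patients and per
    mode, and the within-level 2x2 mode-by-response chi-square test.
    ``overall_tests`` additionally holds, per characteristic, a
    likelihood-ratio test of the mode-by-characteristic interaction in a
    logistic response model (the pooled reading of a table-wide p-value).
    """

    table: pd.DataFrame
    overall_tests: Dict[str, Tuple[float, int, float]]

    def formatted(self) -> pd.DataFrame:
        out = self.table.copy()
        for col in ("all_pct", "tel_pct", "mob_pct"):
            out[col] = out[col].map(lambda v: round_half_away(v, 1))
        return out


def _rate_row(sub: pd.DataFrame) -> dict:
    r = sub["responded"].astype(bool)
    tel = sub["arm"] == TELEPHONE
    mob = sub["arm"] == MOBILE_WEB
    row = dict(
        all_resp=int(r.sum()), all_n=len(sub),
        tel_resp=int(r[tel].sum()), tel_n=int(tel.sum()),
        mob_resp=int(r[mob].sum()), mob_n=int(mob.sum()),
    )
    for k in ("all", "tel", "mob"):
        n = row[f"{k}_n"]
        row[f"{k}_pct"] = 100.0 * row[f"{k}_resp"] / n if n else float("nan")
    try:
        stat, p = chi_square_mode_response(
            row["tel_resp"], row["tel_n"], row["mob_resp"], row["mob_n"]
        )
    except ValidationError:
        stat, p = float("nan"), float("nan")  # undefined: reported as N/A
    row["chi2"], row["p"] = stat, p
    return row


def response_rate_table(data) -> ResponseRateTable:
    """Table-1-style response-rate summary with per-level and pooled tests."""
    import statsmodels.api as sm

    df = as_frame(data)
    rows = [dict(characteristic="total", level="total", **_rate_row(df))]
    overall: Dict[str, Tuple[float, int, float]] = {}
    r = df["responded"].astype(bool).to_numpy(dtype=float)
    for factor in STRATA_FACTORS:
        for level in FACTOR_LEVELS[factor]:
            sub = df[df[factor] == level]
            if len(sub) == 0:
                continue
            rows.append(dict(characteristic=factor, level=level, **_rate_row(sub)))
        # pooled test: LR of responded ~ arm * factor vs arm + factor
        try:
            X0 = patsy.dmatrix(f"1 + C(arm) + C({factor})", df, return_type="dataframe")
            X1 = patsy.dmatrix(f"1 + C(arm) * C({factor})", df, return_type="dataframe")
            fam = sm.families.Binomial()
            dev0 = sm.GLM(r, X0.to_numpy(), family=fam).fit().deviance
            dev1 = sm.GLM(r, X1.to_numpy(), family=fam).fit().deviance
            k = X1.shape[1] - X0.shape[1]
            lr = max(dev0 - dev1, 0.0)
            overall[factor] = (float(lr), int(k), float(stats.chi2.sf(lr, k)))
        except Exception:
            overall[factor] = (float("nan"), 0, float("nan"))
    return ResponseRateTable(table=pd.DataFrame(rows), overall_tests=overall)


# --------------------------------------------------------------------------
# Subgroup analyses

@dataclass
class SubgroupResult:
    variable: str
    estimates: Dict[str, Dict[str, EstimateResult]]  # level -> method -> result
    interaction_p: Dict[str, float]  # method -> p


def _interaction_terms(df: pd.DataFrame, variable: str):
    design = patsy.dmatrix(f"1 + C(arm) * C({variable})", df, return_type="dataframe")
    names = list(design.columns)
    inter = [i for i, c in enumerate(names) if ":" in c]
    if not inter:
        raise EstimationError(f"no interaction terms for variable {variable!r}")
    return design.to_numpy(dtype=float), inter


def _wald_interaction_p(beta: np.ndarray, cov: np.ndarray, idx) -> float:
    b = beta[idx]
    V = cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(stat, len(idx)))


def _pooled_interaction_p(qs: np.ndarray, us: np.ndarray) -> float:
    """Multivariate Rubin pooling (D1) of per-copy interaction contrasts."""
    m, k = qs.shape
    qbar = qs.mean(axis=0)
    Wbar = us.mean(axis=0)
    B = np.cov(qs.T, ddof=1).reshape(k, k)
    r = (1.0 + 1.0 / m) * np.trace(B @ np.linalg.inv(Wbar)) / k
    F = float(qbar @ np.linalg.solve(Wbar, qbar)) / (k * (1.0 + r))
    t = k * (m - 1)
    if r <= 0:
        r = 1e-12
    if t > 4:
        df2 = 4.0 + (t - 4.0) * (1.0 + (1.0 - 2.0 / t) / r) ** 2
    else:
        df2 = 0.5 * t * (1.0 + 1.0 / k) * (1.0 + 1.0 / r) ** 2
    return float(stats.f.sf(F, k, df2))


def subgroup_analysis(data, outcome: pd.Series, variable: str,
                      methods: Sequence[str] = ("unadjusted", "ipw", "mi"),
                      m: int = 50, seed: int = 0) -> SubgroupResult:
    """Per-level mode effects and a mode-by-subgroup interaction test.

    Levels are analyzed by restricting the data to the level; the propensity
    and imputation models then drop the subgroup variable from their
    predictors. Interaction p-values come from a Wald test of the
    arm-by-variable terms in a linear outcome model: on respondents
    (unadjusted), IPW-weighted with a robust covariance (ipw), or fit per
    imputed copy and pooled (mi).
    """
    import statsmodels.api as sm

    if variable not in SUBGROUP_VARIABLES:
        raise ValidationError(
            f"subgroup variable must be one of {SUBGROUP_VARIABLES}, got {variable!r}"
        )
    df = as_frame(data)
    y = outcome.reindex(df.index)
    levels = [l for l in FACTOR_LEVELS[variable] if (df[variable] == l).any()]
    if len(levels) < 2:
        raise EstimationError(
            f"interaction test undefined: {variable!r} has a single level"
        )
    resp = df["responded"].astype(bool)
    for level in levels:
        for arm in (TELEPHONE, MOBILE_WEB):
            if not (resp & (df[variable] == level) & (df["arm"] == arm)).any():
                raise EstimationError(
                    f"no respondents in cell {variable}={level}, arm={arm}"
                )
    other = tuple(f for f in STRATA_FACTORS if f != variable)
    estimates: Dict[str, Dict[str, EstimateResult]] = {}
    for level in levels:
        mask = df[variable] == level
        sub, suby = df[mask], y[mask]
        per: Dict[str, EstimateResult] = {}
        if "unadjusted" in methods:
            per["unadjusted"] = unadjusted_difference(sub, suby)
        if "ipw" in methods:
            fit = fit_response_propensity(sub, factors=("arm",) + other)
            per["ipw"] = ipw_difference(sub, suby, fit)
        if "mi" in methods:
            per["mi"] = mi_difference(sub, suby, m=m, seed=seed, predictors=other)
        estimates[level] = per

    interaction_p: Dict[str, float] = {}
    X, inter_idx = _interaction_terms(df, variable)
    if "unadjusted" in methods:
        keep = (resp & y.notna()).to_numpy()
        res = sm.OLS(y.to_numpy()[keep], X[keep]).fit()
        interaction_p["unadjusted"] = _wald_interaction_p(
            res.params, res.cov_params(), inter_idx
        )
    if "ipw" in methods:
        fit = fit_response_propensity(df)
        keep = (resp & y.notna()).to_numpy()
        w = (1.0 / fit.pi.to_numpy())[keep]
        res = sm.WLS(y.to_numpy()[keep], X[keep], weights=w).fit(cov_type="HC0")
        interaction_p["ipw"] = _wald_interaction_p(
            res.params, res.cov_params(), inter_idx
        )
    if "mi" in methods:
        imputed = impute_outcomes(df, y, m=m, seed=seed)
        qs, us = [], []
        for j in range(imputed.m):
            res = sm.OLS(imputed.completed[j], X).fit()
            qs.append(res.params[inter_idx])
            us.append(res.cov_params()[np.ix_(inter_idx, inter_idx)])
        interaction_p["mi"] = _pooled_interaction_p(np.asarray(qs), np.asarray(us))
    return SubgroupResult(variable=variable, estimates=estimates,
                          interaction_p=interaction_p)


# --------------------------------------------------------------------------
# Power / sample size

def _t_power(n: int, effect: float, alpha: float) -> float:
    df = 2 * n - 2
    if df < 1:
        return 0.0
    ncp = effect * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_sample_size(difference: float, sd: float,
                         power: float = 0.80, alpha: float = 0.05) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    Iterates the exact noncentral-t power formula upward from the normal
    approximation (which understates n slightly).
    """
    if difference == 0:
        raise ValidationError("difference must be nonzero")
    if sd <= 0 or not 0 < power < 1 or not 0 < alpha < 1:
        raise ValidationError("require sd > 0 and power, alpha strictly in (0, 1)")
    effect = abs(difference) / sd
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    n = max(2, math.ceil(2.0 * z**2 / effect**2) - 2)
    while _t_power(n, effect, alpha) < power:
        n += 1
        if n > 10_000_000:
            raise ValidationError("unattainable power for the given inputs")
    while n > 2 and _t_power(n - 1, effect, alpha) >= power:
        n -= 1
    return n


# --------------------------------------------------------------------------
# Headline results table

@dataclass
class ResultsTable:
    """Arm means (SD) among respondents plus the three differences per outcome."""

    table: pd.DataFrame
    estimates: Dict[Tuple[str, str], EstimateResult]  # (outcome, method) -> result

    def formatted(self) -> pd.DataFrame:
        out = self.table.copy()
        num = out.select_dtypes(include=[float]).columns
        for col in num:
            out[col] = out[col].map(
                lambda v: round_half_away(v, 2) if pd.notna(v) else v
            )
        return out


def results_table(data, scores: Optional[pd.DataFrame] = None,
                  outcomes: Sequence[str] = OUTCOME_NAMES,
                  methods: Sequence[str] = ("unadjusted", "ipw", "mi"),
                  m: int = 50, seed: int = 0) -> ResultsTable:
    """Assemble the headline per-outcome mode-effect table."""
    df = as_frame(data)
    if scores is None:
        scores = score_dataset(df)
    fit = None
    if "ipw" in methods:
        if df["responded"].astype(bool).all():
            # complete response: weights are identically 1 and IPW collapses
            # to the unadjusted analysis
            from .estimation import unit_propensity_fit

            fit = unit_propensity_fit(df)
        else:
            fit = fit_response_propensity(df)
    rows, estimates = [], {}
    for out_name in outcomes:
        y = outcome_series(df, scores, out_name)
        resp = df["responded"].astype(bool) & y.notna()
        row: dict = {"outcome": out_name}
        for arm, tag in ((TELEPHONE, "tel"), (MOBILE_WEB, "mob")):
            vals = y[resp & (df["arm"] == arm)]
            row[f"{tag}_mean"] = float(vals.mean())
            row[f"{tag}_sd"] = float(vals.std(ddof=1))
        for method in methods:
            if method == "unadjusted":
                est = unadjusted_difference(df, y)
            elif method == "ipw":
                est = ipw_difference(df, y, fit)
            elif method == "mi":
                est = mi_difference(df, y, m=m, seed=seed)
            else:
                raise ValidationError(f"unknown method {method!r}")
            estimates[(out_name, method)] = est
            row[f"{method}_diff"] = est.difference
            row[f"{method}_ci_low"] = est.ci_low
            row[f"{method}_ci_high"] = est.ci_high
            row[f"{method}_p"] = est.p_value
        rows.append(row)
    return ResultsTable(table=pd.DataFrame(rows), estimates=estimates)
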