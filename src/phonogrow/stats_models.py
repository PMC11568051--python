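"""Regression models for growth-spurt proportions and weighted-degree counts.

Three models, all with the linear predictor ``Spurt + AoA + Frequency(log) +
Length`` (Spurt and AoA treatment-coded against level 1, covariates
continuous):

* proportional degree gain   — quasi-binomial GLM, logit link;
* proportional saturation gain — quasi-binomial GLM, logit link;
* average weighted degree (integer) — zero-inflated negative binomial (NB2,
  logistic zero-inflation, same regressors in both components).

Quasi-binomial means a binomial GLM whose dispersion is estimated from the
Pearson chi-square; quasi-likelihoods have no true likelihood, so McFadden's
pseudo-R-squared ``1 - llf_model / llf_null`` is computed from the underlying
binomial log-likelihood.  Post-hoc spurt comparisons are estimated marginal
means re-gridded to the response scale (averaged over AoA levels at mean
covariates), with delta-method standard errors and Tukey (studentized-range)
family-wise adjustment over the spurt pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP
from statsmodels.stats.outliers_influence import variance_inflation_factor

# Cohen-style odds-ratio thresholds: below the first is a negligible effect.
_OR_THRESHOLDS = ((1.68, "Very small"), (3.47, "Small"), (6.71, "Medium"))

CONTINUOUS_TERMS = ("Frequency (log)", "Length")


class ModelError(RuntimeError):
    pass


def _design(table: pd.DataFrame) -> pd.DataFrame:
    """Treatment-coded design matrix against spurt 1 / AoA 1."""
    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    for level in sorted(table["spurt"].unique())[1:]:
        X[f"Spurt {level}"] = (table["spurt"] == level).astype(float)
    for level in sorted(table["aoa"].unique())[1:]:
        X[f"AoA {level}"] = (table["aoa"] == level).astype(float)
    X["Frequency (log)"] = table["freq_log"].astype(float)
    X["Length"] = table["length"].astype(float)
    return X


def _coef_frame(names: Sequence[str], est, se, stat, p) -> pd.DataFrame:
    return pd.DataFrame(
        {"term": list(names), "estimate": est, "se": se, "statistic": stat, "p": p}
    ).reset_index(drop=True)


def _vifs(X: pd.DataFrame) -> dict[str, float]:
    cols = [c for c in X.columns if c != "Intercept"]
    arr = X.to_numpy(dtype=float)
    return {
        c: float(variance_inflation_factor(arr, list(X.columns).index(c))) for c in cols
    }


def effect_size_label(odds_ratio: float) -> str:
    """Cohen-threshold label, applied symmetrically to ORs below 1."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    magnitude = odds_ratio if odds_ratio >= 1 else 1.0 / odds_ratio
    for cut, label in _OR_THRESHOLDS:
        if magnitude < cut:
            return label
    return "Large"


def standardized_odds_ratios(coef: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    """exp(b * SD(x)) for continuous terms, exp(b) otherwise, with labels."""
    rows = []
    for _, r in coef.iterrows():
        b = r["estimate"]
        if r["term"] in CONTINUOUS_TERMS:
            b = b * float(X[r["term"]].std(ddof=1))
        orat = float(np.exp(b))
        rows.append({"term": r["term"], "std_or": orat, "effect_size": effect_size_label(orat)})
    return pd.DataFrame(rows)


@dataclass
class FitResult:
    """Tidy fit summary plus the pieces needed for post-hoc contrasts."""

    model_type: str
    dv: str
    coefficients: pd.DataFrame
    nobs: int
    dispersion: float | None = None
    mcfadden_r2: float | None = None
    vif: dict[str, float] = field(default_factory=dict)
    std_odds_ratios: pd.DataFrame | None = None
    zero_coefficients: pd.DataFrame | None = None
    converged: bool = True
    _sm_result: object = field(default=None, repr=False)
    _X: pd.DataFrame = field(default=None, repr=False)
    _table: pd.DataFrame = field(default=None, repr=False)

    def to_tidy(self) -> pd.DataFrame:
        out = self.coefficients.assign(component="count" if self.zero_coefficients is not None else "mean")
        if self.zero_coefficients is not None:
            out = pd.concat(
                [out, self.zero_coefficients.assign(component="zero")], ignore_index=True
            )
        return out


def fit_proportional_model(table: pd.DataFrame, dv: str = "degree_gain") -> FitResult:
    """Quasi-binomial logit GLM for a Smithson-Verkuilen-squeezed proportion.

    ``dv`` selects ``prop_degree_gain`` or ``prop_saturation_gain``; rows with
    a missing DV (e.g. words without an L1 benchmark in the saturation model)
    are dropped.
    """
    col = {"degree_gain": "prop_degree_gain", "saturation_gain": "prop_saturation_gain"}.get(dv)
    if col is None:
        raise ValueError(f"unknown proportional DV {dv!r}")
    sub = table.dropna(subset=[col]).reset_index(drop=True)
    if len(sub) == 0:
        raise ModelError(f"no usable rows for DV {dv!r}")
    y = sub[col].to_numpy(dtype=float)
    if not ((y > 0) & (y < 1)).all():
        raise ModelError("proportional DV must lie strictly in (0,1); apply sv_transform first")
    if np.ptp(y) == 0:
        raise ModelError("constant DV; model is not identifiable")
    X = _design(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(scale="X2")
        null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial()).fit()
    mcfadden = float(1.0 - res.llf / null.llf)
    coef = _coef_frame(X.columns, res.params.values, res.bse.values, res.tvalues.values, res.pvalues.values)
    return FitResult(
        model_type="quasibinomial",
        dv=dv,
        coefficients=coef,
        nobs=int(res.nobs),
        dispersion=float(res.scale),
        mcfadden_r2=mcfadden,
        vif=_vifs(X),
        std_odds_ratios=standardized_odds_ratios(coef, X),
        _sm_result=res,
        _X=X,
        _table=sub,
    )


def fit_zinb_model(table: pd.DataFrame, dv: str = "avg_wd_int") -> FitResult:
    """Zero-inflated negative binomial fit for the integer weighted-degree DV.

    The count component is NB2 with log link, the zero-inflation component a
    logistic regression on the same design.  Non-convergence is signalled via
    ``converged=False`` (coefficients still reported, with diagnostics left to
    the caller); degenerate inflation estimates (e.g. a level with no zeros at
    all) are reported as-is.
    """
    sub = table.dropna(subset=[dv]).reset_index(drop=True)
    y = sub[dv].to_numpy()
    if not np.issubdtype(np.asarray(y).dtype, np.integer):
        if not np.allclose(y, np.round(y)):
            raise ModelError("zero-inflated NB requires integer counts")
        y = np.round(y).astype(int)
    if (y < 0).any():
        raise ModelError("counts must be non-negative")
    X = _design(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ZeroInflatedNegativeBinomialP(
            y, X.to_numpy(), exog_infl=X.to_numpy(), inflation="logit", p=2
        )
        # The ZINB likelihood is multimodal: from poor starts the optimizer
        # can park all zeros in the count component (inflation -> -inf, alpha
        # inflated).  Fit from the default start and from an informed start
        # (plain NB for the count part, excess-zero logit intercept for the
        # inflation part) and keep the better optimum.
        candidates = []
        try:
            res_a = model.fit(method="bfgs", maxiter=500, disp=0)
            candidates.append(res_a)
        except Exception:
            pass
        try:
            from statsmodels.discrete.discrete_model import NegativeBinomialP

            nb = NegativeBinomialP(y, X.to_numpy(), p=2).fit(disp=0, maxiter=200)
            zero_obs = float((y == 0).mean())
            zero_nb = float(np.mean((1 + nb.params[-1] * np.exp(nb.fittedvalues)) ** (-1 / nb.params[-1])))
            excess = np.clip(zero_obs - zero_nb, 0.02, 0.95)
            start = np.concatenate(
                [
                    [np.log(excess / (1 - excess))],
                    np.zeros(X.shape[1] - 1),
                    nb.params,
                ]
            )
            res_b = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
            candidates.append(res_b)
        except Exception:
            pass
        if not candidates:
            raise ModelError("zero-inflated NB fit failed from all starts")
        finite = [r for r in candidates if not np.isnan(np.asarray(r.bse)).any()]
        pool = finite or candidates
        res = max(pool, key=lambda r: r.llf)
    names_infl = [f"Zero_{c}" for c in X.columns]
    names = names_infl + list(X.columns) + ["alpha"]
    est, se = np.asarray(res.params), np.asarray(res.bse)
    stat = est / se
    p = 2 * sps.norm.sf(np.abs(stat))
    k = len(X.columns)
    count_coef = _coef_frame(list(X.columns) + ["alpha"], est[k:], se[k:], stat[k:], p[k:])
    zero_coef = _coef_frame(list(X.columns), est[:k], se[:k], stat[:k], p[:k])
    or_count = standardized_odds_ratios(count_coef[count_coef["term"] != "alpha"], X)
    or_zero = standardized_odds_ratios(zero_coef, X).assign(
        term=lambda d: "Zero_" + d["term"]
    )
    return FitResult(
        model_type="zinb",
        dv=dv,
        coefficients=count_coef,
        zero_coefficients=zero_coef,
        nobs=int(res.nobs),
        mcfadden_r2=None,
        vif=_vifs(X),
        std_odds_ratios=pd.concat([or_count, or_zero], ignore_index=True),
        converged=bool(res.mle_retvals.get("converged", True))
        if isinstance(getattr(res, "mle_retvals", None), dict)
        else True,
        _sm_result=res,
        _X=X,
        _table=sub,
    )


def _emm_grid(fit: FitResult) -> tuple[list[int], list[np.ndarray]]:
    """Per-spurt design rows averaged over AoA levels at mean covariates."""
    X, table = fit._X, fit._table
    spurts = sorted(table["spurt"].unique())
    aoas = sorted(table["aoa"].unique())
    cols = list(X.columns)
    f_mean = float(table["freq_log"].mean())
    l_mean = float(table["length"].mean())
    grid_rows: list[np.ndarray] = []
    for s in spurts:
        rows = []
        for a in aoas:
            row = np.zeros(len(cols))
            row[cols.index("Intercept")] = 1.0
            if f"Spurt {s}" in cols:
                row[cols.index(f"Spurt {s}")] = 1.0
            if f"AoA {a}" in cols:
                row[cols.index(f"AoA {a}")] = 1.0
            row[cols.index("Frequency (log)")] = f_mean
            row[cols.index("Length")] = l_mean
            rows.append(row)
        grid_rows.append(np.vstack(rows))
    return spurts, grid_rows


def pairwise_spurt_contrasts(fit: FitResult) -> pd.DataFrame:
    """Tukey-adjusted pairwise spurt differences on the response scale.

    Estimated marginal proportions per spurt are the response-scale
    predictions averaged over AoA levels with covariates at their means.
    Standard errors come from the delta method under the (dispersion-scaled)
    coefficient covariance; p-values use the studentized-range distribution
    over the number of spurt levels.
    """
    if fit.model_type != "quasibinomial":
        raise ModelError("response-scale spurt contrasts require a proportional model fit")
    res = fit._sm_result
    beta = np.asarray(res.params)
    cov = np.asarray(res.cov_params())
    spurts, grids = _emm_grid(fit)
    k = len(spurts)
    est, grad = [], []
    for G in grids:
        eta = G @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        est.append(float(mu.mean()))
        grad.append((mu * (1 - mu)) @ G / len(mu))
    df_resid = float(res.df_resid)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            d = est[i] - est[j]
            g = grad[i] - grad[j]
            se = float(np.sqrt(g @ cov @ g))
            z = d / se if se > 0 else np.nan
            p = float(sps.studentized_range.sf(abs(z) * np.sqrt(2.0), k, df_resid))
            rows.append(
                {
                    "contrast": f"Spurts {spurts[i]} - {spurts[j]}",
                    "estimate": d,
                    "se": se,
                    "z_ratio": z,
                    "p_tukey": min(1.0, p),
                }
            )
    return pd.DataFrame(rows)


def spurt_emmeans(fit: FitResult) -> pd.DataFrame:
    """Estimated marginal proportions per spurt (response scale)."""
    res = fit._sm_result
    beta = np.asarray(res.params)
    spurts, grids = _emm_grid(fit)
    out = []
    for s, G in zip(spurts, grids):
        mu = 1.0 / (1.0 + np.exp(-(G @ beta)))
        out.append({"spurt": s, "estimate": float(mu.mean())})
    return pd.DataFrame(out)
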