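"""Multiple linear regression of RBC endpoints with genetic covariates.

Each model regresses one RBC endpoint (a parameter at a timepoint) on
sex, age, a clinical-status dummy appropriate to the timepoint, and one
genetic covariate: the per-person QV count in a gene set.  Continuous
variables (including the dependent) are z-scored so the reported
coefficients are standardized betas; dummy covariates enter as coded
(sex male 1 / female 2, status dummies per cohort convention).

Every fit reports R^2 with its overall-F p-value, per-covariate
standardized betas with t-based 95% CIs and p-values, and the
diagnostics used to audit the fits: Durbin-Watson (independence,
acceptable range 1.50-2.50), Breusch-Pagan (homoscedasticity),
variance inflation factors (multicollinearity, flag at 5) and
Shapiro-Wilk on the residuals (normality — reported, never gating:
with more than ten observations per variable OLS is robust to
moderate non-normality and the fit proceeds regardless).

Model screening applies Benjamini-Hochberg separately to the R^2
p-values and to the covariate p-values within each declared FDR
family, both at threshold 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.stattools import durbin_watson as _sm_dw

from .stats_core import TestResult, bh_fdr, shapiro_wilk

__all__ = ["Covariate", "ModelSpec", "MLRResult", "fit_mlr", "durbin_watson",
           "breusch_pagan", "vif", "model_screen", "DW_RANGE", "VIF_FLAG"]

DW_RANGE = (1.50, 2.50)
VIF_FLAG = 5.0


@dataclass(frozen=True)
class Covariate:
    """One independent variable: continuous (z-scored) or dummy (as coded)."""

    name: str
    kind: str = "continuous"  # or "dummy"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "dummy"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class ModelSpec:
    """Specification of one regression model.

    ``dependent`` names the endpoint column (e.g. "MCHC_minmax");
    ``covariates`` typically hold sex (dummy), age (continuous), a
    clinical-status dummy, and the genetic qv_count (continuous).
    ``family_id`` groups models for FDR screening.
    """

    dependent: str
    covariates: tuple[Covariate, ...]
    family_id: str = "default"

    def __post_init__(self) -> None:
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicated covariates: {names}")
        if not self.covariates:
            raise ValueError("need at least one covariate")


@dataclass
class MLRResult:
    """Fit summary: R^2, standardized betas, diagnostics."""

    dependent: str
    family_id: str
    n: int
    r_squared: float
    f_pvalue: float
    coef: pd.DataFrame  # covariate, beta, ci_low, ci_high, p
    durbin_watson: float
    dw_in_range: bool
    breusch_pagan_p: float
    vif: pd.Series
    max_vif: float
    shapiro_p: float
    flags: tuple[str, ...] = ()


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be z-scored")
    return (x - x.mean()) / sd


def fit_mlr(spec: ModelSpec, data: pd.DataFrame) -> MLRResult:
    """Ordinary least squares with standardized coefficients.

    Rows with any missing value among the model columns are dropped.
    Rank-deficient designs raise an error naming the collinear
    columns.  A sample size below ten observations per covariate is
    flagged ("low-n"), not fatal.
    """
    cols = [spec.dependent] + [c.name for c in spec.covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns absent from data: {missing}")
    df = data[cols].dropna()
    n = len(df)
    k = len(spec.covariates)
    flags: list[str] = []
    if n <= 10 * k:
        flags.append("low-n")
    if n < k + 2:
        raise ValueError(f"not enough observations ({n}) for {k} covariates")

    y = _zscore(df[spec.dependent].to_numpy(dtype=float))
    X = np.empty((n, k))
    for j, cov in enumerate(spec.covariates):
        col = df[cov.name].to_numpy(dtype=float)
        X[:, j] = _zscore(col) if cov.kind == "continuous" else col
    design = sm.add_constant(pd.DataFrame(X, columns=[c.name for c in spec.covariates]),
                             has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = _collinear_columns(design)
        raise ValueError(f"design matrix rank-deficient; collinear columns: {bad}")

    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame({
        "covariate": [c.name for c in spec.covariates],
        "beta": [fit.params[c.name] for c in spec.covariates],
        "ci_low": [ci.loc[c.name, 0] for c in spec.covariates],
        "ci_high": [ci.loc[c.name, 1] for c in spec.covariates],
        "p": [fit.pvalues[c.name] for c in spec.covariates],
    })

    resid = np.asarray(fit.resid)
    try:
        dw = durbin_watson(resid)
    except ValueError:  # perfect fit: zero residuals
        dw = float("nan")
        flags.append("dw-undefined")
    bp = breusch_pagan(resid, design.to_numpy())
    vifs = vif(design)
    try:
        sw_p = shapiro_wilk(resid).p_value
    except ValueError:
        sw_p = float("nan")
        flags.append("shapiro-skipped")
    f_p = float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else float("nan")
    return MLRResult(
        dependent=spec.dependent, family_id=spec.family_id, n=n,
        r_squared=float(fit.rsquared), f_pvalue=f_p, coef=coef,
        durbin_watson=dw,
        dw_in_range=bool(np.isfinite(dw) and DW_RANGE[0] <= dw <= DW_RANGE[1]),
        breusch_pagan_p=bp.p_value, vif=vifs, max_vif=float(vifs.max()),
        shapiro_p=float(sw_p), flags=tuple(flags))


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    bad = []
    X = design.to_numpy()
    for j, name in enumerate(design.columns):
        if name == "const":
            continue
        others = np.delete(X, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
        resid = X[:, j] - others @ beta
        if np.allclose(resid, 0, atol=1e-8):
            bad.append(name)
    return bad or list(design.columns)


def durbin_watson(residuals: Sequence[float]) -> float:
    """DW = sum (e_t - e_{t-1})^2 / sum e_t^2, in [0, 4]."""
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    if np.allclose(e, 0):
        raise ValueError("zero residual sum of squares; DW undefined")
    return float(_sm_dw(e))


def breusch_pagan(residuals: Sequence[float], design: np.ndarray) -> TestResult:
    """Breusch-Pagan LM test: n * R^2 of e^2 regressed on the design."""
    e = np.asarray(residuals, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != e.size:
        raise ValueError("design must be 2-D with one row per residual")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lm, lm_p, _, _ = het_breuschpagan(e, X)
    if not np.isfinite(lm_p):
        return TestResult(statistic=float(lm), p_value=1.0,
                          method="breusch_pagan", flags=("degenerate-aux-fit",))
    return TestResult(statistic=float(lm), p_value=float(lm_p),
                      method="breusch_pagan", df=X.shape[1] - 1)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per non-constant design column.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the others
    (intercept included).  Perfect collinearity reports inf.
    """
    cols = [c for c in design.columns if c != "const"]
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 covariates")
    X = design.to_numpy(dtype=float)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in cols:
            j = list(design.columns).index(name)
            try:
                v = variance_inflation_factor(X, j)
            except Exception:
                v = float("inf")
            out[name] = float("inf") if not np.isfinite(v) else float(v)
    return pd.Series(out, name="vif")


def model_screen(results: Sequence[MLRResult], r2_fdr: float = 0.1,
                 beta_fdr: float = 0.1,
                 genetic_covariate: str = "qv_count") -> pd.DataFrame:
    """BH screening of a collection of fitted models.

    Within each FDR family, R^2 (overall-F) p-values form one BH family
    and covariate p-values another.  Returns a long table (one row per
    model x covariate) carrying model-level q_r2 and covariate-level q,
    with significance flags at the given thresholds and a convenience
    flag for the genetic covariate.
    """
    base_cols = ("covariate", "beta", "ci_low", "ci_high", "p")
    rows = []
    for i, res in enumerate(results):
        for _, c in res.coef.iterrows():
            extra = {k: c[k] for k in res.coef.columns if k not in base_cols}
            rows.append({
                **extra,
                "model": i, "family_id": res.family_id,
                "dependent": res.dependent, "n": res.n,
                "r2": res.r_squared, "r2_p": res.f_pvalue,
                "covariate": c["covariate"], "beta": c["beta"],
                "ci_low": c["ci_low"], "ci_high": c["ci_high"], "p": c["p"],
                "durbin_watson": res.durbin_watson,
                "dw_in_range": res.dw_in_range,
                "breusch_pagan_p": res.breusch_pagan_p,
                "max_vif": res.max_vif, "shapiro_p": res.shapiro_p,
            })
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["r2_q"] = np.nan
    out["q"] = np.nan
    for fam, sub in out.groupby("family_id"):
        models = sub.drop_duplicates("model")
        q_r2, _ = bh_fdr(models["r2_p"].to_numpy(), threshold=r2_fdr)
        q_map = dict(zip(models["model"], q_r2))
        out.loc[sub.index, "r2_q"] = sub["model"].map(q_map)
        q_cov, _ = bh_fdr(sub["p"].to_numpy(), threshold=beta_fdr)
        out.loc[sub.index, "q"] = q_cov
    out["r2_significant"] = out["r2_q"] < r2_fdr
    out["significant"] = out["q"] < beta_fdr
    out["genetic"] = out["covariate"] == genetic_covariate
    return out
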