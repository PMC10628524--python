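"""Regression layer: mixed models, recall/reactivity regressions, group tests.

Per frequency band the analyses are:

- a linear mixed-effects model ``sw ~ disease + condition + age`` with
  subject-specific random intercepts, fitted by maximum likelihood, reported
  with cluster-by-subject sandwich standard errors and z statistics
  (significance threshold alpha = 0.05);
- per group x condition, ordinary least squares ``sw ~ delayed_recall + age``
  with heteroscedasticity-robust (HC1) standard errors and t statistics
  (alpha = 0.025, the two-group multiplicity correction);
- per group, the same OLS with the eyes-state reactivity
  (SW_EO - SW_EC)/(SW_EO + SW_EC) as outcome (alpha = 0.025);
- two-group demographics: pooled-variance Student t from summary statistics
  and Pearson chi-square (no continuity correction) on a 2x2 table.

Effect sizes: the mixed model reports standardized coefficients
(beta * sd(x)/sd(y)); the OLS fits report per-term partial eta squared
approximated as t^2 / (t^2 + residual df). Neither is claimed to match any
particular published effect-size convention — both definitions are stated
here and in the methods note.

Significance is always strict (``p < alpha``).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as spstats

from .core import GroupComparison, ModelResult, ValidationError

__all__ = [
    "fit_sw_mixed_model",
    "fit_recall_regression",
    "fit_reactivity_regression",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "significance_policy",
]

ALPHA_MIXED = 0.05
ALPHA_REGRESSION = 0.025

_MIXED_TERMS = ["intercept", "disease", "condition", "age"]
_OLS_TERMS = ["intercept", "delayed_recall", "age"]


def _check_band_slice(df: pd.DataFrame, band: str) -> pd.DataFrame:
    sl = df[df["band"] == band]
    if sl.empty:
        raise ValidationError(f"band: no rows for band {band!r}")
    return sl.reset_index(drop=True)


def _cluster_sandwich(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    groups: np.ndarray,
    tau2: float,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-based and cluster-robust covariance of the GLS fixed effects.

    For the random-intercept model, V_i = sigma2 * I + tau2 * J per subject,
    with closed-form inverse
    ``V_i^{-1} = (I - tau2/(sigma2 + n_i tau2) J) / sigma2``. The sandwich is
    ``A^{-1} B A^{-1} * G/(G-1)`` with bread ``A = sum X_i' V_i^{-1} X_i`` and
    meat ``B = sum (X_i' V_i^{-1} r_i)(.)'`` over subjects; the G/(G-1) factor
    is the conventional small-sample cluster adjustment.
    """
    k = X.shape[1]
    A = np.zeros((k, k))
    B = np.zeros((k, k))
    resid = y - X @ beta
    labels = pd.unique(groups)
    for g in labels:
        idx = groups == g
        Xi, ri = X[idx], resid[idx]
        ni = Xi.shape[0]
        shrink = tau2 / (sigma2 + ni * tau2) if tau2 > 0 else 0.0
        XtVinv = (Xi.T - shrink * np.outer(Xi.sum(axis=0), np.ones(ni))) / sigma2
        A += XtVinv @ Xi
        score = XtVinv @ ri
        B += np.outer(score, score)
    Ainv = np.linalg.inv(A)
    G = len(labels)
    robust = Ainv @ B @ Ainv * (G / (G - 1))
    return Ainv, robust


def fit_sw_mixed_model(
    table: pd.DataFrame,
    band: str,
    outcome: str = "sw",
    se_flavor: str = "cluster-robust",
    reml: bool = False,
) -> ModelResult:
    """Random-intercept mixed model of SW on disease, condition and age.

    Coding: control = 0 / AD = 1 and EC = 0 / EO = 1 (reference levels chosen
    so coefficient signs read as AD-relative and eyes-open-relative changes).
    Estimation is maximum likelihood by default (``reml=True`` switches).
    A fit on the boundary (between-subject variance ~ 0) degrades gracefully
    to the pooled-OLS sandwich and is flagged ``"boundary_random_effect"``.
    """
    sl = _check_band_slice(table, band)
    if sl["condition"].nunique() < 2:
        raise ValidationError("table: need both conditions (EO and EC) present")
    y = sl[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(sl)),
            (sl["group"] == "AD").to_numpy(dtype=float),
            (sl["condition"] == "EO").to_numpy(dtype=float),
            sl["age"].to_numpy(dtype=float),
        ]
    )
    groups = sl["subject_id"].to_numpy()
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        try:
            fit = model.fit(reml=reml, method="lbfgs")
        except Exception:
            fit = model.fit(reml=reml)
    beta = np.asarray(fit.fe_params, dtype=float)
    sigma2 = float(fit.scale)
    tau2 = float(np.asarray(fit.cov_re)[0, 0])
    icc = tau2 / (tau2 + sigma2) if (tau2 + sigma2) > 0 else 0.0
    if icc < 1e-6:
        tau2 = 0.0  # exact boundary: GLS degrades to pooled OLS + cluster sandwich
    if icc < 0.01:
        # the optimizer parks near (not at) a zero between-subject variance;
        # flag any fit whose between-subject share is negligible
        flags.append("boundary_random_effect")
    if not fit.converged:
        flags.append("not_converged")
    Ainv, robust_cov = _cluster_sandwich(X, y, beta, groups, tau2, sigma2)
    if se_flavor == "cluster-robust":
        se = np.sqrt(np.diag(robust_cov))
        flavor = "heteroscedasticity-robust"
    elif se_flavor == "model-based":
        se = np.sqrt(np.diag(Ainv))
        flavor = "model-based"
    else:
        raise ValidationError(f"se_flavor: expected 'cluster-robust' or 'model-based', got {se_flavor!r}")
    z = beta / se
    p = 2 * spstats.norm.sf(np.abs(z))
    sd_y = y.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    effect = np.where(sd_x > 0, beta * sd_x / max(sd_y, 1e-300), np.nan)
    return ModelResult(
        outcome=f"{outcome}[{band}]",
        terms=list(_MIXED_TERMS),
        coefficients=beta,
        robust_se=se,
        statistic=z,
        p_value=p,
        effect_size=effect,
        n_obs=len(sl),
        n_subjects=sl["subject_id"].nunique(),
        se_flavor=flavor,
        alpha_threshold=ALPHA_MIXED,
        statistic_name="z",
        flags=flags,
    )


def _ols_robust(
    y: np.ndarray, X: np.ndarray, terms: list[str], outcome: str, n_subjects: int,
    alpha: float, se_flavor: str,
) -> ModelResult:
    n, k = X.shape
    if n - k < 1:
        raise ValidationError(f"insufficient residual df: n={n} observations for {k} terms")
    flags: list[str] = []
    if np.allclose(y.var(), 0.0):
        # degenerate constant outcome: slopes are exactly the zero vector
        beta = np.zeros(k)
        beta[0] = y.mean()
        nan = np.full(k, np.nan)
        stat = np.zeros(k)
        flags.append("degenerate_constant_outcome")
        return ModelResult(
            outcome=outcome, terms=terms, coefficients=beta, robust_se=np.zeros(k),
            statistic=stat, p_value=nan, effect_size=np.zeros(k), n_obs=n,
            n_subjects=n_subjects, se_flavor=se_flavor, alpha_threshold=alpha,
            statistic_name="t", flags=flags,
        )
    if se_flavor == "always-robust":
        fit = sm.OLS(y, X).fit(cov_type="HC1", use_t=True)
        flavor = "heteroscedasticity-robust"
    elif se_flavor == "model-based":
        fit = sm.OLS(y, X).fit(use_t=True)
        flavor = "model-based"
    else:
        raise ValidationError(
            f"se_flavor: expected 'always-robust' or 'model-based', got {se_flavor!r}"
        )
    t = np.asarray(fit.tvalues, dtype=float)
    df_resid = float(fit.df_resid)
    eta2 = t**2 / (t**2 + df_resid)
    return ModelResult(
        outcome=outcome,
        terms=terms,
        coefficients=np.asarray(fit.params, dtype=float),
        robust_se=np.asarray(fit.bse, dtype=float),
        statistic=t,
        p_value=np.asarray(fit.pvalues, dtype=float),
        effect_size=eta2,
        n_obs=n,
        n_subjects=n_subjects,
        se_flavor=flavor,
        alpha_threshold=alpha,
        statistic_name="t",
        flags=flags,
    )


def fit_recall_regression(
    table: pd.DataFrame,
    band: str,
    group: str,
    condition: str,
    outcome: str = "sw",
    se_flavor: str = "always-robust",
) -> ModelResult:
    """OLS of SW (or C/L) on delayed recall + age within one group x condition.

    Robust (HC1) standard errors by default; t statistics use the residual df.
    Slices with n <= 3 raise (no residual degrees of freedom to speak of).
    """
    sl = _check_band_slice(table, band)
    sl = sl[(sl["group"] == group) & (sl["condition"] == condition)]
    if len(sl) <= 3:
        raise ValidationError(
            f"slice {group}/{condition}/{band}: n={len(sl)} <= 3, insufficient residual df"
        )
    y = sl[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sl)), sl["delayed_recall"].to_numpy(float), sl["age"].to_numpy(float)]
    )
    return _ols_robust(
        y, X, list(_OLS_TERMS), f"{outcome}[{band}|{group}|{condition}]",
        sl["subject_id"].nunique(), ALPHA_REGRESSION, se_flavor,
    )


def fit_reactivity_regression(
    table: pd.DataFrame,
    band: str,
    group: str,
    outcome: str = "reactivity",
    se_flavor: str = "always-robust",
) -> ModelResult:
    """OLS of eyes-state reactivity on delayed recall + age within one group.

    Expects one reactivity value per subject for the band. An all-constant
    outcome (e.g. identical EO/EC metrics everywhere) returns zero slopes
    flagged ``"degenerate_constant_outcome"``.
    """
    sl = _check_band_slice(table, band)
    sl = sl[sl["group"] == group]
    if sl["subject_id"].duplicated().any():
        raise ValidationError("table: expected one reactivity row per subject and band")
    if len(sl) <= 3:
        raise ValidationError(f"slice {group}/{band}: n={len(sl)} <= 3, insufficient residual df")
    y = sl[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sl)), sl["delayed_recall"].to_numpy(float), sl["age"].to_numpy(float)]
    )
    return _ols_robust(
        y, X, list(_OLS_TERMS), f"{outcome}[{band}|{group}]",
        sl["subject_id"].nunique(), ALPHA_REGRESSION, se_flavor,
    )


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> GroupComparison:
    """Pooled-variance Student t from group summaries, df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"n1/n2: need >= 2 per group, got ({n1}, {n2})")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("sd1/sd2: standard deviations must be >= 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return GroupComparison(variable, "t", 0.0, 1.0, df)
        raise ValidationError("zero pooled variance with unequal means: t undefined")
    t = (mean1 - mean2) / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2 * spstats.t.sf(abs(t), df)
    return GroupComparison(variable, "t", float(t), float(p), df)


def chi_square_2x2(a: int, b: int, c: int, d: int, variable: str = "") -> GroupComparison:
    """Pearson chi-square (no continuity correction) on [[a, b], [c, d]], df=1."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts: must be >= 0")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValidationError("counts: all row and column margins must be positive")
    chi2, p, df, _ = spstats.chi2_contingency(counts, correction=False)
    return GroupComparison(variable, "chi2", float(chi2), float(p), int(df))


def significance_policy(results: list[ModelResult], analysis_family: str) -> list[ModelResult]:
    """Annotate a family of results with the study's two-tier alpha policy.

    ``mixed`` models use alpha = 0.05; ``regression`` and ``reactivity``
    families use alpha = 0.025 (the only multiplicity correction applied — for
    the two disease groups; there is deliberately no correction across
    frequency bands). Significance is strict: p < alpha.
    """
    if analysis_family == "mixed":
        alpha = ALPHA_MIXED
    elif analysis_family in ("regression", "reactivity"):
        alpha = ALPHA_REGRESSION
    else:
        raise ValidationError(
            f"analysis_family: expected mixed|regression|reactivity, got {analysis_family!r}"
        )
    for r in results:
        r.alpha_threshold = alpha
        with np.errstate(invalid="ignore"):
            r.significant = np.where(np.isfinite(r.p_value), r.p_value < alpha, False)
    return results
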