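"""Regression machinery for one interaction pattern.

Fits the pattern's logistic or linear model, tests the interaction
terms jointly (likelihood-ratio test by default; Wald optional; exact
partial F-test for the linear family), and computes BIC for pattern
selection.  Non-convergence and separation are reported through flags,
never exceptions, so a pattern search can skip degenerate members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .patterns import (
    Direction,
    ModelStructure,
    PatternSpec,
    build_design,
    code_env,
    code_snp,
)

__all__ = ["FitResult", "PatternFit", "fit_glm", "interaction_test", "bic", "fit_pattern"]

# Separation / blow-up heuristics: a finite-sample logistic MLE should
# never legitimately reach these magnitudes on standardized codings.
_MAX_ABS_COEF = 15.0
_MAX_SE = 100.0
_MAXITER = 100
_TOL = 1e-8


@dataclass
class FitResult:
    """A fitted GLM: coefficients, covariance, likelihood, bookkeeping."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    log_likelihood: float
    n_used: int
    n_params: int
    converged: bool
    family: str
    ssr: float | None = None  # residual sum of squares (linear family only)

    @property
    def term_names(self) -> list[str]:
        return list(self.params.index)


@dataclass
class PatternFit:
    """One pattern's fit on a dataset, with its interaction test and BIC."""

    spec: PatternSpec
    fit: FitResult | None
    p_interaction: float | None
    per_term: pd.DataFrame | None
    bic: float | None
    estimable: bool
    n_used: int
    reason: str | None = None

    @property
    def label(self) -> str:
        return self.spec.label


def _validate_outcome(y: np.ndarray, family: str) -> None:
    if family == "logistic":
        vals = np.unique(y)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(
                f"logistic family requires a 0/1 outcome; observed values {vals[:6]}"
            )
    elif family != "linear":
        raise ValueError(f"family must be 'logistic' or 'linear', got {family!r}")


def fit_glm(design: pd.DataFrame, outcome, family: str = "logistic") -> FitResult:
    """Maximum-likelihood fit of a logistic or linear model.

    The linear family reports the Gaussian log-likelihood with the
    variance estimated by maximum likelihood, and counts the variance
    as a parameter, so BIC is comparable across families' conventions.
    Separation or non-convergence yields ``converged=False``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    _validate_outcome(y, family)
    n, p = X.shape
    names = list(design.columns)
    extra = 1 if family == "linear" else 0  # variance parameter
    if n <= p:
        return FitResult(
            params=pd.Series(np.nan, index=names),
            bse=pd.Series(np.nan, index=names),
            cov=pd.DataFrame(np.nan, index=names, columns=names),
            log_likelihood=np.nan, n_used=n, n_params=p + extra,
            converged=False, family=family,
        )
    converged = True
    ssr = None
    try:
        if family == "logistic":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                    maxiter=_MAXITER, tol=_TOL
                )
            converged = bool(res.converged)
        else:
            res = sm.OLS(y, X).fit()
            ssr = float(res.ssr)
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        llf = float(res.llf)  # OLS llf already uses the MLE variance
    except (np.linalg.LinAlgError, ValueError):
        params = np.full(p, np.nan)
        bse = np.full(p, np.nan)
        cov = np.full((p, p), np.nan)
        llf = np.nan
        converged = False
    if converged and (
        not np.isfinite(params).all()
        or not np.isfinite(bse).all()
        or np.abs(params).max() > _MAX_ABS_COEF
        or bse.max() > _MAX_SE
    ):
        converged = False
    return FitResult(
        params=pd.Series(params, index=names),
        bse=pd.Series(bse, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        log_likelihood=llf, n_used=n, n_params=p + extra,
        converged=converged, family=family, ssr=ssr,
    )


def interaction_test(
    fit_full: FitResult, fit_reduced: FitResult, method: str = "lrt"
) -> tuple[float, int, float]:
    """Joint test of the interaction columns (full vs reduced model).

    Returns (statistic, df, p).  ``lrt``: 2*(llf_full - llf_reduced)
    against chi-square(df), clamped at zero; for the linear family an
    exact partial F-test replaces the chi-square.  ``wald``: joint Wald
    chi-square on the coefficients present only in the full model.
    """
    df = fit_full.n_params - fit_reduced.n_params
    if df <= 0:
        raise ValueError("reduced model must be strictly nested in the full model")
    if method == "lrt":
        if fit_full.family == "linear":
            # exact partial F on residual sums of squares
            p_full = fit_full.n_params - 1  # design columns (variance excluded)
            resid_df = fit_full.n_used - p_full
            fstat = ((fit_reduced.ssr - fit_full.ssr) / df) / (fit_full.ssr / resid_df)
            fstat = max(fstat, 0.0)
            return fstat, df, float(st.f.sf(fstat, df, resid_df))
        stat = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
        return stat, df, float(st.chi2.sf(stat, df))
    if method == "wald":
        extra = [t for t in fit_full.term_names if t not in fit_reduced.term_names]
        if len(extra) != df and fit_full.family == "linear":
            pass  # variance param cancels in the name difference for linear
        b = fit_full.params[extra].to_numpy()
        C = fit_full.cov.loc[extra, extra].to_numpy()
        stat = float(b @ np.linalg.solve(C, b))
        stat = max(stat, 0.0)
        k = len(extra)
        return stat, k, float(st.chi2.sf(stat, k))
    raise ValueError(f"method must be 'lrt' or 'wald', got {method!r}")


def bic(fit: FitResult) -> float | None:
    """Bayesian information criterion: -2*logLik + k*ln(n); None if unconverged."""
    if not fit.converged or not np.isfinite(fit.log_likelihood):
        return None
    return -2.0 * fit.log_likelihood + fit.n_params * np.log(fit.n_used)


def _complete_cases(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise KeyError(f"columns not found in data: {missing}")
    return data[cols].dropna().reset_index(drop=True)


def _reduced_design(design: pd.DataFrame) -> pd.DataFrame:
    """Drop the interaction columns; keep intercept, main effects, covariates."""
    return design[[c for c in design.columns if not c.startswith("SNP:")]]


def _per_term_table(fit: FitResult, family: str, ci_level: float) -> pd.DataFrame:
    z = st.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for name in fit.term_names:
        if name == "const":
            continue
        est = fit.params[name]
        se = fit.bse[name]
        lo, hi = est - z * se, est + z * se
        wald_p = 2.0 * st.norm.sf(abs(est) / se) if se > 0 else np.nan
        row = {"term": name, "estimate": est, "ci_low": lo, "ci_high": hi, "p": wald_p}
        if family == "logistic":
            row.update(OR=np.exp(est), OR_low=np.exp(lo), OR_high=np.exp(hi))
        rows.append(row)
    return pd.DataFrame(rows)


def _not_estimable(spec: PatternSpec, n: int, reason: str) -> PatternFit:
    return PatternFit(
        spec=spec, fit=None, p_interaction=None, per_term=None,
        bic=None, estimable=False, n_used=n, reason=reason,
    )


def fit_pattern(
    data: pd.DataFrame,
    spec: PatternSpec,
    snp: str,
    env: str,
    outcome: str,
    env_type: str = "ordinal",
    family: str = "logistic",
    covariates: list[str] | None = None,
    ci_level: float = 0.95,
    test: str = "lrt",
    _reduced_cache: dict | None = None,
) -> PatternFit:
    """Fit one pattern on a subject table and test its interaction terms.

    Complete cases are taken listwise across outcome, SNP, environment
    and covariates.  The reduced model for the interaction test keeps
    the intercept, the structure's main effects and the covariates.
    Designs with a constant or collinear column are flagged
    non-estimable rather than raising.
    """
    covariates = covariates or []
    cc = _complete_cases(data, [outcome, snp, env] + list(covariates))
    n = len(cc)
    try:
        snp_coded = code_snp(cc[snp], spec.mode, spec.snp_dir)
        dummies, ref = code_env(cc[env], spec.env_dir, env_type)
    except ValueError as exc:
        return _not_estimable(spec, n, str(exc))
    if n == 0 or np.nanstd(snp_coded) == 0:
        # monomorphic under this coding: interaction columns carry no SNP signal
        return _not_estimable(spec, n, "SNP is constant under this coding")
    cov_df = cc[list(covariates)].astype(float) if covariates else None
    design, _ = build_design(snp_coded, dummies, spec.structure, cov_df, ref)

    X = design.to_numpy(dtype=float)
    nonconst = X[:, 1:]
    if nonconst.size == 0 or (nonconst == nonconst[0]).all(axis=0).any():
        return _not_estimable(spec, n, "constant design column after complete-case filtering")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _not_estimable(spec, n, "rank-deficient design (collinear columns)")

    y = cc[outcome].to_numpy(dtype=float)
    fit_full = fit_glm(design, y, family)
    if not fit_full.converged:
        return _not_estimable(spec, n, "full-model fit did not converge (possible separation)")

    reduced = _reduced_design(design)
    key = None
    if _reduced_cache is not None:
        key = (spec.structure, tuple(reduced.columns),
               spec.mode if "SNP" in reduced.columns else None,
               spec.snp_dir if "SNP" in reduced.columns else None,
               spec.env_dir if any(c.startswith("ENV_") for c in reduced.columns) else None)
    if key is not None and key in _reduced_cache:
        fit_red = _reduced_cache[key]
    else:
        fit_red = fit_glm(reduced, y, family)
        if key is not None:
            _reduced_cache[key] = fit_red
    if not fit_red.converged:
        return _not_estimable(spec, n, "reduced-model fit did not converge")

    _, _, p_int = interaction_test(fit_full, fit_red, method=test)
    return PatternFit(
        spec=spec,
        fit=fit_full,
        p_interaction=p_int,
        per_term=_per_term_table(fit_full, family, ci_level),
        bic=bic(fit_full),
        estimable=True,
        n_used=n,
    )
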