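"""Covariate-adjusted regressions and percentile-bootstrap mediation.

The mediation model is brain -> thought -> well-being: the predictor x is
the natural log of a component's fractional strength, the mediator m a
thought-pattern score, and the outcome y a well-being domain score.  Paths
are estimated by OLS on standardized variables (binary covariates are left
as indicators), all on the same complete-case sample so that the
decomposition c = c' + a*b holds exactly:

    a  from  m ~ x + covariates
    b, c' from  y ~ x + m + covariates
    c  from  y ~ x + covariates

The indirect effect a*b is tested by resampling subjects with replacement
and taking the 2.5/97.5 percentiles of the bootstrap distribution — the
percentile bootstrap, recommended for small-to-medium samples over the
normal-theory (Sobel) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

CONDITION_LIMIT = 1e8


@dataclass
class RegressionResult:
    """Standardized OLS summary (betas, t, p) for one outcome."""

    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    n_used: int
    n_dropped: int


@dataclass
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    se_indirect: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_used: int
    n_dropped: int
    covariates: tuple

    @property
    def significant(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)


def _is_binary(v: np.ndarray) -> bool:
    return np.unique(v[~np.isnan(v)]).size <= 2


def _standardize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """z-score continuous columns; leave binary indicators untouched."""
    out = df.copy().astype(float)
    for c in out.columns:
        v = out[c].to_numpy()
        if not _is_binary(v):
            sd = v.std()
            if sd == 0:
                raise ValueError(f"column {c!r} has zero variance")
            out[c] = (v - v.mean()) / sd
    return out


def fit_linear(outcome, predictors: pd.DataFrame,
               standardize: bool = True) -> RegressionResult:
    """OLS of an outcome on a predictor table, complete cases only."""
    y = pd.Series(np.asarray(outcome, dtype=float), index=predictors.index,
                  name="outcome")
    data = pd.concat([y, predictors.astype(float)], axis=1)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("fit_linear: dropped %d incomplete cases", n_dropped)
    if len(complete) <= predictors.shape[1] + 1:
        raise ValueError("not enough complete cases for the model")
    X = complete[predictors.columns]
    yv = complete["outcome"].to_numpy()
    if standardize:
        X = _standardize_frame(X)
        yv = (yv - yv.mean()) / yv.std()
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.cond(Xc.to_numpy()) > CONDITION_LIMIT:
        raise ValueError("predictors are (near-)collinear; condition number "
                         f"exceeds {CONDITION_LIMIT:g}")
    fit = sm.OLS(yv, Xc).fit()
    return RegressionResult(params=fit.params.drop("const"),
                            tvalues=fit.tvalues.drop("const"),
                            pvalues=fit.pvalues.drop("const"),
                            df_resid=int(fit.df_resid), n_used=len(complete),
                            n_dropped=n_dropped)


def _ols_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def _batched_coef(Xb: np.ndarray, yb: np.ndarray) -> np.ndarray:
    """OLS coefficients for a batch of resampled designs (B, n, p)."""
    XtX = np.einsum("bnp,bnq->bpq", Xb, Xb)
    Xty = np.einsum("bnp,bn->bp", Xb, yb)
    return np.linalg.solve(XtX, Xty[..., None])[..., 0]


def mediate(x, m, y, covariates: pd.DataFrame | None = None,
            n_boot: int = 5000, seed: int = 0) -> MediationResult:
    """Percentile-bootstrap mediation of x -> m -> y with covariates.

    All variables are standardized once on the analysis (complete-case)
    sample; resampling happens on the standardized rows, so the reported
    paths are standardized coefficients.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (x.shape == m.shape == y.shape) or x.ndim != 1:
        raise ValueError("x, m, y must be 1-D arrays of equal length")
    cov_names: tuple = ()
    if covariates is not None:
        if len(covariates) != x.size:
            raise ValueError("covariates misaligned with x/m/y")
        cov_names = tuple(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.empty((x.size, 0))

    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y) \
        & np.isfinite(C).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("mediate: dropped %d incomplete cases", n_dropped)
    x, m, y, C = x[keep], m[keep], y[keep], C[keep]
    n = x.size
    if n <= C.shape[1] + 3:
        raise ValueError("not enough complete cases for mediation")

    def z(v):
        return (v - v.mean()) / v.std()

    x, m, y = z(x), z(m), z(y)
    Cz = np.column_stack([
        C[:, j] if _is_binary(C[:, j]) else z(C[:, j])
        for j in range(C.shape[1])]) if C.shape[1] else C

    ones = np.ones((n, 1))
    Xa = np.column_stack([ones, x, Cz])          # m ~ x + C
    Xb = np.column_stack([ones, x, m, Cz])       # y ~ x + m + C
    Xc = Xa                                      # y ~ x + C
    for name, X in (("a-path", Xa), ("b-path", Xb)):
        if np.linalg.cond(X) > CONDITION_LIMIT:
            raise ValueError(f"collinear design in {name} model")

    a = _ols_coef(Xa, m)[1]
    bc = _ols_coef(Xb, y)
    c_prime, b = bc[1], bc[2]
    c = _ols_coef(Xc, y)[1]

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    chunk = max(1, min(n_boot, int(2e6 / max(n, 1))))
    done = 0
    while done < n_boot:
        B = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(B, n))
        a_b = _batched_coef(Xa[idx], m[idx])[:, 1]
        b_b = _batched_coef(Xb[idx], y[idx])[:, 2]
        boots[done:done + B] = a_b * b_b
        done += B

    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return MediationResult(
        a=float(a), b=float(b), c=float(c), c_prime=float(c_prime),
        indirect=float(a * b), se_indirect=float(boots.std(ddof=1)),
        ci_low=float(ci_low), ci_high=float(ci_high), n_boot=n_boot,
        seed=seed, n_used=n, n_dropped=n_dropped, covariates=cov_names)


def bonferroni_domains(p_values, k: int = 2):
    """Bonferroni adjustment across well-being domains: min(1, k*p)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, k * p)
    return float(out) if out.ndim == 0 else out
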