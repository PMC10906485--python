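"""Generalized least squares under a phylogenetic covariance.

The workhorse is :func:`fit_gls`, ordinary GLS with error covariance
``sigma^2 * C`` where ``C`` is the Brownian (optionally lambda-scaled)
phylogenetic covariance.  Estimation is by whitening: with ``C = L L'``
(Cholesky), premultiplying the design and response by ``L^{-1}`` reduces
the problem to OLS, giving

    beta  = (X' C^{-1} X)^{-1} X' C^{-1} y
    s2    = (y - X beta)' C^{-1} (y - X beta) / (n - p)

The reported log-likelihood is the *maximized* Gaussian likelihood (ML
variance scale, RSS/n), so AIC values are comparable across fixed-effect
structures; AIC = -2 lnL + 2k with k = p + 1 (coefficients plus the
variance).  R^2 is 1 - RSS_C / TSS_C with both quadratic forms taken in
the C metric and TSS_C from the GLS intercept-only fit under the same C
— the natural GLS generalization of the OLS coefficient of
determination (in [0, 1] for intercept models).

Pagel's lambda is estimated by profiling that likelihood over the
lambda-transformed covariance on [0, 1]; significance against lambda = 0
comes from a likelihood-ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .phylo import PhyloCovariance

__all__ = [
    "GlsFit",
    "LambdaResult",
    "AncovaResult",
    "FitError",
    "fit_gls",
    "cooks_distance",
    "pagels_lambda",
    "ancova_interaction",
    "residual_cascade",
    "treatment_design",
]


class FitError(ValueError):
    """Singular covariance, rank-deficient design, or misaligned data."""


# ---------------------------------------------------------------------------
# linear algebra helpers
# ---------------------------------------------------------------------------


def _as_cov_matrix(C, n: int) -> np.ndarray:
    """Accept a PhyloCovariance, a dense matrix, or None (identity)."""
    if C is None:
        return np.eye(n)
    if isinstance(C, PhyloCovariance):
        M = C.matrix
    else:
        M = np.asarray(C, dtype=float)
    if M.shape != (n, n):
        raise FitError(
            f"covariance is {M.shape} but data have {n} observations "
            "(taxon-order mismatch?)"
        )
    return M


def _chol_lower(C: np.ndarray) -> np.ndarray:
    """Cholesky factor of C; eigenvalue-clipped fallback for near-singular C."""
    try:
        return linalg.cholesky(C, lower=True)
    except linalg.LinAlgError:
        w, V = linalg.eigh(C)
        if w.max() <= 0:
            raise FitError("covariance matrix is not positive semi-definite")
        w_clipped = np.clip(w, 1e-10 * w.max(), None)
        C_fixed = (V * w_clipped) @ V.T
        return linalg.cholesky(C_fixed, lower=True)


def _whiten(L: np.ndarray, A: np.ndarray) -> np.ndarray:
    return linalg.solve_triangular(L, A, lower=True)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------


@dataclass
class GlsFit:
    """One fitted (phylogenetic) GLS model."""

    beta: np.ndarray
    se: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    df_residual: int
    sigma2: float
    loglik: float
    aic: float
    r_squared: float
    residuals: np.ndarray
    fitted: np.ndarray
    cooks_d: np.ndarray
    n_obs: int
    predictor_names: list[str]
    # retained so diagnostics can be recomputed without re-passing data
    _whitened: tuple = field(default=None, repr=False)

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "t": self.t_stats,
                "p": self.p_values,
            },
            index=self.predictor_names,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": {
                name: {
                    "coef": float(b),
                    "se": float(s),
                    "t": float(t),
                    "p": float(p),
                }
                for name, b, s, t, p in zip(
                    self.predictor_names, self.beta, self.se, self.t_stats, self.p_values
                )
            },
            "n_obs": int(self.n_obs),
            "df_residual": int(self.df_residual),
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "r_squared": float(self.r_squared),
        }


@dataclass
class LambdaResult:
    """Maximum-likelihood Pagel's lambda with likelihood-ratio test vs 0."""

    lambda_hat: float
    loglik_hat: float
    loglik_zero: float
    lrt_stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "lambda_hat": float(self.lambda_hat),
            "loglik_hat": float(self.loglik_hat),
            "loglik_zero": float(self.loglik_zero),
            "lrt_stat": float(self.lrt_stat),
            "p_value": float(self.p_value),
        }


@dataclass
class AncovaResult:
    """Phylogenetic ANCOVA: full fit plus the interaction test."""

    fit: GlsFit
    p_interaction: float
    interaction_test: str  # "t" (2-level factor) or "lrt" (>2 levels)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_gls(design, response, C=None, names: list[str] | None = None) -> GlsFit:
    """Fit GLS with error covariance sigma^2 * C.

    Parameters
    ----------
    design
        n x p design matrix; include the intercept column explicitly.
    response
        length-n response vector, row-aligned with ``design`` and with the
        taxa of ``C``.
    C
        PhyloCovariance or dense n x n matrix; None means identity (OLS).
    names
        Optional predictor names (length p).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float).ravel()
    n = y.shape[0]
    if X.shape[0] != n:
        raise FitError("design and response have different numbers of rows")
    p = X.shape[1]
    if p >= n:
        raise FitError(f"need p < n, got p={p}, n={n}")
    M = _as_cov_matrix(C, n)
    L = _chol_lower(M)
    Xw = _whiten(L, X)
    yw = _whiten(L, y)

    if np.linalg.matrix_rank(Xw) < p:
        raise FitError("design matrix is rank-deficient")

    XtX = Xw.T @ Xw
    XtX_inv = linalg.inv(XtX)
    beta = XtX_inv @ (Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    df_resid = n - p
    if df_resid < 1:
        raise FitError("no residual degrees of freedom")
    sigma2 = rss / df_resid
    se = np.sqrt(np.clip(np.diag(XtX_inv), 0, None) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stats = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p_values = 2.0 * stats.t.sf(np.abs(t_stats), df_resid)

    # maximized (ML-scale) Gaussian log-likelihood with covariance s2_ml * C
    sigma2_ml = rss / n
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml <= 0:
        # perfect fit: likelihood unbounded; report +inf consistently
        loglik = np.inf
    else:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_C + n)
    k = p + 1
    aic = -2.0 * loglik + 2.0 * k

    # C-metric R^2 against the GLS intercept-only fit under the same C
    ones_w = _whiten(L, np.ones(n))
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    r_squared = 1.0 - rss / tss if tss > 0 else np.nan

    fitted = X @ beta
    residuals = y - fitted

    # Cook's distance on the whitened model
    H_diag = np.einsum("ij,jk,ik->i", Xw, XtX_inv, Xw)
    with np.errstate(divide="ignore", invalid="ignore"):
        cooks = (resid_w**2 * H_diag) / (p * sigma2 * (1.0 - H_diag) ** 2)
    cooks = np.where(np.isfinite(cooks), cooks, np.inf)

    if names is None:
        names = [f"x{j}" for j in range(p)]
    return GlsFit(
        beta=beta,
        se=se,
        t_stats=t_stats,
        p_values=p_values,
        df_residual=df_resid,
        sigma2=sigma2,
        loglik=float(loglik),
        aic=float(aic),
        r_squared=float(r_squared),
        residuals=residuals,
        fitted=fitted,
        cooks_d=cooks,
        n_obs=n,
        predictor_names=list(names),
        _whitened=(Xw, yw),
    )


def cooks_distance(fit: GlsFit, design, response, C=None) -> np.ndarray:
    """Cook's distance D_i for each observation, in taxon order.

    Computed on the whitened model: premultiply X and y by the inverse
    Cholesky factor of C, then apply the standard OLS influence formula
    D_i = r_i^2 h_ii / (p * s2 * (1 - h_ii)^2).
    """
    X = np.atleast_2d(np.asarray(design, dtype=float))
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if n - p < 2:
        raise FitError("Cook's distance needs n - p >= 2")
    refit = fit_gls(X, y, C, names=fit.predictor_names if fit else None)
    return refit.cooks_d


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _intercept_loglik(y: np.ndarray, M: np.ndarray) -> float:
    """Maximized intercept-only Gaussian log-likelihood under covariance s2*M."""
    n = y.shape[0]
    L = _chol_lower(M)
    yw = _whiten(L, y)
    ones_w = _whiten(L, np.ones(n))
    mu = float(ones_w @ yw) / float(ones_w @ ones_w)
    rss = float((yw - mu * ones_w) @ (yw - mu * ones_w))
    if rss <= 0:
        return np.inf
    sigma2_ml = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)


def pagels_lambda(
    response, C: PhyloCovariance, boundary_mixture: bool = False
) -> LambdaResult:
    """ML estimate of Pagel's lambda for a single trait, with LRT vs 0.

    lambda scales the off-diagonal of the Brownian covariance: 0 means no
    covariance between trait and phylogenetic structure, 1 full Brownian
    covariance.  The estimate maximizes the intercept-only ML likelihood
    over lambda in [0, 1] (bounded scalar optimization, tol 1e-8).

    The default p-value uses the plain chi-square(1) upper tail, which is
    conservative at the lambda = 0 boundary; ``boundary_mixture=True``
    uses the 50:50 point-mass/chi-square(1) mixture instead.
    """
    y = np.asarray(response, dtype=float).ravel()
    n = y.shape[0]
    if n < 4:
        raise FitError("Pagel's lambda needs n >= 4")
    if np.ptp(y) == 0 or np.var(y) == 0:
        raise FitError("constant response: lambda undefined")
    if not isinstance(C, PhyloCovariance):
        C = PhyloCovariance(taxa=[f"t{i}" for i in range(n)], matrix=np.asarray(C))
    if C.n != n:
        raise FitError("response length does not match covariance")
    if C.is_star():
        raise FitError("lambda unidentifiable: star-tree covariance (all off-diagonals 0)")

    def neg_ll(lam: float) -> float:
        return -_intercept_loglik(y, C.lambda_transform(lam).matrix)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    candidates = [(res.x, -res.fun), (0.0, -neg_ll(0.0)), (1.0, -neg_ll(1.0))]
    lambda_hat, loglik_hat = max(candidates, key=lambda t: t[1])
    loglik_zero = -neg_ll(0.0)
    lrt = max(2.0 * (loglik_hat - loglik_zero), 0.0)
    if boundary_mixture:
        p_value = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))
    else:
        p_value = float(stats.chi2.sf(lrt, df=1))
    return LambdaResult(
        lambda_hat=float(lambda_hat),
        loglik_hat=float(loglik_hat),
        loglik_zero=float(loglik_zero),
        lrt_stat=float(lrt),
        p_value=float(p_value),
    )


# ---------------------------------------------------------------------------
# design helpers and ANCOVA
# ---------------------------------------------------------------------------


def treatment_design(factor) -> tuple[np.ndarray, list[str], list[str]]:
    """Treatment-coded dummy block for a categorical predictor.

    Reference level is the first alphabetically; returns (dummies, dummy
    column names, sorted levels).
    """
    f = pd.Series(factor).astype(str)
    levels = sorted(f.unique())
    cols = []
    names = []
    for lev in levels[1:]:
        cols.append((f == lev).to_numpy(dtype=float))
        names.append(f"[{lev}]")
    D = np.column_stack(cols) if cols else np.empty((len(f), 0))
    return D, names, levels


def ancova_interaction(response, continuous_pred, factor_pred, C=None) -> AncovaResult:
    """Phylogenetic ANCOVA: response ~ continuous * factor under C.

    Treatment coding with the alphabetically first level as reference.
    The interaction p-value is the t-test on the interaction coefficient
    for a 2-level factor, or a likelihood-ratio test against the
    no-interaction model for >2 levels.
    """
    y = np.asarray(response, dtype=float).ravel()
    x = np.asarray(continuous_pred, dtype=float).ravel()
    f = pd.Series(factor_pred).astype(str)
    counts = f.value_counts()
    if (counts < 2).any():
        bad = sorted(counts[counts < 2].index)
        raise FitError(f"factor level(s) with < 2 observations: {bad}")
    if counts.size < 2:
        raise FitError("factor must have >= 2 levels")

    D, dnames, levels = treatment_design(f)
    inter = D * x[:, None]
    X_full = np.column_stack([np.ones_like(x), x, D, inter])
    names = (
        ["(Intercept)", "x"]
        + [f"factor{nm}" for nm in dnames]
        + [f"x:factor{nm}" for nm in dnames]
    )
    fit_full = fit_gls(X_full, y, C, names=names)

    n_inter = D.shape[1]
    if len(levels) == 2:
        p_int = float(fit_full.p_values[-1])
        test = "t"
    else:
        X_red = np.column_stack([np.ones_like(x), x, D])
        fit_red = fit_gls(X_red, y, C)
        lrt = max(2.0 * (fit_full.loglik - fit_red.loglik), 0.0)
        p_int = float(stats.chi2.sf(lrt, df=n_inter))
        test = "lrt"
    return AncovaResult(fit=fit_full, p_interaction=p_int, interaction_test=test)


# ---------------------------------------------------------------------------
# residual cascade: relative eye size and residual acuity
# ---------------------------------------------------------------------------


def residual_cascade(acuity, eye_size, body_mass, C=None):
    """Two-stage PGLS residual construction.

    Stage 1 regresses log eye size on log body mass under C; the
    residuals are *relative eye size* (positive = larger eyes than the
    allometric expectation for that body mass).  Stage 2 regresses log
    acuity on relative eye size under C; those residuals are *residual
    acuity* — acuity beyond what eye investment predicts.

    Returns ``(relative_eye_size, residual_acuity, (stage1_fit, stage2_fit))``.
    """
    a = np.asarray(acuity, dtype=float).ravel()
    e = np.asarray(eye_size, dtype=float).ravel()
    m = np.asarray(body_mass, dtype=float).ravel()
    if not (len(a) == len(e) == len(m)):
        raise FitError("acuity, eye size and body mass must have equal length")
    n = len(a)
    X1 = np.column_stack([np.ones(n), m])
    fit1 = fit_gls(X1, e, C, names=["(Intercept)", "log_body_mass"])
    rel_eye = fit1.residuals
    X2 = np.column_stack([np.ones(n), rel_eye])
    fit2 = fit_gls(X2, a, C, names=["(Intercept)", "relative_eye_size"])
    resid_acuity = fit2.residuals
    return rel_eye, resid_acuity, (fit1, fit2)
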