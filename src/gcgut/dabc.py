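"""Bias-corrected compositional differential abundance.

Observed counts are modelled on the log scale as

    y_ij = ln(count_ij + pseudo) = d_i + alpha_j + x_i' beta_j + eps_ij

where ``d_i`` is a sample-specific log sampling fraction — the nuisance that
links true absolute abundances to sequencing counts — and ``beta_j`` are
per-feature log-fold coefficients of the design covariates. Because ``d`` and
the coefficient field are confounded (adding ``X c`` to ``d`` and subtracting
``c`` from every feature's coefficients leaves the fit unchanged), a naive
per-feature regression is biased by the between-sample differences in
sampling fraction. The engine removes that bias in two steps:

1. alternating least squares — given ``d``, fit every feature by OLS on the
   offset-corrected logs; given the coefficients, update ``d_i`` as the mean
   over features of the residual ``y_ij - alpha_j - x_i' beta_j`` — iterated
   to convergence; then
2. coefficient centering — for each non-intercept predictor, the cross-feature
   mode of the coefficients is estimated by a trimmed mean and subtracted,
   under the premise that most features are not differentially abundant.

Wald tests use per-feature heteroscedasticity-robust (HC3 sandwich) standard
errors with normal tails — the log-scale noise mixes a homoscedastic
overdispersion component with count noise whose variance grows as mean
abundance shrinks, so classical OLS errors understate uncertainty exactly
where conditional effects are extreme. Benjamini-Hochberg correction is
applied within each predictor across features. ``d`` is identified only up
to an additive constant and is reported centered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .profiles import CountTable

logger = logging.getLogger(__name__)


class DabcError(ValueError):
    pass


@dataclass
class DabcFit:
    """Per-feature coefficients and tests from the bias-corrected model.

    All coefficient frames are feature x predictor; ``log_sampling_fraction``
    is per sample, centered to mean zero.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    W: pd.DataFrame
    p: pd.DataFrame
    p_bh: pd.DataFrame
    significant: pd.DataFrame
    log_sampling_fraction: pd.Series
    n_iter: int
    converged: bool
    dropped_features: list = field(default_factory=list)

    @property
    def predictors(self) -> list:
        return list(self.beta.columns)

    @property
    def features(self) -> list:
        return list(self.beta.index)

    def to_tsv(self, path, alpha: float = 0.05) -> None:
        rows = []
        for feat in self.beta.index:
            for pred in self.beta.columns:
                rows.append({
                    "feature": feat, "predictor": pred,
                    "beta": self.beta.at[feat, pred],
                    "se": self.se.at[feat, pred],
                    "W": self.W.at[feat, pred],
                    "p": self.p.at[feat, pred],
                    "p_bh": self.p_bh.at[feat, pred],
                    "significant": bool(self.significant.at[feat, pred]),
                })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DabcError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def expected_log1p_poisson(lam, pseudo: float = 1.0,
                           k_max: int = 300) -> np.ndarray:
    """E[ln(N+pseudo)] for N ~ Poisson(lam), vectorized.

    Exact truncated series below lam = 40; second-order delta-method
    asymptote above. Used to remove the floor bias of the log(count+pseudo)
    response at cells whose expected count is small.
    """
    lam = np.maximum(np.asarray(lam, dtype=float), 1e-12)
    out = np.log(lam + pseudo) - lam / (2.0 * (lam + pseudo) ** 2)
    small = lam < 40.0
    ls = lam[small]
    if ls.size:
        k = np.arange(k_max)[:, None]
        log_pmf = k * np.log(ls[None, :]) - ls[None, :] - gammaln(k + 1)
        out[small] = (np.exp(log_pmf) * np.log(k + pseudo)).sum(axis=0)
    return out


def _masked_refit(X, Yc, counts, lam, pred_names, trim):
    """Per-feature OLS excluding zero-count cells with fitted mean < 1,
    with HC3 sandwich errors computed on each feature's retained cells.

    Falls back to the full cell set for a feature when exclusion would leave
    too few rows or a degenerate design.
    """
    n, p = X.shape
    n_feat = Yc.shape[1]
    B = np.empty((p, n_feat))
    se = np.empty((p, n_feat))
    drop = (counts == 0) & (lam < 1.0)
    for j in range(n_feat):
        m = ~drop[:, j]
        if m.sum() < p + 2:
            m = np.ones(n, dtype=bool)
        Xj, yj = X[m], Yc[m, j]
        try:
            XtX_inv = np.linalg.inv(Xj.T @ Xj)
        except np.linalg.LinAlgError:
            Xj, yj = X, Yc[:, j]
            XtX_inv = np.linalg.inv(X.T @ X)
        bj = XtX_inv @ (Xj.T @ yj)
        rj = yj - Xj @ bj
        h = np.einsum("ij,ji->i", Xj @ XtX_inv, Xj.T)
        w = (rj / np.maximum(1e-8, 1.0 - h)) ** 2
        Hj = XtX_inv @ Xj.T
        se[:, j] = np.sqrt((Hj ** 2) @ w)
        B[:, j] = bj
    for k, name in enumerate(pred_names):
        if name == "Intercept":
            continue
        B[k] -= stats.trim_mean(B[k], trim)
    return B, se


def fit_dabc(
    table: CountTable | pd.DataFrame,
    design: pd.DataFrame,
    pseudo: float = 1.0,
    sampling_fraction: pd.Series | np.ndarray | None = None,
    trim: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 100,
    alpha: float = 0.05,
    se_method: str = "hc3",
    curvature_correction: bool = True,
    n_curvature_iter: int = 3,
) -> DabcFit:
    """Fit the bias-corrected log-linear model to a count table.

    ``design`` must contain an ``Intercept`` column; all-zero features are
    dropped (logged). Passing ``sampling_fraction`` fixes ``d`` at known
    values (no alternating estimation), in which case (with
    ``curvature_correction=False``) the per-feature estimates are exactly
    OLS on the offset-corrected logs.

    ``curvature_correction`` additionally removes the floor bias of the
    log(count+1) response: at cells whose model-implied mean count is small,
    E[ln(N+1)] sits far above ln(mean), which attenuates large coefficients;
    the expected offset is computed at the fitted means and subtracted,
    iterating ``n_curvature_iter`` times.
    """
    counts = table.counts if isinstance(table, CountTable) else table
    counts = counts.astype(float)
    if "Intercept" not in design.columns:
        raise DabcError("design must include an Intercept column")
    if not counts.index.equals(design.index):
        if set(counts.index) != set(design.index):
            raise DabcError("count table and design cover different samples")
        design = design.loc[counts.index]
    n, _ = counts.shape
    if n <= design.shape[1]:
        raise DabcError("need more samples than design columns")

    X = design.values.astype(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DabcError("rank-deficient design matrix")

    zero = counts.columns[(counts == 0).all(axis=0)]
    if len(zero):
        logger.info("dropping %d all-zero features", len(zero))
        counts = counts.drop(columns=zero)
    feats = list(counts.columns)
    Y0 = np.log(counts.values + pseudo)
    pred_names = list(design.columns)

    XtX_inv = np.linalg.inv(X.T @ X)
    H = XtX_inv @ X.T  # p_design x n

    fixed_d = sampling_fraction is not None
    if fixed_d:
        d_fixed = np.asarray(
            sampling_fraction.loc[counts.index]
            if isinstance(sampling_fraction, pd.Series) else sampling_fraction,
            dtype=float,
        )
        d_fixed = d_fixed - d_fixed.mean()

    def solve(Y):
        """Alternating estimation of (d, B) with trimmed-mean centering."""
        if fixed_d:
            d = d_fixed.copy()
            B = H @ (Y - d[:, None])
            n_it, conv = 0, True
        else:
            d = np.zeros(n)
            conv = False
            for n_it in range(1, max_iter + 1):
                B = H @ (Y - d[:, None])          # p_design x p_features
                resid = Y - X @ B                 # still contains d
                d_new = resid.mean(axis=1)
                d_new -= d_new.mean()
                delta = np.abs(d_new - d).max()
                d = d_new
                if delta < tol:
                    conv = True
                    break
            if not conv:
                raise DabcError(
                    f"sampling-fraction estimation did not converge in "
                    f"{max_iter} iterations (last max step {delta:.3g})"
                )
            B = H @ (Y - d[:, None])
        # centre each non-intercept predictor's coefficient field on its
        # trimmed-mean mode; fold the shift back into d
        shift = np.zeros(len(pred_names))
        for k, name in enumerate(pred_names):
            if name == "Intercept":
                continue
            shift[k] = stats.trim_mean(B[k], trim)
            B[k] -= shift[k]
        d = d + X @ shift
        d -= d.mean()
        return B, d, n_it, conv

    Y = Y0
    B, d, n_iter, converged = solve(Y)
    if curvature_correction:
        for _ in range(n_curvature_iter):
            lam = np.exp(d[:, None] + X @ B)
            Y = Y0 - (expected_log1p_poisson(lam, pseudo) - np.log(lam))
            B, d, n_iter, converged = solve(Y)
        # final per-feature refit excluding uninformative floor cells: a zero
        # count where the fitted mean is already below one carries almost no
        # information and only drags large coefficients toward zero
        B, se = _masked_refit(X, Y - d[:, None], counts.values,
                              np.exp(d[:, None] + X @ B), pred_names, trim)
    else:
        # per-feature standard errors, d treated as an offset
        resid = (Y - d[:, None]) - X @ B
        if se_method == "hc3":
            leverage = np.einsum("ij,ji->i", X @ XtX_inv, X.T)
            w = (resid / (1.0 - leverage)[:, None]) ** 2  # n x p_features
            se = np.sqrt((H ** 2) @ w)                    # p_design x p_feat
        elif se_method == "ols":
            dof = n - X.shape[1]
            sigma2 = (resid ** 2).sum(axis=0) / dof
            se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
        else:
            raise DabcError(f"unknown se_method {se_method!r}")

    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(se > 0, B / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(W))

    def frame(a):
        return pd.DataFrame(a.T, index=feats, columns=pred_names)

    p_bh = np.empty_like(p)
    for k in range(p.shape[0]):
        p_bh[k] = bh_adjust(p[k])

    return DabcFit(
        beta=frame(B), se=frame(se), W=frame(W), p=frame(p),
        p_bh=frame(p_bh), significant=frame(p_bh < alpha),
        log_sampling_fraction=pd.Series(d, index=counts.index,
                                        name="log_sampling_fraction"),
        n_iter=n_iter, converged=converged, dropped_features=list(zero),
    )


def significant_features(fit: DabcFit, predictor: str) -> tuple[list, float]:
    """Features whose BH-adjusted p-value falls below the significance level
    for ``predictor``, with the percentage of analyzed features (one decimal).
    """
    if predictor not in fit.significant.columns:
        raise DabcError(f"unknown predictor {predictor!r}")
    mask = fit.significant[predictor]
    sig = list(mask.index[mask])
    return sig, percent_of_total(len(sig), len(mask))


def percent_of_total(n_significant: int, n_total: int) -> float:
    """Share of analyzed features, as a percentage rounded to one decimal."""
    if n_total <= 0:
        raise DabcError("n_total must be positive")
    return round(100.0 * n_significant / n_total, 1)
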