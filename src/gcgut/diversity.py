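"""Alpha diversity indices and random-intercept mixed models.

Five within-sample diversity measures are computed per sample: observed
features, the abundance-based coverage estimator (ACE, rare threshold 10),
Shannon entropy in nats, inverse Simpson, and Faith's phylogenetic diversity
(total branch length of the minimal subtree spanning the root and the
observed leaves). Index-on-covariate analyses use Gaussian linear mixed
models with a subject random intercept, fitted by maximum likelihood so that
full/null likelihood-ratio comparisons are valid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode
from skbio.diversity.alpha import (
    ace as _ace,
    chao1 as _chao1,
    faith_pd as _faith_pd,
)
import statsmodels.api as sm

from .profiles import CountTable

DIVERSITY_INDICES = ("observed", "ace", "shannon", "inv_simpson", "faith_pd")


class DiversityError(ValueError):
    pass


def _sample_indices(counts: np.ndarray) -> dict:
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise DiversityError("empty sample")
    pos = counts[counts > 0].astype(float)
    p = pos / pos.sum()
    obs = int(len(pos))
    if (pos > 10).all():
        ace_val = float(obs)  # no rare class, no correction to apply
    else:
        try:
            ace_val = float(_ace(pos.astype(int), rare_threshold=10))
        except ValueError:
            # rare class is all singletons: the ACE coverage estimate is
            # undefined; fall back to bias-corrected Chao1 richness
            ace_val = float(_chao1(pos.astype(int), bias_corrected=True))
    return {
        "observed": obs,
        "ace": ace_val,
        "shannon": float(-(p * np.log(p)).sum()),
        "inv_simpson": float(1.0 / (p ** 2).sum()),
    }


def diversity_indices(table: CountTable | pd.DataFrame,
                      tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample diversity records; Faith's PD only when a rooted tree with
    branch lengths is supplied (its leaf set must cover the observed features).
    """
    counts = table.counts if isinstance(table, CountTable) else table
    feats = np.asarray(counts.columns, dtype=object)
    rows = {}
    for sample in counts.index:
        vec = counts.loc[sample].values.astype(int)
        rec = _sample_indices(vec)
        if tree is not None:
            rec["faith_pd"] = float(_faith_pd(vec, feats, tree))
        rows[sample] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class MixedModelFit:
    """Random-intercept LMM summary (Wald z tests, +/- 1.96 SE intervals)."""

    coefficients: pd.DataFrame     # estimate, se, ci_low, ci_high, z, p
    loglik: float
    n_obs: int
    n_subjects: int
    n_fixed: int
    r2_conditional: float
    var_random: float
    var_residual: float
    converged: bool
    columns: tuple

    def to_tsv(self, path):
        self.coefficients.to_csv(path, sep="\t", index_label="predictor")


def fit_lmm(response, design: pd.DataFrame, groups) -> MixedModelFit:
    """Gaussian LMM with a subject random intercept, fitted by ML.

    ``design`` should include an Intercept column. Non-convergence is flagged
    on the result (mirroring the fallback of dropping random slopes; random
    slopes are not fitted here by default).
    """
    y = np.asarray(response, dtype=float)
    X = design.values.astype(float)
    groups = np.asarray(groups)
    if len(y) <= X.shape[1]:
        raise DiversityError("need more observations than fixed parameters")
    if len(np.unique(groups)) < 2:
        raise DiversityError("need at least two subjects")
    res = None
    last_err = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        # lbfgs is fast but its Hessian turns singular when the random
        # intercept variance hits the zero boundary; fall back to
        # derivative-free optimizers there
        for method in ("lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
                break
            except np.linalg.LinAlgError as err:
                last_err = err
    if res is None:
        raise DiversityError(f"mixed model failed to fit: {last_err}")
    est = res.fe_params
    se = res.bse_fe
    z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
        "z": z, "p": p,
    }, index=design.columns)
    var_r = float(np.asarray(res.cov_re).ravel()[0])
    var_e = float(res.scale)
    var_f = float(np.var(X @ est))
    total = var_f + var_r + var_e
    return MixedModelFit(
        coefficients=coef, loglik=float(res.llf), n_obs=len(y),
        n_subjects=int(len(np.unique(groups))), n_fixed=X.shape[1],
        r2_conditional=(var_f + var_r) / total if total > 0 else np.nan,
        var_random=var_r, var_residual=var_e,
        converged=bool(res.converged), columns=tuple(design.columns),
    )


def full_null_lrt(full: MixedModelFit, null: MixedModelFit):
    """Likelihood-ratio comparison of nested ML fits.

    Returns (chi2, df, p) with df the difference in fixed-parameter counts.
    """
    if not set(null.columns).issubset(full.columns):
        raise DiversityError("null model is not nested in the full model")
    if null.n_obs != full.n_obs:
        raise DiversityError("models were fitted on different data")
    df = full.n_fixed - null.n_fixed
    if df < 0:
        raise DiversityError("null model has more parameters than the full model")
    chi2 = max(0.0, 2.0 * (full.loglik - null.loglik))
    if df == 0:
        return chi2, 0, 1.0  # identical models
    return chi2, df, float(stats.chi2.sf(chi2, df))


def reduce_model(response, design: pd.DataFrame, groups,
                 alpha: float = 0.05) -> tuple[MixedModelFit, pd.DataFrame]:
    """Drop all non-significant predictor-by-age interaction terms (p >=
    alpha) from a fitted full model, keep every main term, and refit.

    Returns (reduced fit, reduced design).
    """
    full = fit_lmm(response, design, groups)
    inter_cols = [c for c in design.columns if ":" in c]
    drop = [c for c in inter_cols if full.coefficients.at[c, "p"] >= alpha]
    reduced_design = design.drop(columns=drop)
    if not drop:
        return full, design
    return fit_lmm(response, reduced_design, groups), reduced_design
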