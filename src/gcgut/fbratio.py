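"""Firmicutes/Bacteroidota ratio and its linear models with drop1 LRTs.

The ratio of the two dominant phyla is a coarse indicator of the gut
community's energy-harvest configuration; it is modelled on the natural-log
scale with ordinary least squares on the standard predictor set plus
predictor-by-age interactions. Single-term deletion compares, for each
deletable term, the full fit against the refit without that term by a
likelihood-ratio test (df = 1); marginality is respected — a main effect
inside a retained interaction is never deleted on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger(__name__)


class FbError(ValueError):
    pass


def compute_fb(phylum_rel: pd.DataFrame,
               firmicutes: str = "Firmicutes",
               bacteroidota: str = "Bacteroidota") -> pd.DataFrame:
    """Per-row F/B ratio and log ratio from phylum relative abundances.

    Rows with zero Bacteroidota (or zero Firmicutes, whose log ratio would be
    infinite) are excluded with a warning; an all-zero pair raises.
    """
    for col in (firmicutes, bacteroidota):
        if col not in phylum_rel.columns:
            raise FbError(f"phylum column {col!r} missing")
    f = phylum_rel[firmicutes].astype(float)
    b = phylum_rel[bacteroidota].astype(float)
    if (f == 0).all() and (b == 0).all():
        raise FbError("both phyla are zero everywhere")
    ok = (f > 0) & (b > 0)
    if (~ok).any():
        logger.warning("excluding %d records with a zero phylum", int((~ok).sum()))
    out = pd.DataFrame({
        "firmicutes_rel": f[ok],
        "bacteroidota_rel": b[ok],
        "ratio": f[ok] / b[ok],
    })
    out["log_ratio"] = np.log(out["ratio"])
    return out


def _ols(y: np.ndarray, X: np.ndarray):
    res = sm.OLS(y, X).fit()
    return res


@dataclass
class FbModelFit:
    """OLS fit of the log F/B ratio with single-term-deletion LRTs."""

    coefficients: pd.DataFrame        # estimate, se, ci_low, ci_high
    lrt: pd.DataFrame                 # per deletable term: LRT, p
    loglik: float
    null_comparison: tuple            # (chi2, df, p) vs intercept-only
    pseudo_r2: float
    n_obs: int
    columns: tuple

    def to_tsv(self, path):
        out = self.coefficients.join(self.lrt, how="left")
        out.to_csv(path, sep="\t", index_label="predictor")


def _deletable_terms(columns) -> list:
    """Interaction terms always; main terms only when not inside a retained
    interaction; never the intercept."""
    inter = [c for c in columns if ":" in c]
    protected = set()
    for c in inter:
        protected.update(c.split(":"))
    out = list(inter)
    for c in columns:
        if c == "Intercept" or ":" in c:
            continue
        if c not in protected:
            out.append(c)
    return out


def fit_fb_model(records: pd.DataFrame, design: pd.DataFrame,
                 response: str = "log_ratio") -> FbModelFit:
    """OLS on the log ratio with drop1 likelihood-ratio tests.

    ``records`` and ``design`` are aligned on their index; the design must
    include an Intercept column.
    """
    common = records.index.intersection(design.index)
    if len(common) < len(design.columns) + 1:
        raise FbError("need more observations than parameters")
    y = records.loc[common, response].values.astype(float)
    X = design.loc[common]
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise FbError(f"rank-deficient design: columns {list(X.columns)}")
    full = _ols(y, X.values)
    est, se = full.params, full.bse
    coef = pd.DataFrame({
        "estimate": est, "se": se,
        "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se,
    }, index=X.columns)

    lrt_rows = {}
    for term in _deletable_terms(X.columns):
        reduced = _ols(y, X.drop(columns=term).values)
        chi2 = max(0.0, 2.0 * (full.llf - reduced.llf))
        lrt_rows[term] = {"LRT": chi2, "p": float(stats.chi2.sf(chi2, 1))}
    lrt = pd.DataFrame.from_dict(lrt_rows, orient="index")

    null = _ols(y, np.ones((len(y), 1)))
    df_null = X.shape[1] - 1
    chi2_null = max(0.0, 2.0 * (full.llf - null.llf))
    fitted = X.values @ est
    r = np.corrcoef(fitted, y)[0, 1] if np.std(fitted) > 0 else 0.0

    return FbModelFit(
        coefficients=coef, lrt=lrt, loglik=float(full.llf),
        null_comparison=(chi2_null, df_null, float(stats.chi2.sf(chi2_null, df_null))),
        pseudo_r2=float(r ** 2), n_obs=len(y), columns=tuple(X.columns),
    )


def reduce_fb_model(records: pd.DataFrame, design: pd.DataFrame,
                    alpha: float = 0.05,
                    response: str = "log_ratio") -> tuple[FbModelFit, pd.DataFrame]:
    """Sequentially drop non-significant interactions (largest drop1 p first),
    keeping main terms, until every remaining interaction is significant."""
    design = design.copy()
    fit = fit_fb_model(records, design, response=response)
    while True:
        inter = [c for c in design.columns
                 if ":" in c and c in fit.lrt.index and fit.lrt.at[c, "p"] >= alpha]
        if not inter:
            return fit, design
        worst = max(inter, key=lambda c: fit.lrt.at[c, "p"])
        design = design.drop(columns=worst)
        fit = fit_fb_model(records, design, response=response)
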