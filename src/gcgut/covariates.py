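"""Developmental-window glucocorticoid covariates and design construction.

Maternal fecal GC metabolite concentrations (ng/g) are aggregated into three
developmental windows — early gestation (days 1-82), late gestation (day 83 to
birth) and lactation (first six months, days 0-182 after birth) — and offspring
GC samples into per-season means. All concentration covariates enter models
log-transformed and z-scaled; age enters either as a three-level class
(infant/juvenile/adult) or as a continuous z-scored variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARLY_GESTATION_END = 82          # last day of the early-gestation window
LACTATION_WINDOW_DAYS = 182       # six months, boundary inclusive

GC_COLUMNS = ("subject_id", "role", "phase", "timing_day", "season", "concentration")

#: GC covariates that are log-then-z transformed before modelling
GC_PREDICTORS = ("EarlyPreGC", "LatePreGC", "PostGC", "OffspringGC")


class CovariateError(ValueError):
    pass


class MissingWindowError(CovariateError):
    def __init__(self, subject, window):
        self.subject, self.window = subject, window
        super().__init__(f"subject {subject!r}: no GC samples in window {window!r}")


def assign_gestation_window(timing_day: int, gestation_length: int = 164) -> str:
    """Classify a gestation day as ``early`` (days 1-82) or ``late``."""
    if not (1 <= timing_day <= gestation_length):
        raise CovariateError(
            f"timing_day={timing_day} outside gestation 1..{gestation_length}"
        )
    return "early" if timing_day <= EARLY_GESTATION_END else "late"


def window_means(gc_samples: pd.DataFrame, gestation_length: int = 164) -> pd.DataFrame:
    """Per-offspring window means of GC concentration.

    ``gc_samples`` has columns subject_id (the offspring/dyad key), role
    (mother/offspring), phase (gestation/lactation/offspring), timing_day
    (day relative to conception for gestation, to birth otherwise), season
    (offspring samples) and concentration (ng/g, > 0).

    Returns one row per subject with columns early_pre_gc, late_pre_gc,
    post_gc, offspring_gc_rich, offspring_gc_lean (arithmetic means; the
    lactation window keeps only days 0-182; a season without offspring
    samples yields NaN for that season's mean, a missing maternal window
    raises :class:`MissingWindowError`).
    """
    if (gc_samples["concentration"] <= 0).any():
        raise CovariateError("GC concentrations must be strictly positive")
    rows = {}
    for subject, grp in gc_samples.groupby("subject_id", sort=False):
        gest = grp[(grp["role"] == "mother") & (grp["phase"] == "gestation")]
        lact = grp[(grp["role"] == "mother") & (grp["phase"] == "lactation")]
        off = grp[grp["role"] == "offspring"]

        windows = gest["timing_day"].map(
            lambda d: assign_gestation_window(int(d), gestation_length)
        )
        early = gest.loc[windows == "early", "concentration"]
        late = gest.loc[windows == "late", "concentration"]
        post = lact.loc[
            (lact["timing_day"] >= 0) & (lact["timing_day"] <= LACTATION_WINDOW_DAYS),
            "concentration",
        ]
        for name, vals in (("early", early), ("late", late), ("post", post)):
            if len(vals) == 0:
                raise MissingWindowError(subject, name)
        row = {
            "early_pre_gc": early.mean(),
            "late_pre_gc": late.mean(),
            "post_gc": post.mean(),
        }
        for season in ("rich", "lean"):
            vals = off.loc[off["season"] == season, "concentration"]
            row[f"offspring_gc_{season}"] = vals.mean() if len(vals) else np.nan
        rows[subject] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass(frozen=True)
class TransformMeta:
    """Log-scale mean/SD used for z-scaling; permits exact inversion."""

    log_mean: float
    log_sd: float

    def inverse(self, z):
        return np.exp(np.asarray(z) * self.log_sd + self.log_mean)


def log_z_transform(values) -> tuple[np.ndarray, TransformMeta]:
    """ln then z-scale (sample SD, n-1 denominator); rejects nonpositive
    values and zero log-variance input."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise CovariateError("need a 1-d array with at least two values")
    if (v <= 0).any():
        raise CovariateError("values must be strictly positive for log transform")
    logs = np.log(v)
    mu, sd = logs.mean(), logs.std(ddof=1)
    if sd == 0:
        raise CovariateError("zero variance after log transform")
    return (logs - mu) / sd, TransformMeta(log_mean=float(mu), log_sd=float(sd))


def z_transform(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Plain z-scale (used for continuous age)."""
    v = np.asarray(values, dtype=float)
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        raise CovariateError("zero variance")
    return (v - mu) / sd, (float(mu), float(sd))


def build_design(
    covariates: pd.DataFrame,
    age: str = "continuous",
    interactions: tuple = (),
    include_group: bool = True,
    include_season: bool = True,
    intercept: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Model design matrix from per-subject covariate rows.

    ``covariates`` needs columns early_pre_gc, late_pre_gc, post_gc,
    offspring_gc (ng/g, already resolved to the modelled season), age_years,
    age_class, sex (F/M), season (lean/rich) and optionally group. GC columns
    are log-then-z scaled over the rows actually supplied (each analysis set
    is scaled on its own data), sex/season/group become treatment dummies
    (references female, lean, first-sorted group), and age enters either as a
    z-scored continuous column (``age="continuous"``) or as juvenile/adult
    dummies with infant reference (``age="class"``). ``interactions`` names
    predictors crossed with continuous Age. Returns (design, transform_meta).
    """
    required = ["early_pre_gc", "late_pre_gc", "post_gc", "offspring_gc",
                "age_years", "sex", "season"]
    for col in required:
        if col not in covariates.columns:
            raise CovariateError(f"missing covariate column {col!r}")
        if covariates[col].isna().any():
            bad = covariates.index[covariates[col].isna()][0]
            raise CovariateError(f"subject {bad!r}: missing value for {col!r}")

    design = pd.DataFrame(index=covariates.index)
    meta: dict = {}
    if intercept:
        design["Intercept"] = 1.0
    gc_map = {
        "EarlyPreGC": "early_pre_gc",
        "LatePreGC": "late_pre_gc",
        "PostGC": "post_gc",
        "OffspringGC": "offspring_gc",
    }
    for name, col in gc_map.items():
        design[name], meta[name] = log_z_transform(covariates[col].values)
    design["Sex[M]"] = (covariates["sex"].astype(str) == "M").astype(float)
    if age == "continuous":
        design["Age"], meta["Age"] = z_transform(covariates["age_years"].values)
    elif age == "class":
        cls = covariates["age_class"].astype(str)
        design["Age[juv]"] = (cls == "juvenile").astype(float)
        design["Age[adu]"] = (cls == "adult").astype(float)
    else:
        raise CovariateError(f"age must be 'continuous' or 'class', got {age!r}")
    if include_season:
        design["Season[rich]"] = (covariates["season"].astype(str) == "rich").astype(float)
    if include_group and "group" in covariates.columns:
        levels = sorted(covariates["group"].astype(str).unique())
        for lev in levels[1:]:
            design[f"Group[{lev}]"] = (covariates["group"].astype(str) == lev).astype(float)
    for pred in interactions:
        if pred not in design.columns:
            raise CovariateError(f"interaction predictor {pred!r} not in design")
        if "Age" not in design.columns:
            raise CovariateError("predictor-by-age interactions need continuous age")
        design[f"{pred}:Age"] = design[pred] * design["Age"]
    return design, meta


def vif_screen(design: pd.DataFrame, threshold: float = 5.0):
    """Variance inflation factors; columns with VIF > threshold are flagged.

    VIF_k = 1/(1 - R^2_k) from regressing column k on the other non-intercept
    columns (with intercept). Exactly collinear columns report VIF = inf.
    """
    cols = [c for c in design.columns if c != "Intercept"]
    if len(cols) < 2:
        raise CovariateError("need at least two non-intercept columns")
    if len(design) <= len(cols):
        raise CovariateError("need more rows than columns")
    vifs = {}
    for col in cols:
        y = design[col].values.astype(float)
        others = [c for c in cols if c != col]
        X = np.column_stack([np.ones(len(design))] + [design[c].values for c in others])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ss_tot = ((y - y.mean()) ** 2).sum()
        ss_res = (resid ** 2).sum()
        if ss_tot == 0:
            vifs[col] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    retained = [c for c in cols if vifs[c] <= threshold]
    return vifs, retained
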