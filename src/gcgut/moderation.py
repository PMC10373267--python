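"""Age-moderation of GC effects: simple slopes at age anchors and their
classification as amplification, attenuation, or reversal.

For a feature with main-effect coefficient ``b`` and predictor-by-age
interaction coefficient ``g`` (age z-scored), the conditional effect of a
one-SD predictor increase at age anchor ``z`` is ``e_z = b + z * g``.
Evaluated at z = -1, 0, +1 (one SD below the mean age, the mean, one SD
above), the trajectory of |e_z| determines the moderation class:

- **reverse** — the effect changes sign between the young and old anchors;
- **amplify** — same sign and |e(+1)| > |e(-1)| (suffix ``_pos``/``_neg`` by
  the sign of the mean-age effect);
- **attenuate** — same sign and |e(+1)| < |e(-1)|.

Anchor effects within ``epsilon`` of zero borrow the other anchor's sign so
numerical zeros never manufacture a reversal; a feature whose three effects
are all within ``epsilon`` of zero (or whose anchors tie exactly) is labelled
``none``. Per-predictor summaries bin the share of features affected into the
ordinal relevance scale (not / slightly / mildly / considerably / highly
relevant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dabc import DabcFit, percent_of_total


class ModerationError(ValueError):
    pass


MODERATION_CLASSES = (
    "amplify_pos", "amplify_neg", "attenuate_pos", "attenuate_neg", "reverse",
)

RELEVANCE_BINS = (
    (0.0, 5.0, "not relevant"),
    (5.0, 10.0, "slightly relevant"),
    (10.0, 20.0, "mildly relevant"),
    (20.0, 40.0, "considerably relevant"),
    (40.0, 100.0, "highly relevant"),
)


@dataclass(frozen=True)
class ModerationConfig:
    """Age anchors (z scale) and the zero tolerance for anchor effects.

    ``anchor_ages`` optionally annotates the anchors with real ages in years
    (purely descriptive; the classification runs on the z scale).
    """

    anchors: tuple = (-1.0, 0.0, 1.0)
    epsilon: float = 1e-9
    anchor_ages: tuple | None = None

    def __post_init__(self):
        if not all(a < b for a, b in zip(self.anchors, self.anchors[1:])):
            raise ModerationError("anchors must be strictly increasing")
        if self.epsilon < 0:
            raise ModerationError("epsilon must be nonnegative")


DEFAULT_CONFIG = ModerationConfig()


def conditional_effects(beta_main: float, beta_interaction: float,
                        config: ModerationConfig = DEFAULT_CONFIG) -> tuple:
    """Simple slopes ``e_z = beta_main + z * beta_interaction`` at the anchors."""
    if not (np.isfinite(beta_main) and np.isfinite(beta_interaction)):
        raise ModerationError("coefficients must be finite")
    return tuple(beta_main + z * beta_interaction for z in config.anchors)


def classify_moderation(effects, config: ModerationConfig = DEFAULT_CONFIG) -> str:
    """Classify an anchor-effect triple; see the module docstring for rules."""
    e_lo, e_mid, e_hi = effects
    eps = config.epsilon
    if abs(e_lo) <= eps and abs(e_hi) <= eps:
        return "none"
    s_lo = np.sign(e_lo) if abs(e_lo) > eps else np.sign(e_hi)
    s_hi = np.sign(e_hi) if abs(e_hi) > eps else np.sign(e_lo)
    if s_lo != s_hi:
        return "reverse"
    suffix = "_pos" if (e_mid if abs(e_mid) > eps else e_lo + e_hi) > 0 else "_neg"
    if abs(e_hi) > abs(e_lo):
        return "amplify" + suffix
    if abs(e_hi) < abs(e_lo):
        return "attenuate" + suffix
    return "none"


def relevance_bin(pct_significant: float) -> str:
    """Ordinal relevance of a predictor from the share of features it
    significantly affects (half-open bins, upper bin closed at 100)."""
    if not (0.0 <= pct_significant <= 100.0):
        raise ModerationError(f"percentage {pct_significant} outside [0, 100]")
    for lo, hi, label in RELEVANCE_BINS:
        if lo <= pct_significant < hi:
            return label
    return RELEVANCE_BINS[-1][2]


@dataclass
class ModerationResult:
    """Per-feature anchor effects and classes for one predictor."""

    predictor: str
    effects: pd.DataFrame          # feature x (e_minus, e_zero, e_plus)
    classes: pd.Series             # feature -> class label

    def to_tsv(self, path):
        out = self.effects.copy()
        out["class"] = self.classes
        out.to_csv(path, sep="\t", index_label="feature")


@dataclass
class ModerationSummary:
    """Per-predictor moderation bookkeeping (counts, shares, relevance)."""

    predictor: str
    n_significant: int
    n_total: int
    pct_of_total: float
    relevance: str
    counts: dict
    pct_among_significant: dict    # amplify/attenuate/reverse, one decimal
    pct_of_all: dict               # same numerators over n_total

    def as_row(self) -> dict:
        row = {
            "predictor": self.predictor,
            "n_significant": self.n_significant,
            "pct_of_total": self.pct_of_total,
            "relevance": self.relevance,
        }
        for k in ("amplify", "attenuate", "reverse"):
            row[f"pct_{k}"] = self.pct_among_significant.get(k)
        return row


def moderation_effects(fit_or_beta, predictor: str, age_predictor: str = "Age",
                       features=None,
                       config: ModerationConfig = DEFAULT_CONFIG) -> ModerationResult:
    """Anchor effects and classes for every requested feature.

    ``fit_or_beta`` is a :class:`~gcgut.dabc.DabcFit` or a feature-by-predictor
    coefficient DataFrame containing columns ``predictor`` and
    ``"<predictor>:<age_predictor>"``.
    """
    beta = fit_or_beta.beta if isinstance(fit_or_beta, DabcFit) else fit_or_beta
    inter = f"{predictor}:{age_predictor}"
    for col in (predictor, inter):
        if col not in beta.columns:
            raise ModerationError(f"coefficient column {col!r} not present")
    if features is None:
        features = beta.index
    rows, classes = {}, {}
    for feat in features:
        eff = conditional_effects(beta.at[feat, predictor],
                                  beta.at[feat, inter], config)
        rows[feat] = dict(zip(("e_minus", "e_zero", "e_plus"), eff))
        classes[feat] = classify_moderation(eff, config)
    effects = pd.DataFrame.from_dict(rows, orient="index")
    return ModerationResult(predictor=predictor, effects=effects,
                            classes=pd.Series(classes, name="class"))


def summarize_predictor(classes: pd.Series, n_total: int,
                        predictor: str = "") -> ModerationSummary:
    """Moderation summary over the significant features of one predictor.

    ``classes`` holds the class labels of the *significant* features only;
    percentages among significant are reported to one decimal (missing when
    nothing is significant), alongside the same counts as shares of all
    ``n_total`` analyzed features and the relevance bin.
    """
    n_sig = int(len(classes))
    groups = {"amplify": 0, "attenuate": 0, "reverse": 0}
    for label in classes:
        for g in groups:
            if str(label).startswith(g):
                groups[g] += 1
    pct_total = percent_of_total(n_sig, n_total)
    if n_sig:
        pct_sig = {g: round(100.0 * c / n_sig, 1) for g, c in groups.items()}
    else:
        pct_sig = {g: None for g in groups}
    pct_all = {g: round(100.0 * c / n_total, 1) for g, c in groups.items()}
    return ModerationSummary(
        predictor=predictor, n_significant=n_sig, n_total=n_total,
        pct_of_total=pct_total, relevance=relevance_bin(pct_total),
        counts=groups, pct_among_significant=pct_sig, pct_of_all=pct_all,
    )


def moderation_summary(fit: DabcFit, predictor: str, age_predictor: str = "Age",
                       config: ModerationConfig = DEFAULT_CONFIG) -> ModerationSummary:
    """End-to-end per-predictor summary from a fitted DA model.

    A feature counts as significantly age-moderated when the BH-adjusted
    p-value of the predictor-by-age interaction falls below the fit's level.
    """
    inter = f"{predictor}:{age_predictor}"
    if inter not in fit.significant.columns:
        raise ModerationError(f"interaction column {inter!r} not in fit")
    sig = fit.significant.index[fit.significant[inter]]
    res = moderation_effects(fit, predictor, age_predictor, features=sig,
                             config=config)
    return summarize_predictor(res.classes, n_total=len(fit.features),
                               predictor=predictor)


def seasonal_concordance(fit_rich: DabcFit, fit_lean: DabcFit, predictor: str,
                         age_predictor: str = "Age") -> pd.Series:
    """Compare the direction of the mean-age effect between seasons.

    Features significant (for the predictor-by-age interaction) in both
    seasons are ``concordant``/``discordant`` by the sign of the mean-age
    effect e0 (= the main-effect coefficient); features significant in one
    season are ``one-season-only``; the rest ``not-significant``.
    """
    if set(fit_rich.features) != set(fit_lean.features):
        raise ModerationError("fits cover different feature universes")
    inter = f"{predictor}:{age_predictor}"
    labels = {}
    for feat in fit_rich.features:
        sr = bool(fit_rich.significant.at[feat, inter])
        sl = bool(fit_lean.significant.at[feat, inter])
        if sr and sl:
            same = np.sign(fit_rich.beta.at[feat, predictor]) == np.sign(
                fit_lean.beta.at[feat, predictor])
            labels[feat] = "concordant" if same else "discordant"
        elif sr or sl:
            labels[feat] = "one-season-only"
        else:
            labels[feat] = "not-significant"
    return pd.Series(labels, name="concordance")
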