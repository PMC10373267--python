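"""Synthetic mother-offspring cohorts with known ground truth.

The generator emulates a cross-sectional field study of a seasonally breeding
primate: dyads of mothers (sampled for fecal GC metabolites across a 164-day
gestation, split at day 82, and a six-month lactation) and offspring sampled
as infants, juveniles, or adults in a rich (March-October) and a lean
(November-February) season. Gut community count tables follow the log-linear
absolute-abundance model the differential-abundance engine assumes:

    count_ij ~ Poisson( exp( log s_i + alpha_j + x_i' beta_j + eps_ij ) )

with per-sample log sampling fractions ``log s_i ~ N(0, sd^2)``, feature
baselines ``alpha_j`` scaled to a target library size, design covariates
``x_i`` (log-z GC windows, z age, sex, season, and GC-by-age interactions),
and Poisson-lognormal overdispersion ``eps_ij ~ N(0, dispersion^2)``. A
subset of features carries designed GC effects whose age moderation class
(amplify/attenuate/reverse, signed) is known exactly, so every downstream
stage can be tested for recovery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .covariates import build_design, window_means
from .moderation import classify_moderation, conditional_effects
from .profiles import CountTable

GC_PREDICTORS = ("EarlyPreGC", "LatePreGC", "PostGC", "OffspringGC")

#: designed per-class (main, interaction-with-age) log-fold effects
DEFAULT_EFFECT_SIZES = {
    "EarlyPreGC": {
        "amplify_pos": (0.8, 0.6),
        "amplify_neg": (-0.8, -0.6),
        "attenuate_pos": (0.8, -0.6),
        "attenuate_neg": (-0.8, 0.6),
        "reverse": (0.5, -1.5),
    }
}

#: phylum composition weights (dominant Firmicutes/Bacteroidota community)
DEFAULT_PHYLA = {
    "Firmicutes": 0.593,
    "Bacteroidota": 0.179,
    "Spirochaetota": 0.093,
    "Proteobacteria": 0.035,
    "Verrucomicrobiota": 0.029,
    "Actinobacteriota": 0.029,
    "Cyanobacteria": 0.016,
    "Fibrobacterota": 0.026,
}

# subject-level window concentration (mean, SD) in ng/g; the SDs anchor the
# one-SD interpretation of each predictor
GC_WINDOW_LEVELS = {
    "early": (180.0, 59.3),
    "late": (210.0, 67.0),
    "post": (160.0, 52.7),
    "offspring": (450.0, 130.1),
}

AGE_CLUSTERS = {"infant": (0.5, 0.15), "juvenile": (4.5, 0.5), "adult": (8.0, 1.0)}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs of the synthetic cohort."""

    n_dyads: int = 30
    gestation_length_days: int = 164
    n_gc_samples_per_window: int = 4
    n_offspring_samples_per_season: int = 4
    n_features: int = 150
    n_per_class: int = 6
    effect_sizes: dict = field(default_factory=lambda: DEFAULT_EFFECT_SIZES)
    phyla: dict = field(default_factory=lambda: DEFAULT_PHYLA)
    dispersion: float = 0.5
    sampling_fraction_sd: float = 0.5
    depth_mean: float = 60_000.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_dyads", "n_gc_samples_per_window",
                     "n_offspring_samples_per_season", "n_features",
                     "n_per_class"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.gestation_length_days < 83:
            raise SimulationError(
                "gestation_length_days must be >= 83 so both windows are nonempty"
            )
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.sampling_fraction_sd < 0:
            raise SimulationError("sampling_fraction_sd must be >= 0")
        if self.depth_mean <= 0:
            raise SimulationError("depth_mean must be > 0")
        if "Firmicutes" not in self.phyla or "Bacteroidota" not in self.phyla:
            raise SimulationError("phyla must include Firmicutes and Bacteroidota")


@dataclass
class GroundTruth:
    """True coefficients and nuisances behind a simulated count table."""

    beta: pd.DataFrame                 # feature x design-column
    log_sampling_fraction: pd.Series   # per sample
    designed_class: pd.Series          # feature -> class label ('null' mostly)
    design: pd.DataFrame               # the true per-sample design used

    def nonnull_features(self) -> list:
        return list(self.designed_class.index[self.designed_class != "null"])


@dataclass
class Cohort:
    gc_samples: pd.DataFrame
    metadata: pd.DataFrame
    table: CountTable
    tree: TreeNode
    ground_truth: GroundTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a log-normal with the given arithmetic
    mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def random_tree(feature_ids, rng: np.random.Generator) -> TreeNode:
    """Rooted random binary tree over the features, exponential branch
    lengths (coalescent-style random pairing)."""
    nodes = [f"{fid}:{rng.exponential(0.5):.6f}" for fid in feature_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{rng.exponential(0.5):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return TreeNode.read(io.StringIO(newick))


def _make_lineages(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Feature lineage table; ~10% of features unclassified at genus level."""
    phyla = list(config.phyla)
    weights = np.array([config.phyla[p] for p in phyla], dtype=float)
    weights = weights / weights.sum()
    assignment = rng.choice(len(phyla), size=config.n_features, p=weights)
    # guarantee both ratio phyla are represented
    assignment[0] = phyla.index("Firmicutes")
    assignment[1] = phyla.index("Bacteroidota")
    rows = {}
    for j in range(config.n_features):
        phylum = phyla[assignment[j]]
        family = f"{phylum[:4]}_fam{j % 7 + 1}"
        genus = "UN" if rng.random() < 0.1 else f"{family}_gen{j % 3 + 1}"
        rows[f"ASV{j + 1:04d}"] = {"phylum": phylum, "family": family,
                                   "genus": genus}
    return pd.DataFrame.from_dict(rows, orient="index")


def _feature_baselines(lineages: pd.DataFrame, phyla: dict,
                       rng: np.random.Generator) -> np.ndarray:
    """Log baseline abundances alpha_j reflecting the phylum weights."""
    counts = lineages["phylum"].value_counts()
    alpha = np.empty(len(lineages))
    for j, (fid, row) in enumerate(lineages.iterrows()):
        w = phyla.get(row["phylum"], 0.01)
        alpha[j] = np.log(w / counts[row["phylum"]]) + rng.normal(0.0, 0.7)
    return alpha


def _assign_effects(config: SimConfig, features,
                    design_columns) -> tuple[pd.DataFrame, pd.Series]:
    """True coefficient matrix and designed moderation classes.

    Classes are assigned to the first features in order (the feature ids are
    themselves randomly generated); the ``reverse`` class is split into two
    mirrored halves so the cross-feature coefficient field stays balanced.
    """
    beta = pd.DataFrame(0.0, index=features, columns=design_columns)
    classes = pd.Series("null", index=features, dtype=object)
    cursor = 0
    for predictor, class_map in config.effect_sizes.items():
        inter_col = f"{predictor}:Age"
        for cls, (main, inter) in class_map.items():
            n = config.n_per_class
            if cursor + n > len(features):
                raise SimulationError("more designed features than n_features")
            block = features[cursor:cursor + n]
            signs = np.ones(n)
            if cls == "reverse":
                signs[n // 2:] = -1.0  # mirrored halves keep the field balanced
            beta.loc[block, predictor] = main * signs
            beta.loc[block, inter_col] = inter * signs
            for fid, s in zip(block, signs):
                eff = conditional_effects(main * s, inter * s)
                expected = classify_moderation(eff)
                if cls != "reverse" and expected != cls:
                    raise SimulationError(
                        f"effect sizes for class {cls!r} classify as {expected!r}"
                    )
                classes[fid] = cls
            cursor += n
    return beta, classes


def _draw_counts(design: pd.DataFrame, beta: pd.DataFrame, alpha: np.ndarray,
                 config: SimConfig, rng: np.random.Generator):
    """Poisson-lognormal counts under the log-linear absolute-abundance model."""
    X = design.values.astype(float)
    log_mu = alpha[None, :] + X @ beta.values.T
    # scale baselines so the expected library size matches depth_mean
    scale = np.log(config.depth_mean) - np.log(np.exp(log_mu).sum(axis=1).mean())
    log_mu = log_mu + scale
    d = rng.normal(0.0, config.sampling_fraction_sd, size=len(design))
    d -= d.mean()
    eps = rng.normal(0.0, config.dispersion, size=log_mu.shape)
    lam = np.exp(log_mu + d[:, None] + eps)
    counts = rng.poisson(lam)
    return counts, d


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _simulate_gc_samples(config: SimConfig, dyads: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Maternal gestation/lactation and offspring per-season GC series."""
    rows = []
    windows = {
        "early": (1, 82, "gestation"),
        "late": (83, config.gestation_length_days, "gestation"),
        "post": (0, 182, "lactation"),
    }
    for dyad, info in dyads.iterrows():
        for window, (lo, hi, phase) in windows.items():
            mu, sigma = _lognormal_params(*GC_WINDOW_LEVELS[window])
            subject_level = rng.lognormal(mu, sigma)
            days = rng.integers(lo, hi + 1, size=config.n_gc_samples_per_window)
            for day in days:
                conc = subject_level * rng.lognormal(-0.045, 0.3)
                rows.append({"subject_id": dyad, "role": "mother",
                             "phase": phase, "timing_day": int(day),
                             "season": "", "concentration": conc})
        mu, sigma = _lognormal_params(*GC_WINDOW_LEVELS["offspring"])
        for season in ("rich", "lean"):
            subject_level = rng.lognormal(mu, sigma)
            for _ in range(config.n_offspring_samples_per_season):
                conc = subject_level * rng.lognormal(-0.045, 0.3)
                rows.append({"subject_id": dyad, "role": "offspring",
                             "phase": "offspring", "timing_day": 0,
                             "season": season, "concentration": conc})
    return pd.DataFrame(rows, columns=["subject_id", "role", "phase",
                                       "timing_day", "season", "concentration"])


def _simulate_dyads(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Dyad roster: age cluster, continuous age, sex, social group."""
    share = {"infant": 16, "juvenile": 7, "adult": 7}  # cross-sectional mix
    total = sum(share.values())
    classes = []
    for cls, n in share.items():
        classes += [cls] * round(n * config.n_dyads / total)
    while len(classes) < config.n_dyads:
        classes.append("infant")
    classes = classes[: config.n_dyads]
    rows = {}
    for i, cls in enumerate(classes):
        mu, sd = AGE_CLUSTERS[cls]
        rows[f"D{i + 1:03d}"] = {
            "age_class": cls,
            "age_years": max(0.05, rng.normal(mu, sd)),
            "sex": "M" if rng.random() < 0.5 else "F",
            "group": rng.choice(["G1", "G2", "G3"]),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def simulate_cohort(config: SimConfig) -> Cohort:
    """Full synthetic cohort: GC series, sample metadata, count table with
    known coefficients, lineages, tree, and ground truth.

    Identical configs (same seed) give bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    dyads = _simulate_dyads(config, rng)
    gc_samples = _simulate_gc_samples(config, dyads, rng)
    win = window_means(gc_samples, config.gestation_length_days)

    # one microbiome sample per offspring per season per replicate
    meta_rows = {}
    for dyad, info in dyads.iterrows():
        for season in ("rich", "lean"):
            for r in range(config.n_offspring_samples_per_season):
                sid = f"{dyad}_{season}_{r + 1}"
                meta_rows[sid] = {
                    "individual": dyad, "season": season,
                    "age_years": info["age_years"],
                    "age_class": info["age_class"],
                    "sex": info["sex"], "group": info["group"],
                }
    metadata = pd.DataFrame.from_dict(meta_rows, orient="index")
    metadata.index.name = "sample_id"

    cov = metadata.join(win, on="individual")
    cov["offspring_gc"] = np.where(
        cov["season"] == "rich", cov["offspring_gc_rich"], cov["offspring_gc_lean"]
    )
    design, _ = build_design(
        cov, age="continuous",
        interactions=GC_PREDICTORS,
        include_group=False,
    )

    lineages = _make_lineages(config, rng)
    features = list(lineages.index)
    alpha = _feature_baselines(lineages, config.phyla, rng)
    beta, classes = _assign_effects(config, features, list(design.columns))
    counts, d = _draw_counts(design, beta, alpha, config, rng)
    table = CountTable(
        counts=pd.DataFrame(counts, index=design.index, columns=features),
        lineages=lineages,
    )
    tree = random_tree(features, rng)
    truth = GroundTruth(
        beta=beta,
        log_sampling_fraction=pd.Series(
            d, index=design.index.rename(None),
            name="log_sampling_fraction"),
        designed_class=classes,
        design=design,
    )
    return Cohort(gc_samples=gc_samples, metadata=metadata, table=table,
                  tree=tree, ground_truth=truth, config=config)


# ---------------------------------------------------------------------------
# generic differential-abundance benchmark dataset
# ---------------------------------------------------------------------------

def simulate_da_dataset(seed: int, n_samples: int = 200, n_features: int = 150,
                        effect_sizes: dict | None = None, n_per_class: int = 6,
                        dispersion: float = 0.5,
                        sampling_fraction_sd: float = 0.5,
                        depth_mean: float = 60_000.0):
    """Design + counts + ground truth for coefficient-recovery benchmarks.

    Covariates are drawn directly on the modelling scale (z-scaled GC windows
    and age as standard normals, sex and season as balanced dummies) with the
    four GC-by-age interaction columns, so the returned design can be passed
    straight to :func:`gcgut.dabc.fit_dabc`.

    Returns ``(table, design, truth)``.
    """
    rng = np.random.default_rng(seed)
    cols = {"Intercept": np.ones(n_samples)}
    for pred in GC_PREDICTORS:
        cols[pred] = rng.normal(size=n_samples)
    cols["Sex[M]"] = (rng.random(n_samples) < 0.5).astype(float)
    cols["Age"] = rng.normal(size=n_samples)
    cols["Season[rich]"] = (rng.random(n_samples) < 0.5).astype(float)
    for pred in GC_PREDICTORS:
        cols[f"{pred}:Age"] = cols[pred] * cols["Age"]
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    design = pd.DataFrame(cols, index=samples)

    config = SimConfig(
        n_features=n_features, n_per_class=n_per_class,
        effect_sizes=(effect_sizes if effect_sizes is not None
                      else DEFAULT_EFFECT_SIZES),
        dispersion=dispersion, sampling_fraction_sd=sampling_fraction_sd,
        depth_mean=depth_mean, seed=seed,
    )
    lineages = _make_lineages(config, rng)
    features = list(lineages.index)
    alpha = _feature_baselines(lineages, config.phyla, rng)
    beta, classes = _assign_effects(config, features, list(design.columns))
    counts, d = _draw_counts(design, beta, alpha, config, rng)
    table = CountTable(
        counts=pd.DataFrame(counts, index=samples, columns=features),
        lineages=lineages,
    )
    truth = GroundTruth(
        beta=beta,
        log_sampling_fraction=pd.Series(d, index=samples,
                                        name="log_sampling_fraction"),
        designed_class=classes,
        design=design,
    )
    return table, design, truth


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(dir_path, cohort: Cohort) -> dict:
    """Write a cohort as TSV/newick/YAML files; returns the path map."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / "counts.tsv",
        "lineages": d / "lineages.tsv",
        "metadata": d / "metadata.tsv",
        "gc_samples": d / "gc_samples.tsv",
        "tree": d / "tree.nwk",
        "truth_beta": d / "truth_beta.tsv",
        "truth_class": d / "truth_class.tsv",
        "truth_sampling_fraction": d / "truth_sampling_fraction.tsv",
        "config": d / "config.yaml",
    }
    cohort.table.to_tsv(paths["counts"], paths["lineages"])
    cohort.metadata.to_csv(paths["metadata"], sep="\t")
    cohort.gc_samples.to_csv(paths["gc_samples"], sep="\t", index=False)
    cohort.tree.write(str(paths["tree"]))
    truth = cohort.ground_truth
    truth.beta.to_csv(paths["truth_beta"], sep="\t", index_label="feature_id",
                      float_format="%.17g")
    truth.designed_class.rename("designed_class").to_csv(
        paths["truth_class"], sep="\t", index_label="feature_id")
    truth.log_sampling_fraction.to_csv(
        paths["truth_sampling_fraction"], sep="\t", index_label="sample_id",
        float_format="%.17g")
    cfg = {k: v for k, v in vars(cohort.config).items()
           if not isinstance(v, dict)}
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh)
    return {k: str(v) for k, v in paths.items()}


def read_fixture(dir_path) -> Cohort:
    """Read a fixture written by :func:`write_fixture` (lossless for counts,
    metadata, GC samples, tree, and full-precision ground truth)."""
    d = Path(dir_path)
    table = CountTable.from_tsv(d / "counts.tsv", d / "lineages.tsv")
    metadata = pd.read_csv(d / "metadata.tsv", sep="\t", index_col="sample_id")
    gc_samples = pd.read_csv(d / "gc_samples.tsv", sep="\t",
                             keep_default_na=False)
    tree = TreeNode.read(str(d / "tree.nwk"))
    beta = pd.read_csv(d / "truth_beta.tsv", sep="\t",
                       index_col="feature_id").astype(float)
    beta.index.name = None
    classes = pd.read_csv(d / "truth_class.tsv", sep="\t",
                          index_col="feature_id",
                          keep_default_na=False)["designed_class"]
    classes.index.name = None
    lsf = pd.read_csv(d / "truth_sampling_fraction.tsv", sep="\t",
                      index_col="sample_id")["log_sampling_fraction"]
    lsf.index.name = None
    with open(d / "config.yaml") as fh:
        cfg = yaml.safe_load(fh)
    config = SimConfig(**cfg)
    truth = GroundTruth(beta=beta, log_sampling_fraction=lsf,
                        designed_class=classes, design=None)
    return Cohort(gc_samples=gc_samples, metadata=metadata, table=table,
                  tree=tree, ground_truth=truth, config=config)
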