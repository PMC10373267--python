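"""End-to-end run: simulate (or load) -> covariates -> profiles -> diversity
-> differential abundance -> moderation -> F/B ratio, with TSV report tables
and a manifest. A fixed config (including its seed) reproduces every output
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .covariates import GC_PREDICTORS, build_design, vif_screen, window_means
from .dabc import fit_dabc
from .diversity import diversity_indices, fit_lmm, full_null_lrt
from .fbratio import compute_fb, reduce_fb_model
from .moderation import ModerationConfig, moderation_summary
from .profiles import CountTable, aggregate_rank, merge_replicates, read_stats
from .simulate import SimConfig, read_fixture, simulate_cohort, write_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    out_dir: str = "gcgut_run"
    seed: int = 0
    input_dir: str | None = None          # fixture dir; None -> simulate
    simulation: dict = field(default_factory=dict)
    ranks: tuple = ("phylum", "family", "genus")
    seasons: tuple = ("rich", "lean")
    bh_q: float = 0.05
    vif_threshold: float = 5.0
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("bh_q", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise PipelineError(f"{name}={v} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("ranks", "seasons"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage; returns the report-path manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    logging.getLogger("gcgut").addHandler(handler)
    try:
        return _run(config, out)
    except Exception as exc:  # annotate with the failing stage
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logging.getLogger("gcgut").removeHandler(handler)


def _run(config: RunConfig, out: Path) -> dict:
    manifest = {"version": __version__, "seed": config.seed,
                "config": vars(config).copy()}
    manifest["config"]["ranks"] = list(config.ranks)
    manifest["config"]["seasons"] = list(config.seasons)

    _stage("cohort")
    if config.input_dir is not None:
        if not Path(config.input_dir).exists():
            raise PipelineError(f"cohort: input_dir {config.input_dir!r} not found")
        cohort = read_fixture(config.input_dir)
    else:
        sim = SimConfig(seed=config.seed, **config.simulation)
        cohort = simulate_cohort(sim)
        write_fixture(out / "cohort", cohort)

    table, metadata, gc = cohort.table, cohort.metadata, cohort.gc_samples

    _stage("profiles")
    stats = read_stats(table)
    with open(out / "read_stats.json", "w") as fh:
        json.dump(stats, fh, indent=1)

    _stage("covariates")
    win = window_means(gc, cohort.config.gestation_length_days)
    cov = metadata.join(win, on="individual")
    cov["offspring_gc"] = cov.apply(
        lambda r: r[f"offspring_gc_{r['season']}"], axis=1)
    cov.to_csv(out / "covariates.tsv", sep="\t")

    _stage("diversity")
    div = diversity_indices(table, cohort.tree)
    div.to_csv(out / "diversity.tsv", sep="\t", index_label="sample_id")
    design_div, _ = build_design(cov, age="class", include_group=True)
    vifs, _ = vif_screen(design_div, config.vif_threshold)
    drop = [c for c, v in vifs.items() if v > config.vif_threshold]
    if drop:
        logger.warning("dropping collinear predictors (VIF>%.0f): %s",
                       config.vif_threshold, drop)
        design_div = design_div.drop(columns=drop)
    groups = metadata["individual"].values
    lmm_rows = []
    for index_name in div.columns:
        full = fit_lmm(div[index_name].values, design_div, groups)
        null = fit_lmm(div[index_name].values,
                       design_div[["Intercept"]], groups)
        chi2, dof, p = full_null_lrt(full, null)
        full.coefficients.assign(index=index_name).to_csv(
            out / f"lmm_{index_name}.tsv", sep="\t", index_label="predictor")
        lmm_rows.append({"index": index_name, "chi2": chi2, "df": dof, "p": p,
                         "r2_conditional": full.r2_conditional,
                         "converged": full.converged})
    pd.DataFrame(lmm_rows).to_csv(out / "lmm_full_null.tsv", sep="\t",
                                  index=False)

    _stage("differential abundance")
    mod_cfg = ModerationConfig()
    grid_rows, summary_rows = [], []
    fits = {}
    for season in config.seasons:
        season_samples = metadata.index[metadata["season"] == season]
        sub = table.counts.loc[season_samples]
        sub_meta = metadata.loc[season_samples]
        for rank in config.ranks:
            sub_table = CountTable(counts=sub, lineages=table.lineages)
            ranked = aggregate_rank(sub_table, rank)
            _, merged = merge_replicates(ranked, sub_meta)
            merged_cov = cov[cov["season"] == season].drop_duplicates(
                subset=None).groupby("individual").first()
            merged_cov = merged_cov.loc[[i for i, s in merged.counts.index]]
            merged_cov.index = merged.counts.index
            design_da, _ = build_design(
                merged_cov, age="continuous", interactions=GC_PREDICTORS,
                include_group=False, include_season=False)
            fit = fit_dabc(merged, design_da, alpha=config.bh_q)
            fit.to_tsv(out / f"dabc_{rank}_{season}.tsv")
            fits[(rank, season)] = fit
            for pred in GC_PREDICTORS:
                summ = moderation_summary(fit, pred, config=mod_cfg)
                row = summ.as_row()
                row.update({"rank": rank, "season": season})
                summary_rows.append(row)
                grid_rows.append({
                    "predictor": f"{pred}:Age", "rank": rank,
                    "season": season, "pct_significant": summ.pct_of_total,
                    "relevance": summ.relevance,
                })

    _stage("moderation")
    pd.DataFrame(grid_rows).to_csv(out / "percent_significant_grid.tsv",
                                   sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(out / "moderation_summary.tsv",
                                      sep="\t", index=False)

    _stage("fb ratio")
    fb_rows = []
    for season in config.seasons:
        season_samples = metadata.index[metadata["season"] == season]
        sub_table = CountTable(counts=table.counts.loc[season_samples],
                               lineages=table.lineages)
        phylum = aggregate_rank(sub_table, "phylum")
        rel, _ = merge_replicates(phylum, metadata.loc[season_samples])
        records = compute_fb(rel)
        merged_cov = cov[cov["season"] == season].groupby("individual").first()
        merged_cov = merged_cov.loc[[i for i, s in records.index]]
        merged_cov.index = records.index
        design_fb, _ = build_design(
            merged_cov, age="continuous", interactions=GC_PREDICTORS,
            include_group=False, include_season=False)
        try:
            fit, reduced_design = reduce_fb_model(records, design_fb,
                                                  alpha=config.alpha)
            fit.to_tsv(out / f"fb_model_{season}.tsv")
            chi2, dof, p = fit.null_comparison
            fb_rows.append({"season": season, "chi2": chi2, "df": dof, "p": p,
                            "pseudo_r2": fit.pseudo_r2, "n": fit.n_obs})
        except Exception as exc:
            raise PipelineError(f"fb ratio ({season}): {exc}") from exc
    pd.DataFrame(fb_rows).to_csv(out / "fb_full_null.tsv", sep="\t",
                                 index=False)

    _stage("manifest")
    cfg_hash = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest["config_hash"] = cfg_hash
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
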