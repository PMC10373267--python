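"""Count tables, taxonomy acceptance, rank aggregation and abundance profiles.

The feature unit is the ASV (amplicon sequence variant) of a 16S rRNA gene
survey, but nothing here depends on that: any nonnegative integer
sample-by-feature matrix with a rank lineage per feature works, including
predicted functional (KO pathway) tables whose "lineage" is a single label.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("phylum", "family", "genus")

#: label used for features whose taxonomy was rejected or missing at a rank
UNCLASSIFIED = "UN"


class ProfileError(ValueError):
    pass


@dataclass
class CountTable:
    """Sample-by-feature count matrix with per-feature rank lineages.

    counts: DataFrame, rows = samples, columns = features, nonnegative ints.
    lineages: DataFrame indexed by feature with columns phylum/family/genus
        (missing ranks carry the ``UN`` label or an ``UN:<parent>`` label).
    """

    counts: pd.DataFrame
    lineages: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ProfileError("count table contains negative entries")
        if self.lineages is None:
            self.lineages = pd.DataFrame(
                {r: UNCLASSIFIED for r in RANKS}, index=self.counts.columns
            )
        missing = self.counts.columns.difference(self.lineages.index)
        if len(missing):
            raise ProfileError(
                f"features without lineage entry: {list(missing)[:5]}"
            )
        self.lineages = self.lineages.loc[self.counts.columns]
        # normalize axis names so TSV round trips compare equal
        self.counts.index.name = None
        self.counts.columns.name = None
        self.lineages.index.name = None

    @property
    def samples(self) -> list:
        return list(self.counts.index)

    @property
    def features(self) -> list:
        return list(self.counts.columns)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)

    # -- TSV round trip ----------------------------------------------------
    def to_tsv(self, counts_path, lineage_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
        if lineage_path is not None:
            self.lineages.to_csv(lineage_path, sep="\t", index_label="feature_id")

    @classmethod
    def from_tsv(cls, counts_path, lineage_path=None) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
        lineages = None
        if lineage_path is not None:
            lineages = pd.read_csv(lineage_path, sep="\t", index_col="feature_id")
        return cls(counts=counts.astype(np.int64), lineages=lineages)


# ---------------------------------------------------------------------------
# taxonomy acceptance
# ---------------------------------------------------------------------------

def accept_hit(percent_identity: float, percent_coverage: float) -> bool:
    """Best-hit acceptance gate: mean of %identity and %coverage >= 93.

    Rejected hits are treated as unclassified at every rank.
    """
    for name, v in (("percent_identity", percent_identity),
                    ("percent_coverage", percent_coverage)):
        if not (0.0 <= v <= 100.0):
            raise ProfileError(f"{name}={v} outside [0, 100]")
    return (percent_identity + percent_coverage) / 2.0 >= 93.0


def lineages_from_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Turn a best-hit table into a lineage table, applying the acceptance gate.

    ``hits`` needs columns feature_id, percent_identity, percent_coverage and
    the rank columns; rejected rows get ``UN`` at all ranks.
    """
    out = {}
    for _, row in hits.iterrows():
        ok = accept_hit(row["percent_identity"], row["percent_coverage"])
        out[row["feature_id"]] = (
            {r: row[r] for r in RANKS} if ok else {r: UNCLASSIFIED for r in RANKS}
        )
    return pd.DataFrame.from_dict(out, orient="index")[list(RANKS)]


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

def _is_unclassified(label) -> bool:
    return (
        label is None
        or (isinstance(label, float) and math.isnan(label))
        or (isinstance(label, str) and (label == UNCLASSIFIED or label.startswith("UN:")))
    )


def _rank_label(lineage: pd.Series, rank: str) -> str:
    """Aggregation label at ``rank``; unclassified features pool under the
    nearest classified parent as ``UN:<parent>`` (one UN row per parent)."""
    label = lineage.get(rank)
    if not _is_unclassified(label):
        return label
    idx = RANKS.index(rank)
    for parent in reversed(RANKS[:idx]):
        parent_label = lineage.get(parent)
        if not _is_unclassified(parent_label):
            return f"UN:{parent_label}"
    return UNCLASSIFIED


def aggregate_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over features sharing a rank label; per-sample totals are
    conserved exactly."""
    if rank not in RANKS:
        raise ProfileError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = table.lineages.apply(_rank_label, axis=1, rank=rank)
    agg = table.counts.T.groupby(labels.values).sum().T
    # carry a lineage table at the aggregated level (ranks above `rank`)
    keep = RANKS[: RANKS.index(rank)]
    lin_rows = {}
    for lab, feats in table.lineages.groupby(labels.values):
        row = {r: feats.iloc[0].get(r, UNCLASSIFIED) for r in keep}
        row[rank] = lab
        lin_rows[lab] = row
    lineages = pd.DataFrame.from_dict(lin_rows, orient="index")
    lineages = lineages.reindex(columns=list(keep) + [rank])
    return CountTable(counts=agg, lineages=lineages.loc[agg.columns])


# ---------------------------------------------------------------------------
# relative abundance and replicate merging
# ---------------------------------------------------------------------------

def relative_abundance(table: CountTable, metadata: pd.DataFrame | None = None,
                       group_by=None):
    """Per-sample proportions; optionally mean +/- SD over a metadata grouping.

    Zero-depth samples are excluded with a warning. Each retained row sums to
    one within 1e-12.
    """
    depths = table.depths
    zero = depths[depths == 0].index
    if len(zero):
        logger.warning("excluding %d zero-depth samples: %s", len(zero), list(zero))
    counts = table.counts.drop(index=zero)
    rel = counts.div(counts.sum(axis=1), axis=0)
    if group_by is None:
        return rel
    groups = metadata.loc[rel.index, group_by]
    mean = rel.groupby(groups if isinstance(group_by, str) else
                       [groups[c] for c in group_by]).mean()
    sd = rel.groupby(groups if isinstance(group_by, str) else
                     [groups[c] for c in group_by]).std(ddof=1)
    return mean, sd


def top_features(mean_rel: pd.Series | pd.DataFrame, k: int) -> list:
    """The ``k`` features with largest mean relative abundance."""
    mean = mean_rel.mean(axis=0) if isinstance(mean_rel, pd.DataFrame) else mean_rel
    return list(mean.sort_values(ascending=False).index[:k])


def merge_replicates(table: CountTable, metadata: pd.DataFrame,
                     individual_col: str = "individual",
                     season_col: str = "season"):
    """Collapse seasonal biological replicates to one row per individual-season.

    Returns ``(rel, counts)``: the mean of per-sample relative abundances and,
    for count-based downstream fits, the per-feature mean counts rounded to the
    nearest integer. Individuals with no sample in a season simply yield no
    row for that season (logged).
    """
    rel = relative_abundance(table)
    meta = metadata.loc[rel.index]
    key = list(zip(meta[individual_col], meta[season_col]))
    key_index = pd.MultiIndex.from_tuples(key, names=[individual_col, season_col])
    rel_m = rel.set_axis(key_index).groupby(level=[0, 1]).mean()
    cnt = table.counts.loc[rel.index].set_axis(key_index)
    cnt_m = cnt.groupby(level=[0, 1]).mean().round().astype(np.int64)
    n_ind = metadata[individual_col].nunique()
    for season, grp in rel_m.groupby(level=1):
        if len(grp) < n_ind:
            logger.info("season %s: %d of %d individuals sampled",
                        season, len(grp), n_ind)
    merged_lineages = table.lineages
    return rel_m, CountTable(counts=cnt_m, lineages=merged_lineages)


# ---------------------------------------------------------------------------
# dataset bookkeeping
# ---------------------------------------------------------------------------

def read_stats(table: CountTable) -> dict:
    """Per-sample sequencing-depth summary.

    The mean is reported truncated toward zero (integer), the SD uses the n-1
    denominator; a single-sample table reports the SD as missing.
    """
    depths = table.depths
    if len(depths) == 0:
        raise ProfileError("empty count table")
    total = int(depths.sum())
    return {
        "total": total,
        "mean": total // len(depths),
        "sd": float(depths.std(ddof=1)) if len(depths) > 1 else None,
        "median": float(depths.median()),
        "range": (int(depths.min()), int(depths.max())),
        "n_samples": int(len(depths)),
    }


def mean_per_subject(n_samples: int, n_subjects: int) -> float:
    """Average sampling effort per subject, reported to one decimal."""
    if n_subjects <= 0:
        raise ProfileError("n_subjects must be positive")
    return round(n_samples / n_subjects, 1)
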