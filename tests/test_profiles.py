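import numpy as np
import pandas as pd
import pytest

from gcgut.profiles import (
    CountTable,
    ProfileError,
    accept_hit,
    aggregate_rank,
    lineages_from_hits,
    mean_per_subject,
    merge_replicates,
    read_stats,
    relative_abundance,
    top_features,
)


def make_table(counts, lineages=None, samples=None):
    counts = np.atleast_2d(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    feats = [f"f{j}" for j in range(counts.shape[1])]
    cdf = pd.DataFrame(counts, index=samples, columns=feats)
    ldf = None
    if lineages is not None:
        ldf = pd.DataFrame(lineages, index=feats)
    return CountTable(counts=cdf, lineages=ldf)


class TestAcceptHit:
    @pytest.mark.parametrize("ident, cov, expected", [
        (93, 93, True),     # boundary: mean exactly 93
        (100, 85, False),   # mean 92.5
        (96, 90, True),     # mean 93
        (100, 100, True),
        (0, 0, False),
    ])
    def test_gate(self, ident, cov, expected):
        assert accept_hit(ident, cov) is expected

    @pytest.mark.parametrize("ident, cov", [(101, 50), (-1, 50), (50, 140)])
    def test_out_of_range_rejected(self, ident, cov):
        with pytest.raises(ProfileError):
            accept_hit(ident, cov)

    def test_rejected_hits_become_unclassified(self):
        hits = pd.DataFrame([
            {"feature_id": "a", "percent_identity": 99, "percent_coverage": 99,
             "phylum": "Firmicutes", "family": "Lachnospiraceae",
             "genus": "Blautia"},
            {"feature_id": "b", "percent_identity": 100, "percent_coverage": 85,
             "phylum": "Firmicutes", "family": "Lachnospiraceae",
             "genus": "Blautia"},
        ])
        lin = lineages_from_hits(hits)
        assert lin.loc["a", "genus"] == "Blautia"
        assert (lin.loc["b"] == "UN").all()


class TestAggregateRank:
    def setup_method(self):
        self.table = make_table(
            [[3, 4, 5, 6]],
            lineages={
                "phylum": ["Bacteroidota"] * 3 + ["Firmicutes"],
                "family": ["Prevotellaceae"] * 3 + ["Lachnospiraceae"],
                "genus": ["Prevotella", "Prevotella", "UN", "Blautia"],
            },
        )

    def test_same_genus_sums(self):
        out = aggregate_rank(self.table, "genus")
        assert out.counts.loc["s0", "Prevotella"] == 7

    def test_unclassified_pools_under_parent(self):
        out = aggregate_rank(self.table, "genus")
        assert out.counts.loc["s0", "UN:Prevotellaceae"] == 5

    def test_per_sample_totals_conserved(self):
        for rank in ("phylum", "family", "genus"):
            out = aggregate_rank(self.table, rank)
            pd.testing.assert_series_equal(out.depths, self.table.depths)

    def test_unknown_rank_rejected(self):
        with pytest.raises(ProfileError, match="rank"):
            aggregate_rank(self.table, "kingdom")


class TestRelativeAbundance:
    def test_single_sample_proportions(self):
        rel = relative_abundance(make_table([[60, 40]]))
        np.testing.assert_allclose(rel.loc["s0"], [0.6, 0.4])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rel = relative_abundance(make_table(rng.integers(1, 50, (6, 9))))
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, atol=1e-12)

    def test_group_means(self):
        table = make_table([[1, 0], [0, 1]])
        meta = pd.DataFrame({"g": ["x", "x"]}, index=["s0", "s1"])
        mean, sd = relative_abundance(table, meta, group_by="g")
        np.testing.assert_allclose(mean.loc["x"], [0.5, 0.5])

    def test_zero_depth_sample_excluded(self):
        rel = relative_abundance(make_table([[2, 2], [0, 0]]))
        assert list(rel.index) == ["s0"]

    def test_top_k_selection(self):
        rng = np.random.default_rng(1)
        rel = relative_abundance(make_table(rng.integers(1, 50, (4, 30))))
        top = top_features(rel, 20)
        assert len(top) == 20
        means = rel.mean(axis=0)
        assert min(means[top]) >= max(means.drop(top))


class TestMergeReplicates:
    def _meta(self, samples, individuals, seasons):
        return pd.DataFrame({"individual": individuals, "season": seasons},
                            index=samples)

    def test_mean_of_relative_abundances(self):
        table = make_table([[2, 8], [4, 6]])
        meta = self._meta(["s0", "s1"], ["A", "A"], ["lean", "lean"])
        rel, _ = merge_replicates(table, meta)
        np.testing.assert_allclose(rel.loc[("A", "lean")], [0.3, 0.7])

    def test_single_replicate_identity(self):
        table = make_table([[2, 8]])
        meta = self._meta(["s0"], ["A"], ["rich"])
        rel, _ = merge_replicates(table, meta)
        np.testing.assert_allclose(rel.loc[("A", "rich")], [0.2, 0.8])

    def test_idempotent_on_merged_tables(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.integers(1, 99, (6, 5)))
        meta = self._meta(table.samples, ["A", "A", "B", "B", "C", "C"],
                          ["lean"] * 6)
        rel1, merged = merge_replicates(table, meta)
        meta2 = pd.DataFrame(
            {"individual": [i for i, s in merged.counts.index],
             "season": [s for i, s in merged.counts.index]},
            index=merged.counts.index)
        merged2 = CountTable(counts=merged.counts.set_axis(
            [f"{i}_{s}" for i, s in merged.counts.index]),
            lineages=merged.lineages)
        meta2.index = merged2.counts.index
        rel2, _ = merge_replicates(merged2, meta2)
        assert rel2.shape == rel1.shape

    def test_unbalanced_seasons_row_counts(self):
        # 30 individuals sampled in lean, only 16 of them in rich
        rng = np.random.default_rng(3)
        inds, seas, rows = [], [], []
        for i in range(30):
            inds.append(f"I{i}")
            seas.append("lean")
            rows.append(rng.integers(1, 50, 4))
            if i < 16:
                inds.append(f"I{i}")
                seas.append("rich")
                rows.append(rng.integers(1, 50, 4))
        table = make_table(np.array(rows))
        meta = self._meta(table.samples, inds, seas)
        rel, _ = merge_replicates(table, meta)
        assert len(rel.xs("lean", level="season")) == 30
        assert len(rel.xs("rich", level="season")) == 16


class TestReadStats:
    def test_small_example(self):
        stats = read_stats(make_table([[10], [20], [30]]))
        assert stats["total"] == 60
        assert stats["mean"] == 20
        assert stats["median"] == 20
        assert stats["range"] == (10, 30)

    def test_mean_truncates_toward_zero(self):
        # depths summing to 64 over 3 samples: 64/3 = 21.33 -> 21
        assert read_stats(make_table([[20], [21], [23]]))["mean"] == 21

    def test_single_sample_sd_missing(self):
        assert read_stats(make_table([[10]]))["sd"] is None

    def test_sd_uses_n_minus_one(self):
        stats = read_stats(make_table([[10], [20], [30]]))
        assert stats["sd"] == pytest.approx(10.0)


def test_mean_per_subject_rounding():
    assert mean_per_subject(192, 30) == 6.4
    assert mean_per_subject(231, 30) == 7.7
    with pytest.raises(ProfileError):
        mean_per_subject(10, 0)


def test_count_table_rejects_negative_and_missing_lineage():
    with pytest.raises(ProfileError):
        make_table([[-1, 2]])
    counts = pd.DataFrame([[1, 2]], index=["s0"], columns=["f0", "f1"])
    with pytest.raises(ProfileError, match="lineage"):
        CountTable(counts=counts,
                   lineages=pd.DataFrame({"phylum": ["P"]}, index=["f0"]))


def test_count_table_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    table = make_table(rng.integers(0, 9, (3, 4)),
                       lineages={"phylum": ["A", "A", "B", "B"],
                                 "family": ["a", "a", "b", "b"],
                                 "genus": ["g1", "g2", "UN", "g3"]})
    table.to_tsv(tmp_path / "c.tsv", tmp_path / "l.tsv")
    back = CountTable.from_tsv(tmp_path / "c.tsv", tmp_path / "l.tsv")
    pd.testing.assert_frame_equal(back.counts, table.counts)
    pd.testing.assert_frame_equal(back.lineages, table.lineages)
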