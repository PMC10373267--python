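import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcgut.covariates import (
    CovariateError,
    MissingWindowError,
    assign_gestation_window,
    build_design,
    log_z_transform,
    vif_screen,
    window_means,
)


class TestGestationWindow:
    @pytest.mark.parametrize("day, expected", [
        (1, "early"), (82, "early"), (83, "late"), (164, "late"),
    ])
    def test_boundaries(self, day, expected):
        assert assign_gestation_window(day, 164) == expected

    @pytest.mark.parametrize("day", [0, -3, 165])
    def test_out_of_gestation_rejected(self, day):
        with pytest.raises(CovariateError):
            assign_gestation_window(day, 164)

    def test_windows_partition_gestation(self):
        labels = [assign_gestation_window(d, 164) for d in range(1, 165)]
        assert labels.count("early") == 82
        assert labels.count("late") == 164 - 82
        assert sorted(set(labels)) == ["early", "late"]


def _gc_row(subject, role, phase, day, conc, season=""):
    return dict(subject_id=subject, role=role, phase=phase, timing_day=day,
                season=season, concentration=conc)


class TestWindowMeans:
    def test_one_sample_per_window(self):
        gc = pd.DataFrame([
            _gc_row("A", "mother", "gestation", 10, 10.0),
            _gc_row("A", "mother", "gestation", 100, 20.0),
            _gc_row("A", "mother", "lactation", 30, 30.0),
        ])
        out = window_means(gc)
        assert out.loc["A", "early_pre_gc"] == 10.0
        assert out.loc["A", "late_pre_gc"] == 20.0
        assert out.loc["A", "post_gc"] == 30.0

    def test_six_month_postnatal_filter(self):
        gc = pd.DataFrame([
            _gc_row("A", "mother", "gestation", 10, 1.0),
            _gc_row("A", "mother", "gestation", 100, 1.0),
            _gc_row("A", "mother", "lactation", 100, 40.0),
            _gc_row("A", "mother", "lactation", 200, 400.0),  # beyond 182 d
        ])
        assert window_means(gc).loc["A", "post_gc"] == 40.0

    def test_arithmetic_mean_within_window(self):
        gc = pd.DataFrame([
            _gc_row("A", "mother", "gestation", 5, 50.0),
            _gc_row("A", "mother", "gestation", 60, 70.0),
            _gc_row("A", "mother", "gestation", 120, 5.0),
            _gc_row("A", "mother", "lactation", 10, 1.0),
        ])
        assert window_means(gc).loc["A", "early_pre_gc"] == 60.0

    def test_missing_window_names_subject_and_window(self):
        gc = pd.DataFrame([
            _gc_row("B", "mother", "gestation", 10, 1.0),
            _gc_row("B", "mother", "lactation", 10, 1.0),
        ])
        with pytest.raises(MissingWindowError, match="B.*late"):
            window_means(gc)

    def test_offspring_means_split_by_season(self):
        gc = pd.DataFrame([
            _gc_row("A", "mother", "gestation", 10, 1.0),
            _gc_row("A", "mother", "gestation", 100, 1.0),
            _gc_row("A", "mother", "lactation", 10, 1.0),
            _gc_row("A", "offspring", "offspring", 0, 100.0, "rich"),
            _gc_row("A", "offspring", "offspring", 0, 300.0, "rich"),
            _gc_row("A", "offspring", "offspring", 0, 50.0, "lean"),
        ])
        out = window_means(gc)
        assert out.loc["A", "offspring_gc_rich"] == 200.0
        assert out.loc["A", "offspring_gc_lean"] == 50.0

    def test_nonpositive_concentration_rejected(self):
        gc = pd.DataFrame([_gc_row("A", "mother", "gestation", 10, 0.0)])
        with pytest.raises(CovariateError):
            window_means(gc)


class TestLogZ:
    def test_two_point_example(self):
        z, meta = log_z_transform([1.0, np.e])
        np.testing.assert_allclose(z, [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-4)

    def test_constant_rejected(self):
        with pytest.raises(CovariateError, match="variance"):
            log_z_transform([3.0, 3.0, 3.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(CovariateError):
            log_z_transform([1.0, -2.0, 3.0])

    @given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=3,
                    max_size=40, unique=True))
    @settings(derandomize=True, max_examples=50)
    def test_normalization_and_inverse(self, values):
        z, meta = log_z_transform(values)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1.0) < 1e-10
        np.testing.assert_allclose(meta.inverse(z), values, rtol=1e-12)


def _cov_frame(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "early_pre_gc": rng.uniform(50, 300, n),
        "late_pre_gc": rng.uniform(50, 300, n),
        "post_gc": rng.uniform(50, 300, n),
        "offspring_gc": rng.uniform(100, 900, n),
        "age_years": rng.uniform(0.3, 9, n),
        "age_class": ["infant", "juvenile", "adult", "infant"] * (n // 4),
        "sex": ["F", "M"] * (n // 2),
        "season": ["lean", "rich"] * (n // 2),
        "group": ["G1", "G2"] * (n // 2),
    }, index=[f"S{i}" for i in range(n)])


class TestBuildDesign:
    def test_dummy_codings(self):
        design, _ = build_design(_cov_frame())
        assert list(design["Sex[M]"][:2]) == [0.0, 1.0]       # female reference
        assert list(design["Season[rich]"][:2]) == [0.0, 1.0]  # lean reference
        assert list(design["Group[G2]"][:2]) == [0.0, 1.0]

    def test_interaction_is_elementwise_product(self):
        design, _ = build_design(_cov_frame(), interactions=("EarlyPreGC",))
        np.testing.assert_allclose(
            design["EarlyPreGC:Age"], design["EarlyPreGC"] * design["Age"])

    def test_gc_columns_are_z_scaled(self):
        design, meta = build_design(_cov_frame())
        for col in ("EarlyPreGC", "LatePreGC", "PostGC", "OffspringGC", "Age"):
            assert abs(design[col].mean()) < 1e-8
            assert abs(design[col].std(ddof=1) - 1) < 1e-8

    def test_age_class_dummies(self):
        design, _ = build_design(_cov_frame(), age="class")
        assert {"Age[juv]", "Age[adu]"} <= set(design.columns)
        assert "Age" not in design.columns

    def test_permutation_equivariance(self):
        cov = _cov_frame(8)
        d1, _ = build_design(cov)
        perm = list(cov.index[::-1])
        d2, _ = build_design(cov.loc[perm])
        pd.testing.assert_frame_equal(d1.loc[perm], d2)

    def test_missing_covariate_names_subject(self):
        cov = _cov_frame()
        cov.loc["S3", "post_gc"] = np.nan
        with pytest.raises(CovariateError, match="S3"):
            build_design(cov)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 16
        design = pd.DataFrame({
            "Intercept": np.ones(n),
            "a": np.tile([1.0, -1.0], n // 2),
            "b": np.tile([1.0, 1.0, -1.0, -1.0], n // 4),
        })
        vifs, retained = vif_screen(design)
        assert vifs["a"] == pytest.approx(1.0)
        assert vifs["b"] == pytest.approx(1.0)
        assert retained == ["a", "b"]

    def test_duplicate_column_flagged_infinite(self):
        n = 12
        x = np.arange(n, dtype=float)
        design = pd.DataFrame({"Intercept": np.ones(n), "a": x, "b": x})
        vifs, retained = vif_screen(design)
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])
        assert retained == []

    def test_r2_09_gives_vif_10(self):
        # x2 = x1 + e/3 with e orthogonal to x1 and var(e)=var(x1): R^2 = 0.9
        x1 = np.tile([1.0, -1.0], 10)
        e = np.tile([1.0, 1.0, -1.0, -1.0], 5)
        design = pd.DataFrame({"Intercept": np.ones(20), "x1": x1,
                               "x2": x1 + e / 3.0})
        vifs, retained = vif_screen(design)
        assert vifs["x2"] == pytest.approx(10.0)
        assert "x2" not in retained
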